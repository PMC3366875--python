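# cdamesh

Clinicians searching the literature about a patient face a gap between the
patient's electronic health record and PubMed's vocabulary: MEDLINE
citations are indexed with **MeSH** (Medical Subject Headings) descriptors,
while the record is free text inside the coded sections of an **HL7-CDA**
document. `cdamesh` closes that gap in two steps:

1. **Keyword identification** — parse the CDA document into sections,
   restrict attention to sections a configuration declares relevant
   (Allergies, History of Present Illness, …), and scan the narrative for
   MeSH descriptors and their entry-term synonyms using a normalized
   hash-table lookup with greedy longest match. Each rule confines matching
   to a subset of the 16 MeSH tree branches (a *Penicillin* mention means
   something different in *Allergies* than in *Family History*), and
   mentions preceded by a negation trigger ("no Pain") are flagged and
   excluded from query candidacy.
2. **Iterative query construction** — AND-chain selected keywords with a
   disease descriptor from branch C into PubMed `[mh]` queries:

   ```
   (term_1[mh]) AND (term_2[mh]) AND … AND (term_n[mh]) AND (disease[mh])
   ```

   The n-th query retrieves only citations indexed by at least *n + 1* of
   the record's MeSH terms — formally, every returned citation has
   relatedness `Rel = |MeSH(citation) ∩ (MeSH(record) ∪ {disease})| ≥ n+1`
   — so each iteration shrinks the result list toward a manageable,
   record-specific set. Subheading qualifiers (`Asthma/epidemiology`) add
   a further restriction when admissible for both the descriptor and the
   section.

The package ships a deterministic local citation backend implementing the
query semantics exactly, an optional live NCBI E-utilities client
(rate-limited, cached), descriptor-level precision/recall evaluation
against gold annotations, and seeded generators for mini-MeSH thesauri,
CDA documents with known ground truth, and MeSH-indexed corpora — so the
whole pipeline is testable offline.

## Worked example

Generate a self-contained fixture set and run the pipeline:

```bash
$ cdamesh make-fixtures --out demo --seed 11 --n-descriptors 60 --n-docs 3 --n-citations 150
wrote fixtures for 3 documents to demo

$ cdamesh identify demo/doc001.xml --mesh demo/mesh.tsv \
    --backend local --corpus demo/corpus.tsv --disease Tugoto
section 0 [22:33] Puve Paduvi (D000020) ^4
section 0 [57:70] Zecegi Mesori (D000030) ^2
section 0 [94:98] Becu (D000036) ^2
section 0 [103:107] Rebi (D000059) [negated]
section 1 [22:26] Tome (D000027) ^1
section 1 [50:54] Talo (D000043) ^1
```

Each line is one identified MeSH mention: section index, character span,
preferred name, descriptor id. The superscript (`^4`) is the candidate
count — how many citations the query would retrieve if that keyword were
AND-added to the current disease query; `[negated]` marks a mention
preceded by a negation trigger, shown but never offered as a query
candidate. Selecting a keyword builds and runs the query:

```bash
$ cdamesh query demo/doc001.xml --mesh demo/mesh.tsv --disease Tugoto \
    --term "Puve Paduvi" --backend local --corpus demo/corpus.tsv
(Puve Paduvi[mh]) AND (Tugoto[mh])
count: 4
PM000122
PM000082
PM000079
PM000126
```

Four citations are indexed by both the disease and the selected keyword
(newest first). Evaluation against the generated gold annotations shows
the branch-restriction trade-off — widening the branch set catches
out-of-branch distractor mentions and costs precision:

```bash
$ cdamesh evaluate --docs demo --gold demo/gold.tsv --mesh demo/mesh.tsv \
    --branches ABCDEFGHIJKLMNVZ --branches ABCDEFG --baseline
config	precision	recall
ABCDEFGHIJKLMNVZ	78.6	100.0
ABCDEFG	100.0	100.0
baseline	66.7	100.0
```

The same operations are available as a library: `load_mesh`, `parse_cda`,
`identify_keywords`, `initial_query`/`add_term`/`render_query`,
`LocalBackend.count`, `precision_recall`, `reduction_curve`. See
`docs/methods.md` for the model and its assumptions.

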