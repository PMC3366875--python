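# Methods

## The identification model

`cdamesh` performs dictionary-based concept recognition: a MeSH thesaurus
is compiled into a hash table mapping *normalized* surface forms (every
entry term of every descriptor) to descriptor ids, and the narrative of
each relevant CDA section is scanned against it.

**Normalization.** A surface form's lookup key is produced by
lower-casing, collapsing every run of non-alphanumeric characters to a
single space, and stripping the ends. This is deliberately slightly
stronger than trimming edge punctuation: the matcher joins token windows
with spaces, so `Diabetes Mellitus , Type 1` (as tokenized, with the comma
a separate token) and the entry term `Diabetes Mellitus, Type 1` must map
to the same key (`diabetes mellitus type 1`). The function is
deterministic and idempotent. No stemming is applied — MeSH entry terms
already enumerate lexical variants, and exact matching preserves
precision.

**Sentence and token segmentation.** A small regex segmenter is used:
sentences end at `.`, `!` or `?` followed by whitespace; tokens are
maximal word characters or single punctuation marks, with character
offsets into the section text preserved throughout (the standoff output
depends on exact spans). Punctuation tokens participate in multi-word
windows ("Diabetes Mellitus, Type 1") but a match may neither start nor
end on one.

**Matching.** Greedy longest match, left to right, within one sentence:
at each token position, windows from `max_term_tokens` (the longest entry
term, measured in the same token convention) down to 1 are normalized and
looked up; the first hit whose descriptor set intersects the section's
allowed descriptors emits one match per intersecting descriptor (ambiguous
entry terms yield all candidates) and scanning resumes past the window.
Matches never cross sentence boundaries. This is the standard
dictionary-NER choice; the test suite pins it against an exhaustive
n-gram scan with longest-match pruning.

**Section relevance and branch restriction.** An ordered list of section
rules drives the scan. A rule matches a section by LOINC/SNOMED code
(checked first, across all rules, because codes are unambiguous) or by
normalized title; the first matching rule wins and unmatched sections are
skipped entirely. Each rule restricts the dictionary to descriptors with
at least one tree number in its branch set. Two defaults coexist and are
separately overridable: the shipped rules carry branches A–G, and a rule
whose branches are left unset falls back to the nine branches A–G, N, Z.
The disease anchoring queries is drawn from branch C by default.

**Negation.** A mention is negated when one of the `window` (default 3)
tokens immediately preceding it within its sentence, normalized, is in
the trigger lexicon {no, not, denies, denied, without, negative, absent,
non}. Both lexicon and window are deliberately simple and configurable; a
trigger more than `window` tokens away ("No family history of asthma",
window 3) is not detected — a documented limitation of window-based
negation. Negated mentions remain in the output, flagged, but are
excluded from query candidacy and from evaluation.

## Queries and retrieval

A query is an ordered conjunction of term clauses plus a final disease
clause, rendered as `(Name[mh])` conjuncts joined with ` AND `. A clause
with q attached qualifiers renders as q separate conjuncts
`(Name/qualifier[mh])`. The `[mh]` tag is rendered on every conjunct,
including qualified ones, for uniform MeSH-field semantics. Preferred
names (not the matched surface form) are rendered, since PubMed MeSH
fields are descriptor-based. Clause order is selection order; duplicate
descriptors are no-ops; attaching a qualifier requires admissibility for
both the descriptor (its allowable-qualifier list) and the originating
section's rule.

The local backend implements the conjunction exactly: a citation matches
a bare clause when the clause descriptor appears among its index terms,
and a qualified clause when each explicit (descriptor, qualifier) pair
appears. Hence the n-th query's results all share at least n + 1 index
terms with the record (the n selected terms plus the disease) — the
relatedness guarantee `Rel ≥ n+1` holds *exactly* on this backend.
Optional MeSH explosion (a descriptor matching its tree descendants, as
live PubMed `[mh]` does) is off by default precisely because it breaks
that guarantee; live and local counts therefore differ by design when
explosion applies server-side. The live E-utilities client is count-only
(`retmax=0`), cached on the rendered query string, and rate-limited to
1,000 requests per minute by default (configurable; conservative presets
are advisable for current NCBI policy). It is never exercised by the test
suite — live counts are time-varying.

## Evaluation

Scoring is at the descriptor level (the clinical gold standard is
term-level, not span-level): per document, tp = |identified ∩ gold|,
fp = |identified \ gold|, fn = |gold \ identified|, with negated
identifications excluded. Macro averaging — the mean of per-document
precision and recall — is the default; micro (pooled counts) is
available. A document with empty gold and empty identification counts as
P = R = 100 (convention; exclusion is selectable). `branch_sweep` re-runs
identification under forced branch sets plus an optional baseline row
(every section, all 16 branches, negated mentions retained).
`reduction_curve` replaces interactive keyword clicking with three
deterministic selection policies: document order, smallest surviving
count, or a scripted descriptor list reproducing a user session.

## Synthetic data: what it emulates and what it does not

The generators emulate the structure of the target data — a thesaurus
with synonyms, tree numbers and allowable qualifiers; CDA documents whose
relevant sections contain plantable mentions, negated mentions and
out-of-branch distractors, plus an irrelevant "Appointment" section; and
a citation corpus whose index sets favor a focus list so AND chains
shrink realistically. They do **not** emulate clinical language:
sentences are templated ("Patient presents with X.", "No X reported."),
every generated word is a globally unique pseudo-word, and each generated
descriptor lives in a single branch. These choices make the pipeline
*exactly solvable* — the gold standard, every confusion count and every
query count are computable from generator bookkeeping — which is the
point of the fixtures: a passing suite certifies the algorithmic
contracts (matching, filtering, negation, counting), not robustness to
real clinical prose, misspellings, sense ambiguity or abbreviations.

Default study conditions: 60 descriptors mixed over branches A–G, N, Z
(in-branch) and J, K (out-of-branch), a 30% synonym rate and 40%
multi-word rate; 10 documents with 5 planted positives, 1 negated
mention, 2 distractors and 1 irrelevant-section mention each; 200
citations with a 25% qualifier rate. Three independent PRNG streams
(thesaurus / documents / corpus) derive from one seed; identical spec and
seed give byte-identical fixtures.

## Numerical and design choices

- Rule precedence: code match beats title match; among equally matching
  rules the first in config order wins.
- Ambiguous surface forms return all candidate descriptors; downstream
  deduplication is by descriptor.
- Local search order is date descending, then id — the date ordering
  PubMed presents, made deterministic.
- The cache is keyed on the canonical rendered query string; the local
  backend's cache never expires (pure function), the live client's has a
  TTL.
- `by-smallest-count` curve policy prefers the smallest *non-zero*
  count (an empty result list helps no one), falling back to the overall
  smallest when every extension would reach zero.
- Degenerate inputs: an empty thesaurus has `max_term_tokens = 1`; a CDA
  file without sections parses to an empty document and validates with a
  warning; an empty corpus counts 0 for every query; a document with no
  identifiable keywords yields a length-1 reduction curve (the general
  disease query).

## Problem sizes

The test suite and the acceptance script run on fixtures of 40–90
descriptors, 1–10 documents and 100–200 citations, with 100 random
fixture pairs for the oracle-agreement measurement — sizes at which the
exhaustive oracles (all-n-gram scans, per-citation predicate evaluation)
are themselves fast, keeping every check exact rather than sampled.

## Known limitations

- Negation is window-based and lexicon-based; scope-aware negation (e.g.
  NegEx-style termination) is out of scope.
- No word-sense disambiguation, abbreviation expansion, or non-English
  support.
- CDA structured entries are ignored; only narrative text is mined.
- Supplementary concept records and MeSH see-also relations are not
  modeled.
- The live client's counts are index-dependent and time-varying; nothing
  in the package asserts them.
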