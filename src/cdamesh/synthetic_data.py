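"""Seeded generators for mini-MeSH thesauri, CDA documents with gold
annotations, and MeSH-indexed citation corpora.

The generators make the full pipeline *exactly solvable*: every surface
form is a globally unique pseudo-word (so dictionary matching is
unambiguous), planted mentions are embedded verbatim in templated
sentences, and the gold standard plus every query count is computable from
the generator's own bookkeeping.  Narrative realism is deliberately
secondary to exactness — sentences read "Patient presents with X." and
"No X reported."

Three independent PRNG streams (thesaurus / documents / corpus) are derived
from one seed so each fixture kind is reproducible on its own.  The same
spec and seed always produce byte-identical fixtures.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cda_reader import CdaDocument, CdaSection, SectionCode
from .citation_backend import Citation, Corpus
from .evaluation import GoldAnnotation
from .mesh_model import (
    BRANCH_LETTERS,
    MeshDescriptor,
    MeshThesaurus,
    Qualifier,
    QUALIFIER_NAMES,
)

__all__ = [
    "GeneratorSpec",
    "make_mini_mesh",
    "make_cda_set",
    "make_corpus",
    "make_curve_corpus",
    "expected_confusion",
    "expected_recall",
]

#: Words that appear in sentence templates; generated pseudo-words must
#: avoid them (and the negation lexicon) so matching stays unambiguous.
_RESERVED = frozenset(
    {
        "patient", "presents", "with", "reported", "history", "of",
        "scheduled", "follow", "up", "regarding", "examination", "shows",
        "no", "not", "denies", "denied", "without", "negative", "absent",
        "non", "stable", "condition", "overall",
    }
)

_QUALIFIER_POOL = ["EP", "DI", "TH", "GE", "CO", "DT"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for fixture generation.

    Counts are per document; ``branch_mix`` weights the single MeSH branch
    each generated descriptor lives in (a portion must fall outside
    ``relevant_branches`` or no out-of-branch distractors can be planted).
    """

    seed: int = 0
    n_descriptors: int = 60
    branch_mix: tuple[tuple[str, float], ...] = (
        ("A", 1.0), ("B", 1.0), ("C", 3.0), ("D", 1.5), ("E", 1.0),
        ("F", 1.0), ("G", 1.0), ("N", 0.5), ("Z", 0.5),
        ("J", 1.0), ("K", 1.0),
    )
    n_docs: int = 10
    planted_positives: int = 5
    negated_mentions: int = 1
    distractors: int = 2
    irrelevant_section_mentions: int = 1
    synonym_rate: float = 0.3
    multiword_rate: float = 0.4
    n_citations: int = 200
    qualifier_rate: float = 0.25
    relevant_branches: frozenset[str] = frozenset("ABCDEFG")

    def __post_init__(self) -> None:
        for name in (
            "n_descriptors", "n_docs", "planted_positives", "negated_mentions",
            "distractors", "irrelevant_section_mentions", "n_citations",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        weights = [w for _, w in self.branch_mix]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("branch_mix weights must be >= 0 and not all zero")
        bad = {b for b, _ in self.branch_mix} - BRANCH_LETTERS
        if bad:
            raise ValueError(f"invalid branch letters in branch_mix: {sorted(bad)}")
        for name in ("synonym_rate", "multiword_rate", "qualifier_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")

    def rng(self, stream: int) -> random.Random:
        """Independent PRNG stream (0 = thesaurus, 1 = documents, 2 = corpus)."""
        return random.Random((self.seed * 1_000_003 + stream) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Pseudo-word supply
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


class _WordSupply:
    """Globally unique pronounceable pseudo-words, avoiding reserved words."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set(_RESERVED)

    def word(self) -> str:
        while True:
            n_syll = self.rng.choice([2, 3, 3])
            w = "".join(
                self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
                for _ in range(n_syll)
            )
            if w not in self.used:
                self.used.add(w)
                return w


# ---------------------------------------------------------------------------
# Mini-MeSH
# ---------------------------------------------------------------------------

def make_mini_mesh(spec: GeneratorSpec) -> MeshThesaurus:
    """A small thesaurus with unique entry terms.

    Each descriptor lives in a single branch drawn from ``branch_mix`` (1–3
    tree numbers there), gets a multi-word preferred name at
    ``multiword_rate``, an extra synonym at ``synonym_rate``, and 0–3
    allowable qualifiers.
    """
    rng = spec.rng(0)
    words = _WordSupply(rng)
    branches = [b for b, _ in spec.branch_mix]
    weights = [w for _, w in spec.branch_mix]

    descriptors: list[MeshDescriptor] = []
    for i in range(spec.n_descriptors):
        uid = f"D{i + 1:06d}"
        n_words = 2 if rng.random() < spec.multiword_rate else 1
        name = " ".join(words.word() for _ in range(n_words)).title()
        entry_terms = {name}
        if rng.random() < spec.synonym_rate:
            entry_terms.add(
                " ".join(words.word() for _ in range(rng.choice([1, 2]))).title()
            )
        branch = rng.choices(branches, weights=weights, k=1)[0]
        tree_numbers = set()
        for _ in range(rng.choice([1, 1, 2, 3])):
            tree_numbers.add(
                f"{branch}{rng.randint(1, 99):02d}.{rng.randint(100, 999)}"
            )
        n_quals = rng.choice([0, 1, 2, 3])
        quals = frozenset(
            Qualifier(name=QUALIFIER_NAMES[a], abbreviation=a)
            for a in rng.sample(_QUALIFIER_POOL, n_quals)
        )
        descriptors.append(
            MeshDescriptor(
                id=uid,
                preferred_name=name,
                entry_terms=frozenset(entry_terms),
                tree_numbers=frozenset(tree_numbers),
                allowable_qualifiers=quals,
            )
        )
    return MeshThesaurus(descriptors)


# ---------------------------------------------------------------------------
# CDA documents with gold annotations
# ---------------------------------------------------------------------------

def _partition_pools(
    thesaurus: MeshThesaurus, relevant_branches: frozenset[str]
) -> tuple[list[str], list[str]]:
    """(in-branch, strictly-out-of-branch) descriptor id pools, sorted."""
    inside, outside = [], []
    for uid in sorted(thesaurus.descriptors):
        b = thesaurus.descriptors[uid].branches
        (inside if b & relevant_branches else outside).append(uid)
    return inside, outside


def _surface(rng: random.Random, d: MeshDescriptor, synonym_rate: float) -> str:
    synonyms = sorted(d.entry_terms - {d.preferred_name})
    if synonyms and rng.random() < synonym_rate:
        return rng.choice(synonyms)
    return d.preferred_name


def make_cda_set(
    spec: GeneratorSpec, thesaurus: MeshThesaurus
) -> tuple[list[CdaDocument], list[GoldAnnotation]]:
    """Documents with planted, negated, out-of-branch and irrelevant-section
    mentions, plus the gold annotations (planted non-negated in-branch
    mentions in relevant sections only).

    Sections 0 ("History of Present Illness") and 1 ("Allergies") are
    relevant under the shipped configuration; section 2 ("Appointment")
    is not.  All planted descriptors within one document are distinct, so
    descriptor-level gold is exact.
    """
    rng = spec.rng(1)
    inside, outside = _partition_pools(thesaurus, spec.relevant_branches)
    need_in = spec.planted_positives + spec.negated_mentions
    need_in += spec.irrelevant_section_mentions
    if len(inside) < need_in:
        raise ValueError(
            f"thesaurus has {len(inside)} in-branch descriptors; "
            f"{need_in} needed per document"
        )
    if len(outside) < spec.distractors:
        raise ValueError(
            f"thesaurus has {len(outside)} out-of-branch descriptors; "
            f"{spec.distractors} needed per document"
        )

    docs: list[CdaDocument] = []
    gold: list[GoldAnnotation] = []
    for doc_idx in range(spec.n_docs):
        doc_id = f"doc{doc_idx + 1:03d}"
        picked_in = rng.sample(inside, need_in)
        positives = picked_in[: spec.planted_positives]
        negated = picked_in[
            spec.planted_positives : spec.planted_positives + spec.negated_mentions
        ]
        irrelevant = picked_in[spec.planted_positives + spec.negated_mentions :]
        distract = rng.sample(outside, spec.distractors)

        half = (len(positives) + 1) // 2
        sec0_sentences = [
            f"Patient presents with {_surface(rng, thesaurus.descriptors[d], spec.synonym_rate)}."
            for d in positives[:half]
        ] + [
            f"No {_surface(rng, thesaurus.descriptors[d], spec.synonym_rate)} reported."
            for d in negated
        ]
        sec1_sentences = [
            f"Patient presents with {_surface(rng, thesaurus.descriptors[d], spec.synonym_rate)}."
            for d in positives[half:]
        ] + [
            f"Patient presents with {_surface(rng, thesaurus.descriptors[d], spec.synonym_rate)}."
            for d in distract
        ]
        sec2_sentences = [
            f"Scheduled follow up regarding {_surface(rng, thesaurus.descriptors[d], spec.synonym_rate)}."
            for d in irrelevant
        ]
        for sentences in (sec0_sentences, sec1_sentences, sec2_sentences):
            if not sentences:
                sentences.append("Overall stable condition.")

        sections = (
            CdaSection(
                title="History of Present Illness",
                codes=frozenset({SectionCode("LOINC", "10164-2")}),
                text=" ".join(sec0_sentences),
                order_index=0,
            ),
            CdaSection(
                title="Allergies",
                codes=frozenset({SectionCode("LOINC", "48765-2")}),
                text=" ".join(sec1_sentences),
                order_index=1,
            ),
            CdaSection(
                title="Appointment",
                codes=frozenset(),
                text=" ".join(sec2_sentences),
                order_index=2,
            ),
        )
        docs.append(
            CdaDocument(doc_id=doc_id, title=f"Synthetic record {doc_id}",
                        sections=sections)
        )
        for d in positives[:half]:
            gold.append(GoldAnnotation(doc_id, d, 0))
        for d in positives[half:]:
            gold.append(GoldAnnotation(doc_id, d, 1))
    return docs, gold


# ---------------------------------------------------------------------------
# Citation corpora
# ---------------------------------------------------------------------------

def make_corpus(
    spec: GeneratorSpec,
    thesaurus: MeshThesaurus,
    focus_descriptors: Sequence[str] = (),
) -> Corpus:
    """A random MeSH-indexed corpus.

    ``focus_descriptors`` (typically a document's gold terms plus the
    disease) are indexed with geometrically decreasing probabilities
    (0.8, 0.56, ...), so AND chains over them shrink realistically; every
    citation additionally indexes 1–3 background descriptors.  A
    ``qualifier_rate`` fraction of index terms carry an explicit qualifier
    pair drawn from the descriptor's allowable list.
    """
    rng = spec.rng(2)
    all_ids = sorted(thesaurus.descriptors)
    background = [d for d in all_ids if d not in set(focus_descriptors)]

    def maybe_qualified(did: str) -> tuple[str, Optional[str]]:
        quals = sorted(
            q.abbreviation
            for q in thesaurus.descriptors[did].allowable_qualifiers
        )
        if quals and rng.random() < spec.qualifier_rate:
            return (did, rng.choice(quals))
        return (did, None)

    citations: list[Citation] = []
    for i in range(spec.n_citations):
        terms: set[tuple[str, Optional[str]]] = set()
        p = 0.8
        for did in focus_descriptors:
            if rng.random() < p:
                terms.add(maybe_qualified(did))
            p *= 0.7
        for did in rng.sample(background, min(rng.choice([1, 2, 3]), len(background))):
            terms.add(maybe_qualified(did))
        if not terms:
            terms.add(maybe_qualified(rng.choice(all_ids)))
        citations.append(
            Citation(
                citation_id=f"PM{i + 1:06d}",
                title=f"Synthetic citation {i + 1}",
                index_terms=frozenset(terms),
                date=_dt.date(2000 + rng.randint(0, 10), rng.randint(1, 12),
                              rng.randint(1, 28)),
            )
        )
    return Corpus(citations)


def make_curve_corpus(
    thesaurus: MeshThesaurus,
    disease_id: str,
    term_ids: Sequence[str],
    counts: Sequence[int],
    seed: int = 0,
) -> Corpus:
    """A corpus constructed backward from a prescribed reduction curve.

    ``counts[m]`` is the number of citations the query ``disease AND
    term_1 … AND term_m`` must retrieve (``counts[0]`` = disease-only
    count); the sequence must be non-increasing with ``len(counts) ==
    len(term_ids) + 1``.  Citation j indexes the disease plus every
    ``term_k`` with ``j < counts[k+1]``, which realizes the curve exactly
    without MeSH explosion.  Background descriptors outside the chain are
    sprinkled in for realism and cannot perturb the counts.
    """
    if len(counts) != len(term_ids) + 1:
        raise ValueError("need len(counts) == len(term_ids) + 1")
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise ValueError("counts must be non-increasing")
    rng = random.Random(seed % (2**31 - 1))
    chain = {disease_id, *term_ids}
    background = [d for d in sorted(thesaurus.descriptors) if d not in chain]

    citations: list[Citation] = []
    for j in range(counts[0]):
        terms: set[tuple[str, Optional[str]]] = {(disease_id, None)}
        for k, tid in enumerate(term_ids):
            if j < counts[k + 1]:
                terms.add((tid, None))
        for did in rng.sample(background, min(2, len(background))):
            terms.add((did, None))
        citations.append(
            Citation(
                citation_id=f"PM{j + 1:06d}",
                title=f"Synthetic citation {j + 1}",
                index_terms=frozenset(terms),
                date=_dt.date(2005, 1, 1) + _dt.timedelta(days=j % 3650),
            )
        )
    return Corpus(citations)


# ---------------------------------------------------------------------------
# Bookkeeping oracles
# ---------------------------------------------------------------------------

def expected_confusion(
    gold: Sequence[GoldAnnotation],
    thesaurus: MeshThesaurus,
    doc_ids: Sequence[str],
    kept_branches: frozenset[str],
) -> dict[str, tuple[int, int, int]]:
    """Per-document (tp, fp, fn) the pipeline must produce when rules are
    restricted to ``kept_branches``: a gold descriptor is found iff one of
    its tree numbers lies in a kept branch; the construction plants no
    in-branch false positives."""
    out: dict[str, tuple[int, int, int]] = {d: (0, 0, 0) for d in doc_ids}
    for a in gold:
        tp, fp, fn = out[a.doc_id]
        branches = thesaurus.descriptors[a.descriptor_id].branches
        if branches & kept_branches:
            tp += 1
        else:
            fn += 1
        out[a.doc_id] = (tp, fp, fn)
    return out


def expected_recall(
    gold: Sequence[GoldAnnotation],
    thesaurus: MeshThesaurus,
    doc_ids: Sequence[str],
    kept_branches: frozenset[str],
) -> float:
    """Macro-averaged recall (percent) predicted by the bookkeeping."""
    conf = expected_confusion(gold, thesaurus, doc_ids, kept_branches)
    recalls = [
        100.0 * tp / (tp + fn) if tp + fn else 100.0
        for tp, _, fn in conf.values()
    ]
    return sum(recalls) / len(recalls) if recalls else 100.0
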