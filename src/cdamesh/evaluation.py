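"""Evaluation of keyword identification and of query-iteration trajectories.

Identification is scored against clinician-style gold annotations at the
descriptor (concept) level: per document, true positives are identified
descriptors present in gold, false positives identified-but-not-gold,
false negatives gold-but-missed.  Macro averaging (mean of per-document
precision and recall) is the default; micro (pooled counts) is available.
A document with empty gold and empty identification scores P = R = 100 by
convention (selectable).

``branch_sweep`` reproduces the branch-configuration comparison — widening
the branch restriction can only add identified concepts, so recall rises
and precision falls when distractor mentions live outside the kept
branches.  ``reduction_curve`` traces the citation-count trajectory as
keywords are AND-added to the disease query one per iteration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .cda_reader import CdaDocument
from .configuration import AppConfig, SectionRule
from .keyword_identifier import (
    IdentifiedKeyword,
    identify_baseline,
    identify_keywords,
)
from .mesh_model import MeshDescriptor, MeshThesaurus
from .query_engine import Query, add_term, render_query

__all__ = [
    "GoldAnnotation",
    "EvalResult",
    "precision_recall",
    "branch_sweep",
    "reduction_curve",
    "load_gold_tsv",
    "save_gold_tsv",
    "identified_descriptor_sets",
]


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    descriptor_id: str
    section_index: Optional[int] = None


@dataclass(frozen=True)
class EvalResult:
    precision: float  # percent
    recall: float  # percent
    per_doc: tuple[tuple[str, int, int, int], ...]  # (doc_id, tp, fp, fn)
    averaging: str = "macro"


def identified_descriptor_sets(
    docs: Sequence[CdaDocument],
    keywords_per_doc: Sequence[Sequence[IdentifiedKeyword]],
    include_negated: bool = False,
) -> dict[str, frozenset[str]]:
    """Collapse keyword occurrences to per-document descriptor sets,
    dropping negated mentions unless asked to keep them."""
    out: dict[str, frozenset[str]] = {}
    for doc, kws in zip(docs, keywords_per_doc):
        out[doc.doc_id] = frozenset(
            k.descriptor_id for k in kws if include_negated or not k.negated
        )
    return out


def precision_recall(
    identified: Mapping[str, frozenset[str]],
    gold: Mapping[str, frozenset[str]],
    averaging: str = "macro",
    empty_doc_convention: str = "perfect",
) -> EvalResult:
    """Descriptor-level precision/recall over aligned per-document sets.

    ``averaging='macro'`` (default) is the mean of per-document P and R;
    ``'micro'`` pools tp/fp/fn.  ``empty_doc_convention`` controls documents
    with empty gold and empty identification: ``'perfect'`` scores them
    100/100, ``'exclude'`` drops them from the macro mean.
    """
    if set(identified) != set(gold):
        raise ValueError("identified and gold document id sets must align")
    if averaging not in ("macro", "micro"):
        raise ValueError(f"unknown averaging {averaging!r}")

    per_doc: list[tuple[str, int, int, int]] = []
    for doc_id in sorted(gold):
        ident, g = identified[doc_id], gold[doc_id]
        tp = len(ident & g)
        fp = len(ident - g)
        fn = len(g - ident)
        per_doc.append((doc_id, tp, fp, fn))

    def doc_pr(tp: int, fp: int, fn: int) -> Optional[tuple[float, float]]:
        if tp == fp == fn == 0:
            return None if empty_doc_convention == "exclude" else (100.0, 100.0)
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 100.0
        return (p, r)

    if averaging == "macro":
        prs = [pr for _, tp, fp, fn in per_doc if (pr := doc_pr(tp, fp, fn))]
        if not prs:
            precision = recall = 100.0
        else:
            precision = sum(p for p, _ in prs) / len(prs)
            recall = sum(r for _, r in prs) / len(prs)
    else:
        tp = sum(t for _, t, _, _ in per_doc)
        fp = sum(f for _, _, f, _ in per_doc)
        fn = sum(f for _, _, _, f in per_doc)
        precision = 100.0 * tp / (tp + fp) if tp + fp else 100.0
        recall = 100.0 * tp / (tp + fn) if tp + fn else 100.0

    return EvalResult(
        precision=precision,
        recall=recall,
        per_doc=tuple(per_doc),
        averaging=averaging,
    )


def branch_sweep(
    docs: Sequence[CdaDocument],
    gold: Mapping[str, frozenset[str]],
    thesaurus: MeshThesaurus,
    config: AppConfig,
    branch_configs: Sequence[tuple[str, Union[frozenset[str], str]]],
    averaging: str = "macro",
) -> pd.DataFrame:
    """Evaluate identification under several branch restrictions.

    Each entry of ``branch_configs`` is ``(label, branches)`` where
    ``branches`` is a branch-letter set overriding every rule, or the
    string ``"baseline"`` selecting the all-section all-branch baseline.
    Returns a tidy frame with columns ``config``, ``precision``, ``recall``.
    """
    rows = []
    for label, branches in branch_configs:
        if branches == "baseline":
            per_doc = [identify_baseline(d, thesaurus) for d in docs]
            identified = identified_descriptor_sets(docs, per_doc, include_negated=True)
        else:
            forced = AppConfig(
                rules=tuple(
                    replace(r, branches=frozenset(branches)) for r in config.rules
                ),
                default_branches_when_unset=frozenset(branches),
                disease_branch=config.disease_branch,
            )
            per_doc = [identify_keywords(d, thesaurus, forced) for d in docs]
            identified = identified_descriptor_sets(docs, per_doc)
        res = precision_recall(identified, gold, averaging=averaging)
        rows.append(
            {"config": label, "precision": res.precision, "recall": res.recall}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CurvePoint:
    iteration: int
    query: str
    count: int
    added_descriptor: Optional[str] = None


def reduction_curve(
    doc: CdaDocument,
    disease: MeshDescriptor,
    backend,
    thesaurus: MeshThesaurus,
    config: AppConfig,
    policy: Union[str, Sequence[str]] = "by-span-order",
    stop_count: int = 10,
    max_iterations: int = 10,
) -> list[CurvePoint]:
    """Citation-count trajectory across query iterations.

    Iteration 0 is the disease-only general query; each step AND-adds one
    identified (non-negated, deduplicated) keyword chosen by ``policy``:

    * ``"by-span-order"`` — document order of first occurrence;
    * ``"by-smallest-count"`` — the keyword whose addition leaves the
      smallest non-zero count (smallest overall if all would hit zero);
    * an explicit descriptor-id sequence — a scripted user session.

    Stops when the count reaches ``stop_count`` or below, keywords are
    exhausted, or ``max_iterations`` steps were taken.  Counts are
    non-increasing by AND monotonicity.
    """
    keywords = identify_keywords(doc, thesaurus, config)
    seen: set[str] = set()
    pool: list[str] = []
    for k in keywords:
        if not k.negated and k.descriptor_id not in seen and k.descriptor_id != disease.id:
            seen.add(k.descriptor_id)
            pool.append(k.descriptor_id)

    scripted: Optional[list[str]] = None
    if not isinstance(policy, str):
        scripted = [d for d in policy]
        missing = set(scripted) - set(pool)
        if missing:
            raise ValueError(f"scripted descriptors not identified: {sorted(missing)}")

    query = Query(disease=disease)
    curve = [CurvePoint(0, render_query(query), backend.count(query))]
    while (
        curve[-1].count > stop_count
        and len(curve) - 1 < max_iterations
        and pool
    ):
        if scripted is not None:
            if not scripted:
                break
            chosen = scripted.pop(0)
        elif policy == "by-span-order":
            chosen = pool[0]
        elif policy == "by-smallest-count":
            counts = {
                d: backend.count(add_term(query, thesaurus.descriptors[d]))
                for d in pool
            }
            nonzero = {d: c for d, c in counts.items() if c > 0}
            pick_from = nonzero if nonzero else counts
            chosen = min(pick_from, key=lambda d: (pick_from[d], d))
        else:
            raise ValueError(f"unknown policy {policy!r}")
        pool.remove(chosen)
        query = add_term(query, thesaurus.descriptors[chosen])
        curve.append(
            CurvePoint(
                iteration=len(curve) - 1 + 1,
                query=render_query(query),
                count=backend.count(query),
                added_descriptor=chosen,
            )
        )
    return curve


# ---------------------------------------------------------------------------
# Gold annotation I/O
# ---------------------------------------------------------------------------

def load_gold_tsv(source) -> list[GoldAnnotation]:
    """Gold TSV: ``doc_id, descriptor_id[, section_index]``."""
    own = not hasattr(source, "read")
    fh: IO = open(source, "r", encoding="utf-8") if own else source
    try:
        out: list[GoldAnnotation] = []
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not "".join(row).strip():
                continue
            section = int(row[2]) if len(row) > 2 and row[2] != "" else None
            out.append(GoldAnnotation(row[0], row[1], section))
        return out
    finally:
        if own:
            fh.close()


def save_gold_tsv(annotations: Iterable[GoldAnnotation], dest) -> None:
    own = not hasattr(dest, "write")
    fh: IO = open(dest, "w", encoding="utf-8") if own else dest
    try:
        for a in annotations:
            suffix = "" if a.section_index is None else f"\t{a.section_index}"
            fh.write(f"{a.doc_id}\t{a.descriptor_id}{suffix}\n")
    finally:
        if own:
            fh.close()


def gold_descriptor_sets(
    annotations: Iterable[GoldAnnotation], doc_ids: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Per-document gold descriptor sets covering all ``doc_ids``."""
    out: dict[str, set[str]] = {d: set() for d in doc_ids}
    for a in annotations:
        out.setdefault(a.doc_id, set()).add(a.descriptor_id)
    return {d: frozenset(s) for d, s in out.items()}
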