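"""Boolean query construction, rendering, relatedness and candidate counts.

A query is an ordered conjunction of MeSH term clauses anchored by a
disease descriptor (branch C).  The n-th query — disease plus n selected
keywords — retrieves citations indexed by at least n + 1 of the record's
MeSH terms, because every conjunct must appear in the citation's index
set.  Rendering follows the PubMed ``[mh]`` field syntax::

    (Asthma[mh]) AND (Hypertension[mh]) AND (Diabetes Mellitus, Type 1[mh])

and a clause carrying q selected qualifiers expands to q conjuncts
``(Name/qualifier[mh])``.  The relatedness of a citation to a record is

    Rel = |MeSH(citation) ∩ (MeSH(record) ∪ {disease})|
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

from .configuration import SectionRule
from .keyword_identifier import IdentifiedKeyword
from .mesh_model import MeshDescriptor, MeshThesaurus, Qualifier

__all__ = [
    "QueryClause",
    "Query",
    "QueryError",
    "AdmissibilityError",
    "initial_query",
    "add_term",
    "attach_qualifier",
    "render_query",
    "relevance",
    "annotate_counts",
]


class QueryError(Exception):
    pass


class AdmissibilityError(QueryError):
    """Qualifier not allowable for the descriptor and/or the section rule."""


@dataclass(frozen=True)
class QueryClause:
    descriptor_id: str
    preferred_name: str
    qualifiers: tuple[Qualifier, ...] = ()


@dataclass(frozen=True)
class Query:
    """Immutable query value; ``iteration`` is the number of term clauses."""

    disease: MeshDescriptor
    clauses: tuple[QueryClause, ...] = ()
    strict_disease_branch: bool = True

    def __post_init__(self) -> None:
        if self.strict_disease_branch and "C" not in self.disease.branches:
            raise QueryError(
                f"disease {self.disease.preferred_name!r} has no tree number in "
                "branch C (Diseases)"
            )
        ids = [c.descriptor_id for c in self.clauses]
        if len(ids) != len(set(ids)):
            raise QueryError("clauses must be deduplicated by descriptor")

    @property
    def iteration(self) -> int:
        return len(self.clauses)

    @property
    def descriptor_ids(self) -> frozenset[str]:
        return frozenset(c.descriptor_id for c in self.clauses)


def _as_descriptor(
    term: Union[MeshDescriptor, IdentifiedKeyword], thesaurus: MeshThesaurus | None
) -> MeshDescriptor:
    if isinstance(term, MeshDescriptor):
        return term
    if term.negated:
        raise QueryError(
            f"negated mention of {term.descriptor_id} cannot enter a query"
        )
    if thesaurus is None:
        raise QueryError("a thesaurus is required to resolve an identified keyword")
    return thesaurus.descriptors[term.descriptor_id]


def initial_query(
    disease: MeshDescriptor,
    term: Union[MeshDescriptor, IdentifiedKeyword],
    thesaurus: MeshThesaurus | None = None,
    strict: bool = True,
) -> Query:
    """The first query: ``(term_1[mh]) AND (disease[mh])``."""
    return add_term(
        Query(disease=disease, strict_disease_branch=strict), term, thesaurus
    )


def add_term(
    query: Query,
    term: Union[MeshDescriptor, IdentifiedKeyword],
    thesaurus: MeshThesaurus | None = None,
) -> Query:
    """Return a new query with the term AND-added; duplicate descriptors are
    a no-op.  Negated keywords are rejected."""
    d = _as_descriptor(term, thesaurus)
    if d.id in query.descriptor_ids:
        return query
    clause = QueryClause(descriptor_id=d.id, preferred_name=d.preferred_name)
    return replace(query, clauses=query.clauses + (clause,))


def attach_qualifier(
    query: Query,
    descriptor_id: str,
    qualifier: Qualifier,
    rule: SectionRule | None,
    thesaurus: MeshThesaurus,
) -> Query:
    """Attach a subheading to a clause already in the query.

    Admissible only when the qualifier is allowable for the descriptor AND
    for the originating section's rule (an unset rule admits all).
    Idempotent for an already-attached qualifier.
    """
    if descriptor_id not in query.descriptor_ids:
        raise QueryError(f"descriptor {descriptor_id} is not in the query")
    allowable = thesaurus.descriptors[descriptor_id].allowable_qualifiers
    if qualifier not in allowable:
        raise AdmissibilityError(
            f"{qualifier.abbreviation} is not an allowable qualifier of "
            f"descriptor {descriptor_id}"
        )
    if rule is not None and rule.qualifiers and (
        qualifier.abbreviation not in rule.qualifiers
    ):
        raise AdmissibilityError(
            f"{qualifier.abbreviation} is excluded by the section rule"
        )
    clauses = tuple(
        replace(c, qualifiers=c.qualifiers + (qualifier,))
        if c.descriptor_id == descriptor_id and qualifier not in c.qualifiers
        else c
        for c in query.clauses
    )
    return replace(query, clauses=clauses)


def render_query(query: Query) -> str:
    """Render to the PubMed dialect; deterministic and injective on
    canonical queries.  Zero clauses render the disease-only general query."""
    conjuncts: list[str] = []
    for clause in query.clauses:
        if clause.qualifiers:
            conjuncts.extend(
                f"({clause.preferred_name}/{q.name}[mh])" for q in clause.qualifiers
            )
        else:
            conjuncts.append(f"({clause.preferred_name}[mh])")
    conjuncts.append(f"({query.disease.preferred_name}[mh])")
    return " AND ".join(conjuncts)


def relevance(
    citation_terms: Iterable[str], ehr_terms: Iterable[str], disease_id: str
) -> int:
    """Relatedness degree: size of the intersection between a citation's
    indexing descriptors and the record's terms plus the disease."""
    return len(frozenset(citation_terms) & (frozenset(ehr_terms) | {disease_id}))


def annotate_counts(
    keywords: Sequence[IdentifiedKeyword],
    query: Query,
    backend,
    thesaurus: MeshThesaurus,
) -> list[IdentifiedKeyword]:
    """Fill each keyword's candidate count: the citations retrieved if the
    keyword were AND-added to the current query.

    Negated keywords and keywords already in the query get no count; a
    backend failure marks only the affected keyword count-unavailable
    (``None``).
    """
    out: list[IdentifiedKeyword] = []
    for kw in keywords:
        if kw.negated or kw.descriptor_id in query.descriptor_ids:
            out.append(replace(kw, candidate_count=None))
            continue
        try:
            count = backend.count(add_term(query, kw, thesaurus))
        except Exception:
            out.append(replace(kw, candidate_count=None))
            continue
        out.append(replace(kw, candidate_count=count))
    return out
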