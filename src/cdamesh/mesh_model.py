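"""MeSH thesaurus model and the normalized lookup table used for matching.

The Medical Subject Headings (MeSH) vocabulary is a set of *descriptors*
(main headings), each carrying synonym *entry terms*, one or more *tree
numbers* locating it in the 16-branch MeSH hierarchy, and a list of
*allowable qualifiers* (subheadings such as ``epidemiology``).  Keyword
identification needs fast surface-form lookup, so the thesaurus is compiled
into a hash table mapping normalized entry terms to descriptor ids.

Two on-disk dialects are supported:

* ``mesh-xml`` — the official NLM descriptor XML (``DescriptorRecordSet``),
  year-agnostic;
* ``fixture-tsv`` — a compact tab-separated dialect used for packaged and
  generated fixtures: ``id, preferred_name, entry terms (pipe-joined),
  tree numbers (pipe-joined), qualifier abbreviations (pipe-joined)``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from lxml import etree

__all__ = [
    "BRANCH_LETTERS",
    "QUALIFIER_NAMES",
    "Qualifier",
    "MeshDescriptor",
    "MeshThesaurus",
    "MeshError",
    "MeshParseError",
    "MeshValidationError",
    "normalize_term",
    "load_mesh",
    "save_mesh_tsv",
    "descriptors_in_branches",
    "allowable_qualifiers_for",
]

#: The 16 top-level MeSH tree branches (A=Anatomy ... Z=Geographic Locations).
BRANCH_LETTERS: frozenset[str] = frozenset("ABCDEFGHIJKLMNVZ")

#: Canonical names for the qualifier abbreviations used by fixtures; the
#: official XML loader reads names directly from the file instead.
QUALIFIER_NAMES: Mapping[str, str] = {
    "EP": "epidemiology",
    "DI": "diagnosis",
    "TH": "therapy",
    "DT": "drug therapy",
    "GE": "genetics",
    "CO": "complications",
    "SU": "surgery",
    "PC": "prevention & control",
    "ET": "etiology",
    "ME": "metabolism",
}

_NON_ALNUM = re.compile(r"[^0-9a-z]+")
# Token convention shared with the matcher: words or single punctuation marks.
_RAW_TOKEN = re.compile(r"\w+|[^\w\s]")


class MeshError(Exception):
    """Base class for thesaurus errors."""


class MeshParseError(MeshError):
    """Malformed thesaurus source (carries line/element context)."""


class MeshValidationError(MeshError):
    """Structurally parsed but invalid thesaurus content."""


def normalize_term(text: str) -> str:
    """Normalize a surface form into its lookup key.

    Lower-cases, collapses every run of non-alphanumeric characters
    (whitespace and punctuation alike) to a single space, and strips the
    ends.  Deterministic and idempotent; ``""`` maps to ``""``.

    >>> normalize_term("Bronchial  Asthma,")
    'bronchial asthma'
    """
    return _NON_ALNUM.sub(" ", text.lower()).strip()


@dataclass(frozen=True, order=True)
class Qualifier:
    """A MeSH subheading, e.g. ``epidemiology`` (abbreviation ``EP``)."""

    name: str
    abbreviation: str

    def __post_init__(self) -> None:
        if not self.name:
            raise MeshValidationError("qualifier name must be non-empty")
        if self.abbreviation and not (
            len(self.abbreviation) == 2 and self.abbreviation.isupper()
        ):
            raise MeshValidationError(
                f"qualifier abbreviation must be 2 uppercase chars: {self.abbreviation!r}"
            )


@dataclass(frozen=True)
class MeshDescriptor:
    """A MeSH main heading with its synonyms, tree positions and qualifiers."""

    id: str
    preferred_name: str
    entry_terms: frozenset[str]
    tree_numbers: frozenset[str]
    allowable_qualifiers: frozenset[Qualifier] = frozenset()

    def __post_init__(self) -> None:
        if not self.entry_terms:
            raise MeshValidationError(f"{self.id}: entry_terms must be non-empty")
        if self.preferred_name not in self.entry_terms:
            object.__setattr__(
                self, "entry_terms", self.entry_terms | {self.preferred_name}
            )
        for tn in self.tree_numbers:
            if not tn or tn[0] not in BRANCH_LETTERS:
                raise MeshValidationError(
                    f"{self.id}: tree number {tn!r} does not start with one of "
                    f"the 16 branch letters"
                )

    @property
    def branches(self) -> frozenset[str]:
        return frozenset(tn[0] for tn in self.tree_numbers)


class MeshThesaurus:
    """A compiled thesaurus: descriptors plus the normalized lookup table.

    ``lookup`` maps :func:`normalize_term` of every entry term to the set of
    descriptor ids carrying it (a surface form may be ambiguous);
    ``branch_index`` maps each branch letter to the descriptor ids with at
    least one tree number there; ``max_term_tokens`` is the longest entry
    term measured in matcher tokens, words and punctuation marks alike
    (1 for an empty thesaurus), bounding the n-gram window during matching.
    """

    def __init__(self, descriptors: Iterable[MeshDescriptor]):
        self.descriptors: dict[str, MeshDescriptor] = {}
        for d in descriptors:
            if d.id in self.descriptors:
                raise MeshValidationError(f"duplicate descriptor id {d.id!r}")
            self.descriptors[d.id] = d

        self.lookup: dict[str, frozenset[str]] = {}
        self.branch_index: dict[str, frozenset[str]] = {}
        self.max_term_tokens: int = 1

        lk: dict[str, set[str]] = {}
        bi: dict[str, set[str]] = {}
        for d in self.descriptors.values():
            for term in d.entry_terms:
                key = normalize_term(term)
                if not key:
                    continue
                lk.setdefault(key, set()).add(d.id)
                # window bound measured in matcher tokens, where punctuation
                # inside an entry term ("Diabetes Mellitus, Type 1") counts
                self.max_term_tokens = max(
                    self.max_term_tokens, len(_RAW_TOKEN.findall(term))
                )
            for letter in d.branches:
                bi.setdefault(letter, set()).add(d.id)
        self.lookup = {k: frozenset(v) for k, v in lk.items()}
        self.branch_index = {k: frozenset(v) for k, v in bi.items()}

    @property
    def qualifier_inventory(self) -> frozenset[Qualifier]:
        """Union of the allowable-qualifier sets of all descriptors."""
        out: set[Qualifier] = set()
        for d in self.descriptors.values():
            out |= d.allowable_qualifiers
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeshThesaurus):
            return NotImplemented
        return self.descriptors == other.descriptors

    def __len__(self) -> int:
        return len(self.descriptors)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.descriptors

    def __repr__(self) -> str:
        return f"MeshThesaurus({len(self.descriptors)} descriptors)"


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

def _open(source: str | Path | IO) -> IO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source, "r", encoding="utf-8")


def _qualifier_from_abbrev(abbrev: str) -> Qualifier:
    name = QUALIFIER_NAMES.get(abbrev, abbrev.lower())
    return Qualifier(name=name, abbreviation=abbrev)


def load_mesh(source: str | Path | IO, dialect: str = "fixture-tsv") -> MeshThesaurus:
    """Load a thesaurus from ``mesh-xml`` (official NLM) or ``fixture-tsv``.

    Raises :class:`MeshParseError` naming the offending line/element on
    malformed input and :class:`MeshValidationError` on duplicate ids.
    """
    if dialect == "fixture-tsv":
        return _load_fixture_tsv(source)
    if dialect == "mesh-xml":
        return _load_mesh_xml(source)
    raise ValueError(f"unknown MeSH dialect {dialect!r}")


def _load_fixture_tsv(source: str | Path | IO) -> MeshThesaurus:
    fh = _open(source)
    descriptors: list[MeshDescriptor] = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise MeshParseError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}"
            )
        uid, name, terms, trees, quals = parts
        if not uid or not name:
            raise MeshParseError(f"line {lineno}: empty id or preferred name")
        try:
            descriptors.append(
                MeshDescriptor(
                    id=uid,
                    preferred_name=name,
                    entry_terms=frozenset(t for t in terms.split("|") if t),
                    tree_numbers=frozenset(t for t in trees.split("|") if t),
                    allowable_qualifiers=frozenset(
                        _qualifier_from_abbrev(q) for q in quals.split("|") if q
                    ),
                )
            )
        except MeshValidationError as exc:
            raise MeshParseError(f"line {lineno}: {exc}") from exc
    return MeshThesaurus(descriptors)


def _load_mesh_xml(source: str | Path | IO) -> MeshThesaurus:
    """Parse the official NLM descriptor XML (DescriptorRecordSet).

    Year-agnostic: only stable elements are read (DescriptorUI,
    DescriptorName, ConceptList term strings, TreeNumberList,
    AllowableQualifiersList).
    """
    try:
        tree = etree.parse(source if hasattr(source, "read") else str(source))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MeshParseError(f"cannot parse MeSH XML: {exc}") from exc

    descriptors: list[MeshDescriptor] = []
    for rec in tree.iter("DescriptorRecord"):
        uid = rec.findtext("DescriptorUI")
        name = rec.findtext("DescriptorName/String")
        if not uid or not name:
            raise MeshParseError(
                f"DescriptorRecord at line {rec.sourceline}: missing UI or name"
            )
        terms = {t.text for t in rec.iter("String") if t.text} | {name}
        trees = {t.text for t in rec.iter("TreeNumber") if t.text}
        quals: set[Qualifier] = set()
        for aq in rec.iter("AllowableQualifier"):
            qname = aq.findtext("QualifierReferredTo/QualifierName/String")
            abbr = aq.findtext("Abbreviation")
            if qname and abbr:
                quals.add(Qualifier(name=qname, abbreviation=abbr.strip().upper()))
        descriptors.append(
            MeshDescriptor(
                id=uid,
                preferred_name=name,
                entry_terms=frozenset(terms),
                tree_numbers=frozenset(trees),
                allowable_qualifiers=frozenset(quals),
            )
        )
    return MeshThesaurus(descriptors)


def save_mesh_tsv(thesaurus: MeshThesaurus, dest: str | Path | IO) -> None:
    """Write the fixture-TSV dialect (UTF-8, no header, sorted by id)."""
    own = not hasattr(dest, "write")
    fh: IO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for uid in sorted(thesaurus.descriptors):
            d = thesaurus.descriptors[uid]
            fh.write(
                "\t".join(
                    [
                        d.id,
                        d.preferred_name,
                        "|".join(sorted(d.entry_terms)),
                        "|".join(sorted(d.tree_numbers)),
                        "|".join(sorted(q.abbreviation for q in d.allowable_qualifiers)),
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def mesh_to_tsv_string(thesaurus: MeshThesaurus) -> str:
    buf = io.StringIO()
    save_mesh_tsv(thesaurus, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Branch / qualifier queries
# ---------------------------------------------------------------------------

def descriptors_in_branches(
    thesaurus: MeshThesaurus, branches: Iterable[str]
) -> frozenset[str]:
    """Descriptor ids with at least one tree number in any of ``branches``.

    Monotone in ``branches``; invalid letters raise
    :class:`MeshValidationError`.
    """
    branch_set = frozenset(branches)
    bad = branch_set - BRANCH_LETTERS
    if bad:
        raise MeshValidationError(f"invalid branch letter(s): {sorted(bad)}")
    out: set[str] = set()
    for letter in branch_set:
        out |= thesaurus.branch_index.get(letter, frozenset())
    return frozenset(out)


def allowable_qualifiers_for(
    thesaurus: MeshThesaurus, descriptor_id: str
) -> frozenset[Qualifier]:
    """The allowable-qualifier set of one descriptor (possibly empty)."""
    try:
        return thesaurus.descriptors[descriptor_id].allowable_qualifiers
    except KeyError:
        raise KeyError(f"unknown descriptor id {descriptor_id!r}") from None
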