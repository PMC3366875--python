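"""Dictionary-based MeSH keyword identification in CDA narratives.

For each document section that a configuration rule declares relevant, the
narrative is split into sentences and tokens, consecutive-token windows are
looked up in the thesaurus hash table restricted to the section's tree
branches (greedy longest match, left to right, never crossing a sentence
boundary), and mentions preceded by a negation trigger within a small
window are flagged.  Negated mentions stay in the output for display but
are excluded from query candidacy.

A baseline mode identifies every MeSH occurrence — all sections, all 16
branches, negated mentions retained — for evaluation comparisons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import IO, Iterable, Optional, Sequence

from .cda_reader import CdaDocument
from .configuration import (
    AppConfig,
    effective_branches,
    effective_qualifiers,
    resolve_section,
)
from .mesh_model import (
    BRANCH_LETTERS,
    MeshThesaurus,
    Qualifier,
    descriptors_in_branches,
    normalize_term,
)

__all__ = [
    "TokenSpan",
    "IdentifiedKeyword",
    "NEGATION_LEXICON",
    "DEFAULT_NEGATION_WINDOW",
    "split_sentences",
    "tokenize",
    "match_terms",
    "is_negated",
    "identify_keywords",
    "identify_baseline",
    "write_standoff",
]

#: Trigger words marking the following mention as negated.
NEGATION_LEXICON: frozenset[str] = frozenset(
    {"no", "not", "denies", "denied", "without", "negative", "absent", "non"}
)
#: Tokens inspected immediately before a match, within its sentence.
DEFAULT_NEGATION_WINDOW = 3

# A sentence ends at ., ! or ? followed by whitespace (or end of text).
_SENT_BOUNDARY = re.compile(r"[.!?]+(?:\s+|$)")
# Word tokens, or single punctuation marks (which never match terms).
_TOKEN = re.compile(r"\w+|[^\w\s]")


@dataclass(frozen=True)
class TokenSpan:
    """A token or sentence span with 0-based half-open character offsets
    into the section text."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class IdentifiedKeyword:
    """One matched MeSH concept occurrence in a document section."""

    descriptor_id: str
    surface: str
    section_index: int
    span: TokenSpan
    negated: bool = False
    candidate_qualifiers: frozenset[Qualifier] = frozenset()
    candidate_count: Optional[int] = None


def split_sentences(text: str) -> list[TokenSpan]:
    """Sentence spans: non-overlapping, ordered, covering all non-blank text."""
    spans: list[TokenSpan] = []
    pos = 0
    for m in _SENT_BOUNDARY.finditer(text):
        chunk = text[pos : m.end()]
        stripped = chunk.strip()
        if stripped:
            lead = len(chunk) - len(chunk.lstrip())
            start = pos + lead
            spans.append(TokenSpan(text=stripped, start=start, end=start + len(stripped)))
        pos = m.end()
    tail = text[pos:].strip()
    if tail:
        lead = len(text[pos:]) - len(text[pos:].lstrip())
        start = pos + lead
        spans.append(TokenSpan(text=tail, start=start, end=start + len(tail)))
    return spans


def tokenize(sentence: TokenSpan) -> list[TokenSpan]:
    """Word and punctuation tokens with document-level offsets."""
    return [
        TokenSpan(
            text=m.group(), start=sentence.start + m.start(), end=sentence.start + m.end()
        )
        for m in _TOKEN.finditer(sentence.text)
    ]


def match_terms(
    tokens: Sequence[TokenSpan],
    thesaurus: MeshThesaurus,
    allowed: frozenset[str],
    max_len: int | None = None,
) -> list[tuple[str, TokenSpan]]:
    """Greedy longest-match dictionary scan over one sentence's tokens.

    At each position, windows of ``max_len`` down to 1 tokens are joined,
    normalized and looked up; the first (longest) hit whose descriptor set
    intersects ``allowed`` emits one ``(descriptor_id, span)`` per
    intersecting descriptor, and scanning resumes past the window.
    Windows starting or ending on a punctuation token never match.
    """
    if max_len is None:
        max_len = thesaurus.max_term_tokens
    matches: list[tuple[str, TokenSpan]] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit_len = 0
        hit_ids: frozenset[str] = frozenset()
        for length in range(min(max_len, n - i), 0, -1):
            window = tokens[i : i + length]
            if not normalize_term(window[0].text) or not normalize_term(
                window[-1].text
            ):
                continue
            key = normalize_term(" ".join(t.text for t in window))
            ids = thesaurus.lookup.get(key, frozenset()) & allowed
            if ids:
                hit_len, hit_ids = length, ids
                break
        if hit_len:
            span = TokenSpan(
                text=" ".join(t.text for t in tokens[i : i + hit_len]),
                start=tokens[i].start,
                end=tokens[i + hit_len - 1].end,
            )
            for did in sorted(hit_ids):
                matches.append((did, span))
            i += hit_len
        else:
            i += 1
    return matches


def is_negated(
    tokens: Sequence[TokenSpan],
    match_span: TokenSpan,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> bool:
    """True iff a negation trigger occurs among the ``window`` tokens
    immediately preceding the match within the same sentence."""
    if window < 1:
        raise ValueError("negation window must be >= 1")
    preceding = [t for t in tokens if t.end <= match_span.start]
    return any(
        normalize_term(t.text) in NEGATION_LEXICON for t in preceding[-window:]
    )


def _scan_section(
    text: str,
    section_index: int,
    thesaurus: MeshThesaurus,
    allowed: frozenset[str],
    candidate_qualifiers,
    negation_window: int,
) -> list[IdentifiedKeyword]:
    out: list[IdentifiedKeyword] = []
    for sentence in split_sentences(text):
        tokens = tokenize(sentence)
        for did, span in match_terms(tokens, thesaurus, allowed):
            out.append(
                IdentifiedKeyword(
                    descriptor_id=did,
                    surface=text[span.start : span.end],
                    section_index=section_index,
                    span=span,
                    negated=is_negated(tokens, span, negation_window),
                    candidate_qualifiers=candidate_qualifiers(did),
                )
            )
    return out


def identify_keywords(
    doc: CdaDocument,
    thesaurus: MeshThesaurus,
    config: AppConfig,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> list[IdentifiedKeyword]:
    """The configured identification pipeline.

    Sections without a matching rule are skipped; matched sections restrict
    the dictionary to the rule's effective branches; candidate qualifiers
    are the intersection of the descriptor's allowable qualifiers with the
    rule's effective qualifiers.  Output ordered by (section, offset).
    """
    keywords: list[IdentifiedKeyword] = []
    for section in doc.sections:
        rule = resolve_section(section, config)
        if rule is None:
            continue
        allowed = descriptors_in_branches(thesaurus, effective_branches(rule, config))
        section_quals = effective_qualifiers(rule, thesaurus)

        def quals_for(did: str) -> frozenset[Qualifier]:
            return thesaurus.descriptors[did].allowable_qualifiers & section_quals

        keywords.extend(
            _scan_section(
                section.text,
                section.order_index,
                thesaurus,
                allowed,
                quals_for,
                negation_window,
            )
        )
    keywords.sort(key=lambda k: (k.section_index, k.span.start, k.descriptor_id))
    return keywords


def identify_baseline(
    doc: CdaDocument,
    thesaurus: MeshThesaurus,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> list[IdentifiedKeyword]:
    """Baseline: every section, all 16 branches, negation flagged but not
    used to exclude anything.  A concept superset of the configured mode."""
    allowed = descriptors_in_branches(thesaurus, BRANCH_LETTERS)
    keywords: list[IdentifiedKeyword] = []
    for section in doc.sections:
        keywords.extend(
            _scan_section(
                section.text,
                section.order_index,
                thesaurus,
                allowed,
                lambda did: thesaurus.descriptors[did].allowable_qualifiers,
                negation_window,
            )
        )
    keywords.sort(key=lambda k: (k.section_index, k.span.start, k.descriptor_id))
    return keywords


def write_standoff(
    doc_id: str, keywords: Iterable[IdentifiedKeyword], dest: IO
) -> None:
    """Standoff TSV: doc_id, section_index, start, end, descriptor_id, negated."""
    for k in keywords:
        dest.write(
            f"{doc_id}\t{k.section_index}\t{k.span.start}\t{k.span.end}"
            f"\t{k.descriptor_id}\t{int(k.negated)}\n"
        )
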