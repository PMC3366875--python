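"""Independent brute-force oracles the implementation is checked against.

These deliberately re-derive the matching and filtering semantics from
first principles (exhaustive n-gram enumeration, per-descriptor branch
scans, standalone negation filter) instead of calling the library's
matcher, so agreement is meaningful.
"""

from __future__ import annotations

from cdamesh import normalize_term, split_sentences, tokenize
from cdamesh.configuration import (
    effective_branches,
    effective_qualifiers,
    resolve_section,
)
from cdamesh.keyword_identifier import NEGATION_LEXICON


def brute_force_allowed(thesaurus, branches) -> frozenset[str]:
    """Branch filter re-derived by scanning every descriptor's tree numbers."""
    return frozenset(
        uid
        for uid, d in thesaurus.descriptors.items()
        if any(tn[0] in branches for tn in d.tree_numbers)
    )


def brute_force_matches(text, thesaurus, allowed):
    """All-n-gram scan + longest-match pruning over one section text.

    Returns [(descriptor_id, (start, end))] in scan order.
    """
    results = []
    for sent in split_sentences(text):
        tokens = tokenize(sent)
        hits = {}  # start index -> (length, ids) keeping the longest
        for i in range(len(tokens)):
            for length in range(1, thesaurus.max_term_tokens + 1):
                if i + length > len(tokens):
                    break
                window = tokens[i : i + length]
                if not normalize_term(window[0].text) or not normalize_term(
                    window[-1].text
                ):
                    continue
                key = normalize_term(" ".join(t.text for t in window))
                ids = thesaurus.lookup.get(key, frozenset()) & allowed
                if ids and (i not in hits or length > hits[i][0]):
                    hits[i] = (length, ids)
        pos = 0
        while pos < len(tokens):
            if pos in hits:
                length, ids = hits[pos]
                span = (tokens[pos].start, tokens[pos + length - 1].end)
                for did in sorted(ids):
                    results.append((did, span))
                pos += length
            else:
                pos += 1
    return results


def brute_force_negated(text, start, window=3) -> bool:
    """Standalone negation filter: re-tokenize the sentence containing the
    offset and inspect the preceding window."""
    for sent in split_sentences(text):
        if sent.start <= start < sent.end:
            tokens = [t for t in tokenize(sent) if t.end <= start]
            return any(
                normalize_term(t.text) in NEGATION_LEXICON
                for t in tokens[-window:]
            )
    return False


def oracle_identify(doc, thesaurus, config, window=3):
    """Composition of the independent filters: section relevance, branch
    restriction, n-gram matching, negation.

    Returns [(section_index, descriptor_id, start, end, negated)] sorted.
    """
    out = []
    for section in doc.sections:
        rule = resolve_section(section, config)
        if rule is None:
            continue
        allowed = brute_force_allowed(thesaurus, effective_branches(rule, config))
        for did, (start, end) in brute_force_matches(section.text, thesaurus, allowed):
            out.append(
                (
                    section.order_index,
                    did,
                    start,
                    end,
                    brute_force_negated(section.text, start, window),
                )
            )
    out.sort(key=lambda r: (r[0], r[2], r[1]))
    return out


def brute_force_corpus_count(corpus, clause_pairs) -> int:
    """Citations whose index sets satisfy every (descriptor, qualifiers)
    clause, evaluated per citation from the raw pair sets."""
    n = 0
    for c in corpus:
        ok = True
        for did, quals in clause_pairs:
            if quals:
                if any((did, q) not in c.index_terms for q in quals):
                    ok = False
                    break
            elif did not in {d for d, _ in c.index_terms}:
                ok = False
                break
        if ok:
            n += 1
    return n
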