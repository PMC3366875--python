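"""Citation retrieval backends: local corpus, cache, optional live client.

The local backend evaluates the Boolean query semantics exactly over an
in-memory corpus of MeSH-indexed citations and is the deterministic test
oracle target.  A citation matches a query iff, for every clause, the
clause descriptor appears in its index set — and, when the clause carries
qualifiers, each (descriptor, qualifier) pair appears.  The disease clause
is treated identically.  Optional *explosion* makes a descriptor also match
its tree descendants, as live PubMed ``[mh]`` does; it is off by default
because the n+1 relatedness guarantee holds only without it.

The live client speaks NCBI E-utilities ESearch (count-only via
``retmax=0``) through Bio.Entrez, behind a query cache and a rate limiter
defaulting to 1,000 requests per minute.
"""

from __future__ import annotations

import csv
import datetime as _dt
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional

from lxml import etree

from .mesh_model import MeshThesaurus
from .query_engine import Query, render_query

__all__ = [
    "Citation",
    "Corpus",
    "CorpusError",
    "LocalBackend",
    "QueryCache",
    "CachedBackend",
    "RateLimiter",
    "EntrezBackend",
    "DEFAULT_RATE_LIMIT_PER_MINUTE",
    "load_corpus",
    "save_corpus_tsv",
]

#: Default request budget for the live client (requests per minute).
DEFAULT_RATE_LIMIT_PER_MINUTE = 1000


class CorpusError(Exception):
    pass


@dataclass(frozen=True)
class Citation:
    """A literature record carrying its MeSH index terms as
    (descriptor_id, qualifier_abbreviation_or_None) pairs."""

    citation_id: str
    title: str
    index_terms: frozenset[tuple[str, Optional[str]]]
    date: _dt.date

    def __post_init__(self) -> None:
        if not self.index_terms:
            raise CorpusError(f"{self.citation_id}: index_terms must be non-empty")

    @property
    def descriptor_ids(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.index_terms)


class Corpus:
    def __init__(self, citations: Iterable[Citation]):
        self.citations: dict[str, Citation] = {}
        for c in citations:
            if c.citation_id in self.citations:
                raise CorpusError(f"duplicate citation id {c.citation_id!r}")
            self.citations[c.citation_id] = c

    def __len__(self) -> int:
        return len(self.citations)

    def __iter__(self):
        return iter(self.citations.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.citations == other.citations


# ---------------------------------------------------------------------------
# Local backend
# ---------------------------------------------------------------------------

class LocalBackend:
    """Pure-function evaluation of queries over a local corpus.

    With ``explode=True`` a thesaurus must be supplied; a clause descriptor
    then also matches any descriptor whose tree number extends one of its
    own (dot-prefix descent).
    """

    def __init__(
        self,
        corpus: Corpus,
        thesaurus: MeshThesaurus | None = None,
        explode: bool = False,
    ):
        if explode and thesaurus is None:
            raise ValueError("explosion requires a thesaurus")
        self.corpus = corpus
        self.thesaurus = thesaurus
        self.explode = explode

    def _expansion(self, descriptor_id: str) -> frozenset[str]:
        if not self.explode:
            return frozenset({descriptor_id})
        assert self.thesaurus is not None
        roots = self.thesaurus.descriptors[descriptor_id].tree_numbers
        out = {descriptor_id}
        for d in self.thesaurus.descriptors.values():
            for tn in d.tree_numbers:
                if any(tn == r or tn.startswith(r + ".") for r in roots):
                    out.add(d.id)
                    break
        return frozenset(out)

    def _clause_matches(
        self, citation: Citation, descriptor_id: str, qualifiers
    ) -> bool:
        ids = self._expansion(descriptor_id)
        if not qualifiers:
            return bool(ids & citation.descriptor_ids)
        return all(
            any((d, q.abbreviation) in citation.index_terms for d in ids)
            for q in qualifiers
        )

    def matches(self, query: Query, citation: Citation) -> bool:
        for clause in query.clauses:
            if not self._clause_matches(citation, clause.descriptor_id, clause.qualifiers):
                return False
        return self._clause_matches(citation, query.disease.id, ())

    def search(self, query: Query) -> list[Citation]:
        """Matching citations, newest first then by id (PubMed date order)."""
        hits = [c for c in self.corpus if self.matches(query, c)]
        hits.sort(key=lambda c: (c.date, c.citation_id))
        hits.reverse()
        return hits

    def count(self, query: Query) -> int:
        return sum(1 for c in self.corpus if self.matches(query, c))


# ---------------------------------------------------------------------------
# Cache
# ---------------------------------------------------------------------------

@dataclass
class QueryCache:
    """Query-string-keyed history of (count, citation ids, timestamp)."""

    entries: dict[str, tuple[int, tuple[str, ...], float]] = field(default_factory=dict)
    ttl_seconds: Optional[float] = None

    def get(self, key: str) -> Optional[tuple[int, tuple[str, ...], float]]:
        hit = self.entries.get(key)
        if hit is None:
            return None
        if self.ttl_seconds is not None and time.time() - hit[2] > self.ttl_seconds:
            del self.entries[key]
            return None
        return hit

    def put(self, key: str, count: int, ids: Iterable[str]) -> None:
        self.entries[key] = (count, tuple(ids), time.time())


class CachedBackend:
    """Transparent cache wrapper: results equal the wrapped backend's."""

    def __init__(self, backend, cache: QueryCache | None = None):
        self.backend = backend
        self.cache = cache if cache is not None else QueryCache()
        self.backend_calls = 0

    def count(self, query: Query) -> int:
        key = render_query(query)
        hit = self.cache.get(key)
        if hit is not None:
            return hit[0]
        self.backend_calls += 1
        if hasattr(self.backend, "search"):
            results = self.backend.search(query)
            self.cache.put(key, len(results), (c.citation_id for c in results))
            return len(results)
        count = self.backend.count(query)
        self.cache.put(key, count, ())
        return count

    def search(self, query: Query) -> list[Citation]:
        self.count(query)  # ensure cached
        key = render_query(query)
        ids = self.cache.get(key)[1]  # type: ignore[index]
        return [self.backend.corpus.citations[i] for i in ids]


# ---------------------------------------------------------------------------
# Live E-utilities client (optional; never used by the test suite)
# ---------------------------------------------------------------------------

class RateLimiter:
    """Token-style limiter: at most ``per_minute`` acquisitions in any
    sliding 60-second window; blocks (or raises) when exhausted."""

    def __init__(self, per_minute: int = DEFAULT_RATE_LIMIT_PER_MINUTE,
                 block: bool = True):
        if per_minute < 1:
            raise ValueError("rate limit must be >= 1/minute")
        self.per_minute = per_minute
        self.block = block
        self._stamps: list[float] = []

    def acquire(self) -> None:
        now = time.monotonic()
        self._stamps = [t for t in self._stamps if now - t < 60.0]
        if len(self._stamps) >= self.per_minute:
            if not self.block:
                raise RuntimeError("rate limit exhausted")
            wait = 60.0 - (now - self._stamps[0])
            time.sleep(max(wait, 0.0))
            return self.acquire()
        self._stamps.append(now)


class EntrezBackend:
    """Count-only PubMed client via Bio.Entrez ESearch (``retmax=0``).

    Responses are cached on the rendered query string; all calls pass
    through the rate limiter.  Network access is entirely optional — the
    import of Bio.Entrez is deferred to the first call.
    """

    def __init__(
        self,
        email: str,
        tool: str = "cdamesh",
        rate_limit_per_minute: int = DEFAULT_RATE_LIMIT_PER_MINUTE,
        cache: QueryCache | None = None,
    ):
        self.email = email
        self.tool = tool
        self.rate_limiter = RateLimiter(per_minute=rate_limit_per_minute)
        self.cache = cache if cache is not None else QueryCache(ttl_seconds=86400.0)
        self.call_log: list[str] = []

    def count(self, query: Query) -> int:
        key = render_query(query)
        hit = self.cache.get(key)
        if hit is not None:
            return hit[0]
        from Bio import Entrez  # deferred: live use only

        Entrez.email = self.email
        Entrez.tool = self.tool
        self.rate_limiter.acquire()
        self.call_log.append(key)
        handle = Entrez.esearch(db="pubmed", term=key, retmax=0)
        try:
            record = Entrez.read(handle)
        finally:
            handle.close()
        count = int(record["Count"])
        self.cache.put(key, count, ())
        return count


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------

def _parse_terms(blob: str) -> frozenset[tuple[str, Optional[str]]]:
    terms: set[tuple[str, Optional[str]]] = set()
    for item in blob.split("|"):
        item = item.strip()
        if not item:
            continue
        if "/" in item:
            d, q = item.split("/", 1)
            terms.add((d, q))
        else:
            terms.add((item, None))
    return frozenset(terms)


def load_corpus(source: str | Path | IO, dialect: str = "fixture-tsv") -> Corpus:
    """Load citations from the fixture TSV (``id, title, date,
    pipe-joined descriptor[/qualifier]``) or a MEDLINE XML subset
    (PubmedArticle → PMID, ArticleTitle, MeshHeadingList)."""
    if dialect == "fixture-tsv":
        return _load_corpus_tsv(source)
    if dialect == "medline-xml":
        return _load_corpus_medline(source)
    raise ValueError(f"unknown corpus dialect {dialect!r}")


def _load_corpus_tsv(source: str | Path | IO) -> Corpus:
    own = not hasattr(source, "read")
    fh: IO = open(source, "r", encoding="utf-8") if own else source  # type: ignore[assignment]
    try:
        citations: list[Citation] = []
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) != 4:
                raise CorpusError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(row)}"
                )
            cid, title, date_s, terms = row
            citations.append(
                Citation(
                    citation_id=cid,
                    title=title,
                    index_terms=_parse_terms(terms),
                    date=_dt.date.fromisoformat(date_s),
                )
            )
        return Corpus(citations)
    finally:
        if own:
            fh.close()


def _load_corpus_medline(source: str | Path | IO) -> Corpus:
    tree = etree.parse(source if hasattr(source, "read") else str(source))
    citations: list[Citation] = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID") or ""
        title = art.findtext(".//ArticleTitle") or ""
        date_s = art.findtext(".//DateCompleted/Year") or "1900"
        terms: set[tuple[str, Optional[str]]] = set()
        for mh in art.iter("MeshHeading"):
            dn = mh.find("DescriptorName")
            if dn is None:
                continue
            did = dn.get("UI") or (dn.text or "")
            qn = mh.find("QualifierName")
            if qn is not None:
                terms.add((did, qn.get("UI") or (qn.text or "")))
            terms.add((did, None))
        citations.append(
            Citation(
                citation_id=pmid,
                title=title,
                index_terms=frozenset(terms),
                date=_dt.date(int(date_s), 1, 1),
            )
        )
    return Corpus(citations)


def save_corpus_tsv(corpus: Corpus, dest: str | Path | IO) -> None:
    own = not hasattr(dest, "write")
    fh: IO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for cid in sorted(corpus.citations):
            c = corpus.citations[cid]
            terms = "|".join(
                sorted(f"{d}/{q}" if q else d for d, q in c.index_terms)
            )
            fh.write(f"{c.citation_id}\t{c.title}\t{c.date.isoformat()}\t{terms}\n")
    finally:
        if own:
            fh.close()
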