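"""Citation counting backends: a local boolean engine and the NCBI E-utilities.

The local engine indexes a citation corpus (positional phrase postings over
case-folded tokens, per-descriptor indexing sets, major-topic sets, subset
membership) and evaluates query ASTs with documented semantics:

* ``[tiab]`` phrase clauses match citations whose token stream contains the
  phrase's tokens contiguously in order; tokenization case-folds and splits
  on any non-alphanumeric character, so ``adult-onset diabetes`` and
  ``adult onset diabetes`` are equivalent;
* ``[mh]`` matches citations indexed with the descriptor or any descendant
  (tree explosion, as in PubMed's default); ``[mesh:noexp]`` matches the
  descriptor only; ``[majr]`` matches the exploded set restricted to
  major-topic assignments;
* ``medline[sb]`` matches citations in the MEDLINE-indexed subset;
* AND/OR are set intersection/union, and the count is the final cardinality.

The live backend issues count-only ``esearch`` requests, honours NCBI rate
limits, retries transient failures with exponential backoff, and caches
every (query, count) pair in an append-only TSV so interrupted runs resume
without re-querying.
"""

from __future__ import annotations

import json
import logging
import re
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from lxml import etree

from meshexpand.metrics import CountTriple
from meshexpand.queries import (
    BoolClause,
    Field,
    QueryNode,
    QuerySet,
    Strategy,
    TermClause,
    render,
)
from meshexpand.vocabulary import Vocabulary, descendants

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Case-fold and split on any non-alphanumeric run, dropping empties."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


@dataclass(frozen=True)
class Citation:
    """One corpus record: title+abstract text, index terms, subset membership.

    ``index_terms`` holds (descriptor id, major_topic) pairs; ``in_subset``
    is the MEDLINE-indexed analogue of ``medline[sb]``.
    """

    citation_id: str
    text: str = ""
    index_terms: frozenset[tuple[str, bool]] = frozenset()
    in_subset: bool = True

    def __post_init__(self) -> None:
        if not self.citation_id:
            raise ValueError("citation_id must be nonempty")
        object.__setattr__(self, "index_terms", frozenset(self.index_terms))


class CorpusIndex:
    """Inverted indexes over a citation corpus, bound to a vocabulary."""

    def __init__(self, vocabulary: Vocabulary) -> None:
        self.vocabulary = vocabulary
        #: token -> citation id -> sorted positions
        self.postings: dict[str, dict[str, list[int]]] = {}
        #: descriptor id -> citation ids indexed with it
        self.mh_index: dict[str, set[str]] = {}
        #: descriptor id -> citation ids where it is a major topic
        self.majr_index: dict[str, set[str]] = {}
        self.subset_ids: set[str] = set()
        self.all_ids: set[str] = set()
        self._descendants_cache: dict[str, set[str]] = {}

    def add(self, citation: Citation) -> None:
        if citation.citation_id in self.all_ids:
            raise ValueError(f"duplicate citation id {citation.citation_id!r}")
        cid = citation.citation_id
        self.all_ids.add(cid)
        if citation.in_subset:
            self.subset_ids.add(cid)
        for pos, token in enumerate(tokenize(citation.text)):
            self.postings.setdefault(token, {}).setdefault(cid, []).append(pos)
        for did, major in citation.index_terms:
            self.mh_index.setdefault(did, set()).add(cid)
            if major:
                self.majr_index.setdefault(did, set()).add(cid)

    def exploded(self, descriptor_id: str) -> set[str]:
        """Descriptor plus tree descendants, cached per index."""
        cached = self._descendants_cache.get(descriptor_id)
        if cached is None:
            cached = descendants(self.vocabulary, descriptor_id)
            self._descendants_cache[descriptor_id] = cached
        return cached


def index_corpus(citations: Iterable[Citation], vocabulary: Vocabulary) -> CorpusIndex:
    """Build a :class:`CorpusIndex`; citation ids must be unique."""
    index = CorpusIndex(vocabulary)
    for citation in citations:
        index.add(citation)
    return index


def _phrase_match(index: CorpusIndex, tokens: Sequence[str]) -> set[str]:
    postings = [index.postings.get(t) for t in tokens]
    if any(p is None for p in postings):
        return set()
    first = postings[0]
    rest = [(i, {cid: set(pos) for cid, pos in p.items()}) for i, p in enumerate(postings[1:], 1)]
    out = set()
    for cid, positions in first.items():
        if all(cid in p for _, p in rest):
            for start in positions:
                if all(start + offset in p[cid] for offset, p in rest):
                    out.add(cid)
                    break
    return out


def _resolve_descriptor(index: CorpusIndex, clause: TermClause) -> str | None:
    if clause.descriptor_id is not None:
        return clause.descriptor_id
    for did, d in index.vocabulary.descriptors.items():
        if d.preferred_term.strip().lower() == clause.text:
            return did
    return None


def _eval(index: CorpusIndex, node: QueryNode) -> set[str]:
    if isinstance(node, TermClause):
        if node.field == Field.TIAB:
            tokens = tokenize(node.text)
            if not tokens:
                logger.warning("phrase %r has no tokens; clause matches nothing", node.text)
                return set()
            return _phrase_match(index, tokens)
        if node.field == Field.SB:
            return set(index.subset_ids)
        did = _resolve_descriptor(index, node)
        if did is None or did not in index.vocabulary.descriptors:
            logger.warning("MH clause %r resolves to no descriptor", node.text)
            return set()
        if node.field == Field.MH_NOEXP:
            return set(index.mh_index.get(did, set()))
        if node.field == Field.MH:
            out: set[str] = set()
            for member in index.exploded(did):
                out |= index.mh_index.get(member, set())
            return out
        if node.field == Field.MAJR:
            out = set()
            for member in index.exploded(did):
                out |= index.majr_index.get(member, set())
            return out
        raise ValueError(f"unsupported field {node.field}")
    sets = [_eval(index, child) for child in node.children]
    out = sets[0]
    for s in sets[1:]:
        out = out & s if node.op == "AND" else out | s
    return out


def match_set(index: CorpusIndex, query: QueryNode) -> set[str]:
    """Citation ids matching a query AST under the local semantics."""
    return _eval(index, query)


def count_local(index: CorpusIndex, query: QueryNode) -> int:
    """Cardinality of the query's match set."""
    return len(_eval(index, query))


# ---------------------------------------------------------------------------
# backends


class LocalBackend:
    """Count queries against a :class:`CorpusIndex`.

    ``restrict_gold_to_subset`` (default on) intersects the gold-standard
    set A with the indexed subset before counting, so that C <= A and
    recall <= 1 hold even though the A query itself carries no subset
    clause.
    """

    def __init__(self, index: CorpusIndex, restrict_gold_to_subset: bool = True) -> None:
        self.index = index
        self.restrict_gold_to_subset = restrict_gold_to_subset
        self.queries_issued = 0

    def count(self, query: QueryNode, as_gold: bool = False) -> int:
        self.queries_issued += 1
        matched = _eval(self.index, query)
        if as_gold and self.restrict_gold_to_subset:
            matched &= self.index.subset_ids
        return len(matched)


@dataclass
class BackendConfig:
    """Settings for the live E-utilities backend.

    Rate limits default to NCBI policy: 3 requests/second without an API
    key, 10 with one.
    """

    base_url: str = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    api_key: str | None = None
    max_requests_per_second: float | None = None
    max_retries: int = 3
    backoff_seconds: float = 1.0
    use_post: bool = True
    cache_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.max_requests_per_second is None:
            self.max_requests_per_second = 10.0 if self.api_key else 3.0
        if self.max_requests_per_second <= 0:
            raise ValueError("max_requests_per_second must be > 0")


#: transport signature: (url, form fields) -> response body bytes
Transport = Callable[[str, dict[str, str]], bytes]


def _urllib_transport(url: str, params: dict[str, str]) -> bytes:
    data = urllib.parse.urlencode(params).encode("ascii")
    try:
        with urllib.request.urlopen(urllib.request.Request(url, data=data)) as resp:
            return resp.read()
    except urllib.error.HTTPError as exc:
        if exc.code == 429 or exc.code >= 500:
            raise TransientBackendError(f"HTTP {exc.code}") from exc
        raise
    except urllib.error.URLError as exc:
        raise TransientBackendError(str(exc)) from exc


class TransientBackendError(RuntimeError):
    """A retryable transport failure (HTTP 429/5xx or network error)."""


class BackendError(RuntimeError):
    """A non-recoverable backend failure; carries the query string."""


class EntrezBackend:
    """Count-only esearch client with rate limiting, retries and a cache.

    The cache is an append-only TSV (query string, count, ISO timestamp)
    keyed by the exact rendered query string; cached queries are served
    without any network call, which makes interrupted runs resumable and
    repeat runs cheap.
    """

    def __init__(
        self,
        config: BackendConfig | None = None,
        transport: Transport | None = None,
        sleep: Callable[[float], None] = time.sleep,
    ) -> None:
        self.config = config or BackendConfig()
        self.transport = transport or _urllib_transport
        self.sleep = sleep
        self.queries_issued = 0
        self.attempts_log: list[str] = []
        self._last_request_time = 0.0
        self._cache: dict[str, int] = {}
        if self.config.cache_path:
            self._load_cache(Path(self.config.cache_path))

    def _load_cache(self, path: Path) -> None:
        if not path.exists():
            return
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            query, count, _timestamp = line.split("\t")
            self._cache[query] = int(count)

    def _append_cache(self, query: str, count: int) -> None:
        self._cache[query] = count
        if self.config.cache_path:
            stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
            with open(self.config.cache_path, "a", encoding="utf-8") as fh:
                fh.write(f"{query}\t{count}\t{stamp}\n")

    def _throttle(self) -> None:
        interval = 1.0 / self.config.max_requests_per_second
        wait = self._last_request_time + interval - time.monotonic()
        if wait > 0:
            self.sleep(wait)
        self._last_request_time = time.monotonic()

    def count_query_string(self, query_string: str) -> int:
        """esearch count for a rendered query; cached, throttled, retried."""
        if not query_string:
            raise BackendError("empty query string")
        if query_string in self._cache:
            return self._cache[query_string]
        params = {"db": "pubmed", "term": query_string, "rettype": "count"}
        if self.config.api_key:
            params["api_key"] = self.config.api_key
        delay = self.config.backoff_seconds
        last_error: Exception | None = None
        for attempt in range(1 + self.config.max_retries):
            self._throttle()
            self.attempts_log.append(query_string)
            try:
                body = self.transport(self.config.base_url, params)
                count = self._parse_count(body)
            except TransientBackendError as exc:
                last_error = exc
                logger.warning("attempt %d for query failed: %s", attempt + 1, exc)
                self.sleep(delay)
                delay *= 2
                continue
            self.queries_issued += 1
            self._append_cache(query_string, count)
            return count
        raise BackendError(
            f"esearch failed after {1 + self.config.max_retries} attempts "
            f"for query {query_string!r}: {last_error}"
        )

    @staticmethod
    def _parse_count(body: bytes) -> int:
        try:
            root = etree.fromstring(body)
        except etree.XMLSyntaxError as exc:
            raise TransientBackendError(f"unparseable esearch response: {exc}") from exc
        count = root.findtext("Count")
        if count is None:
            raise TransientBackendError("esearch response lacks Count element")
        return int(count)

    def count(self, query: QueryNode, as_gold: bool = False) -> int:
        # as_gold is a local-engine concern; the live A query runs verbatim.
        return self.count_query_string(render(query))


def counts_for_query_set(
    query_set: QuerySet, backend: LocalBackend | EntrezBackend
) -> dict[Strategy, CountTriple]:
    """A/B/C counts for every strategy present in a query set.

    A is computed once and shared across strategies; strategies with an
    empty expansion are absent from the result.  Backend failures are
    re-raised annotated with the descriptor and strategy.
    """
    try:
        a = backend.count(query_set.gold, as_gold=True)
    except BackendError as exc:
        raise BackendError(f"descriptor {query_set.descriptor_id}: A query failed: {exc}") from exc
    out: dict[Strategy, CountTriple] = {}
    for strategy in query_set.retrieved:
        try:
            b = backend.count(query_set.retrieved[strategy])
            c = backend.count(query_set.intersection[strategy])
        except BackendError as exc:
            raise BackendError(
                f"descriptor {query_set.descriptor_id}, strategy {strategy.value}: {exc}"
            ) from exc
        out[strategy] = CountTriple(A=a, B=b, C=c)
    return out


# ---------------------------------------------------------------------------
# corpus serialization (JSON lines, one citation per line)


def write_corpus(citations: Iterable[Citation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cit in citations:
            fh.write(
                json.dumps(
                    {
                        "citation_id": cit.citation_id,
                        "text": cit.text,
                        "index_terms": sorted([did, major] for did, major in cit.index_terms),
                        "in_subset": cit.in_subset,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus(path: str | Path) -> list[Citation]:
    citations = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc.msg}") from exc
            citations.append(
                Citation(
                    citation_id=doc["citation_id"],
                    text=doc.get("text", ""),
                    index_terms=frozenset(
                        (did, bool(major)) for did, major in doc.get("index_terms", [])
                    ),
                    in_subset=bool(doc.get("in_subset", True)),
                )
            )
    return citations
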