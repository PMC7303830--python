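"""Descriptor vocabularies, synonym mapping tables and tree relations.

A vocabulary mirrors the structure of MeSH: each descriptor has an opaque
unique identifier, a preferred term, entry terms (the descriptor's own
synonyms, always including the preferred term), and one or more tree
numbers — dotted-path codes such as ``C04.557.337`` whose first letter is
the MeSH category (A–N, V, Z).  Synonym sets for the UMLS and CISMeF
expansion strategies arrive as pre-built mapping tables keyed by descriptor
id; the MeSH strategy's synonyms are the entry terms themselves.

Vocabularies load from a simple JSON carrier (the canonical test format)
or from the NLM MeSH descriptor XML format (``desc20xx.xml``).
"""

from __future__ import annotations

import bisect
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

#: Expansion strategies backed by a synonym mapping table.
EXPANSION_STRATEGIES = ("MESH", "UMLS", "CISMEF")

_TREE_NUMBER_RE = re.compile(r"^[A-NVZ]\d+(?:\.\d+)*$")


class VocabularyError(ValueError):
    """Raised for malformed or inconsistent vocabulary inputs."""


def normalize_terms(terms: Iterable[str]) -> list[str]:
    """Lowercase, strip and deduplicate a term list, preserving first-seen order.

    Duplicate detection is exact string equality after lowercasing and
    whitespace stripping; no further Unicode folding is applied.  The
    operation is idempotent.
    """
    seen: set[str] = set()
    out: list[str] = []
    for term in terms:
        t = term.strip().lower()
        if t and t not in seen:
            seen.add(t)
            out.append(t)
    return out


@dataclass(frozen=True)
class Descriptor:
    """One MeSH-like heading.

    ``entry_terms`` is stored normalized (lowercase, deduplicated) and always
    contains the normalized preferred term exactly once.
    """

    id: str
    preferred_term: str
    entry_terms: tuple[str, ...] = ()
    tree_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise VocabularyError("descriptor id must be nonempty")
        if not self.preferred_term or not self.preferred_term.strip():
            raise VocabularyError(f"descriptor {self.id!r}: preferred_term must be nonempty")
        terms = normalize_terms((self.preferred_term, *self.entry_terms))
        object.__setattr__(self, "entry_terms", tuple(terms))
        for tn in self.tree_numbers:
            if not _TREE_NUMBER_RE.match(tn):
                raise VocabularyError(
                    f"descriptor {self.id!r}: malformed tree number {tn!r}"
                )
        object.__setattr__(self, "tree_numbers", tuple(self.tree_numbers))


@dataclass
class MappingTable:
    """Per-strategy synonym table: descriptor id -> ordered synonym list."""

    strategy: str
    synonyms_by_descriptor: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in EXPANSION_STRATEGIES:
            raise VocabularyError(f"unknown strategy {self.strategy!r}")
        self.synonyms_by_descriptor = {
            did: normalize_terms(syns)
            for did, syns in self.synonyms_by_descriptor.items()
        }


class Vocabulary:
    """A set of descriptors plus per-strategy mapping tables.

    ``indexing_use_counts`` records, per descriptor, how many citations are
    indexed with it; descriptors used at least once form the evaluation set
    (the *eligible* descriptors).  When absent it can be filled in from a
    corpus with :meth:`set_use_counts_from_corpus`.
    """

    def __init__(
        self,
        descriptors: Iterable[Descriptor],
        mappings: Iterable[MappingTable] = (),
        indexing_use_counts: Mapping[str, int] | None = None,
    ) -> None:
        self.descriptors: dict[str, Descriptor] = {}
        for d in descriptors:
            if d.id in self.descriptors:
                raise VocabularyError(f"duplicate descriptor id {d.id!r}")
            self.descriptors[d.id] = d
        self.mappings: dict[str, MappingTable] = {}
        for table in mappings:
            if table.strategy in self.mappings:
                raise VocabularyError(f"duplicate mapping table {table.strategy!r}")
            for did in table.synonyms_by_descriptor:
                if did not in self.descriptors:
                    raise VocabularyError(
                        f"mapping {table.strategy!r} refers to unknown descriptor {did!r}"
                    )
            self.mappings[table.strategy] = table
        self.indexing_use_counts: dict[str, int] = dict(indexing_use_counts or {})
        for did, n in self.indexing_use_counts.items():
            if did not in self.descriptors:
                raise VocabularyError(f"use count for unknown descriptor {did!r}")
            if n < 0:
                raise VocabularyError(f"negative use count for {did!r}")
        # sorted tree-number index for fast descendant queries
        self._tree_index: list[tuple[str, str]] = sorted(
            (tn, d.id) for d in self.descriptors.values() for tn in d.tree_numbers
        )

    def __len__(self) -> int:
        return len(self.descriptors)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.descriptors

    def __getitem__(self, descriptor_id: str) -> Descriptor:
        try:
            return self.descriptors[descriptor_id]
        except KeyError:
            raise KeyError(f"unknown descriptor {descriptor_id!r}") from None

    def eligible_ids(self) -> list[str]:
        """Descriptor ids used at least once for indexing citations."""
        return [
            did
            for did in self.descriptors
            if self.indexing_use_counts.get(did, 0) >= 1
        ]

    def set_use_counts_from_corpus(self, citations: Iterable) -> None:
        """Derive ``indexing_use_counts`` from a citation corpus."""
        counts = {did: 0 for did in self.descriptors}
        for cit in citations:
            for did, _major in cit.index_terms:
                if did in counts:
                    counts[did] += 1
        self.indexing_use_counts = counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return (
            self.descriptors == other.descriptors
            and {s: t.synonyms_by_descriptor for s, t in self.mappings.items()}
            == {s: t.synonyms_by_descriptor for s, t in other.mappings.items()}
            and self.indexing_use_counts == other.indexing_use_counts
        )


def synonyms_for(vocabulary: Vocabulary, descriptor_id: str, strategy: str) -> list[str]:
    """Normalized synonym list for one descriptor under one expansion strategy.

    For the MESH strategy this is the descriptor's entry-term list (never
    empty: it contains at least the preferred term).  For UMLS/CISMeF it is
    the mapping-table entry, or an empty list when the descriptor has no
    mapping.
    """
    descriptor = vocabulary[descriptor_id]
    if strategy == "MESH":
        return list(descriptor.entry_terms)
    if strategy not in EXPANSION_STRATEGIES:
        raise KeyError(f"unknown strategy {strategy!r}")
    table = vocabulary.mappings.get(strategy)
    if table is None:
        return []
    return list(table.synonyms_by_descriptor.get(descriptor_id, []))


def categories_of(descriptor: Descriptor) -> set[str]:
    """Set of MeSH category letters (first letter of each tree number).

    Descriptors with no tree numbers yield the empty set; stratified reports
    treat them as uncategorized and exclude them.
    """
    return {tn[0] for tn in descriptor.tree_numbers}


def descendants(vocabulary: Vocabulary, descriptor_id: str) -> set[str]:
    """Ids of the descriptor and every descriptor below it in the tree.

    A descriptor is a descendant when one of its tree numbers extends one of
    the ancestor's tree numbers by whole dot-separated segments; matching is
    segment-aligned, so ``C23.55`` is not an ancestor of ``C23.550``.
    Includes ``descriptor_id`` itself (reflexive).
    """
    descriptor = vocabulary[descriptor_id]
    out = {descriptor_id}
    index = vocabulary._tree_index
    for tn in descriptor.tree_numbers:
        prefix = tn + "."
        lo = bisect.bisect_left(index, (tn, ""))
        for pos in range(lo, len(index)):
            cand, did = index[pos]
            if cand == tn or cand.startswith(prefix):
                out.add(did)
            elif not cand.startswith(tn):
                break
    return out


# ---------------------------------------------------------------------------
# serialization


def load_vocabulary(path: str | Path, format: str = "json") -> Vocabulary:
    """Load a vocabulary from the JSON carrier or from MeSH descriptor XML."""
    path = Path(path)
    if format == "json":
        return _load_json(path)
    if format == "mesh_xml":
        return _load_mesh_xml(path)
    raise ValueError(f"unknown vocabulary format {format!r}")


def save_vocabulary(vocabulary: Vocabulary, path: str | Path) -> None:
    """Write the canonical JSON carrier (UTF-8, stable key order)."""
    doc = {
        "descriptors": [
            {
                "id": d.id,
                "preferred_term": d.preferred_term,
                "entry_terms": list(d.entry_terms),
                "tree_numbers": list(d.tree_numbers),
            }
            for d in vocabulary.descriptors.values()
        ],
        "mappings": {
            strategy: table.synonyms_by_descriptor
            for strategy, table in vocabulary.mappings.items()
        },
        "indexing_use_counts": vocabulary.indexing_use_counts,
    }
    Path(path).write_text(
        json.dumps(doc, ensure_ascii=False, indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )


def _load_json(path: Path) -> Vocabulary:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise VocabularyError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if isinstance(doc, list):  # bare descriptor list, no mappings
        doc = {"descriptors": doc}
    if not isinstance(doc, dict) or "descriptors" not in doc:
        raise VocabularyError(f"{path}: expected a 'descriptors' list")
    descriptors = []
    for i, entry in enumerate(doc["descriptors"]):
        try:
            descriptors.append(
                Descriptor(
                    id=str(entry["id"]),
                    preferred_term=str(entry["preferred_term"]),
                    entry_terms=tuple(entry.get("entry_terms", ())),
                    tree_numbers=tuple(entry.get("tree_numbers", ())),
                )
            )
        except KeyError as exc:
            raise VocabularyError(f"{path}: descriptor #{i} missing field {exc}") from exc
    mappings = [
        MappingTable(strategy=strategy, synonyms_by_descriptor=dict(table))
        for strategy, table in doc.get("mappings", {}).items()
    ]
    return Vocabulary(
        descriptors,
        mappings,
        indexing_use_counts=doc.get("indexing_use_counts"),
    )


def _load_mesh_xml(path: Path) -> Vocabulary:
    """Read the NLM desc-format subset: DescriptorRecord / DescriptorName /
    TreeNumberList / ConceptList-TermList elements."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise VocabularyError(f"{path}: XML parse error: {exc}") from exc
    descriptors = []
    for rec in tree.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI")
        name = rec.findtext("DescriptorName/String")
        if not ui or not name:
            line = rec.sourceline
            raise VocabularyError(
                f"{path}: DescriptorRecord at line {line} lacks DescriptorUI/DescriptorName"
            )
        tree_numbers = [
            el.text.strip() for el in rec.findall("TreeNumberList/TreeNumber") if el.text
        ]
        entry_terms = [
            el.text.strip()
            for el in rec.findall("ConceptList/Concept/TermList/Term/String")
            if el.text
        ]
        descriptors.append(
            Descriptor(
                id=ui,
                preferred_term=name,
                entry_terms=tuple(entry_terms),
                tree_numbers=tuple(tree_numbers),
            )
        )
    return Vocabulary(descriptors)
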