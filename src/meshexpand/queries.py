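"""Construction and rendering of the per-descriptor tagged boolean queries.

For each descriptor and each search strategy three queries are built:

* A — the gold standard, ``"preferred term"[mh]`` (the citations NLM
  indexers assigned the descriptor to);
* B — the retrieved set, the strategy's synonyms in ``[tiab]`` joined by
  OR and restricted to the MEDLINE-indexed subset with ``medline[sb]``;
* C — the intersection, A's term clause ANDed with B.

With all four strategies available (ATM, MeSH entry terms, UMLS mappings,
CISMeF mappings) and the gold query shared, a descriptor yields nine
distinct queries.  Queries are abstract syntax trees rendered
deterministically to PubMed syntax, so the same tree always produces the
same byte string.

Tag modes vary the gold standard: ``EXPLODE`` uses ``[mh]`` (tree explosion
on, PubMed's default), ``NOEXP`` uses ``[mesh:noexp]``, and ``MAJR`` uses
``[majr]`` (major-topic indexing only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Union

from meshexpand.vocabulary import Descriptor, Vocabulary, synonyms_for


class Field(Enum):
    """PubMed field tags the engine understands."""

    MH = "mh"
    MH_NOEXP = "mesh:noexp"
    MAJR = "majr"
    TIAB = "tiab"
    SB = "sb"


class TagMode(Enum):
    """Gold-standard tag variant (sensitivity modes)."""

    EXPLODE = "explode"
    NOEXP = "noexp"
    MAJR = "majr"


class Strategy(Enum):
    """The four search strategies under comparison."""

    ATM = "ATM"
    MESH = "MESH"
    UMLS = "UMLS"
    CISMEF = "CISMEF"


_GOLD_FIELD = {
    TagMode.EXPLODE: Field.MH,
    TagMode.NOEXP: Field.MH_NOEXP,
    TagMode.MAJR: Field.MAJR,
}


@dataclass(frozen=True)
class TermClause:
    """A single quoted phrase with a field tag.

    ``text`` must be nonempty and already normalized (lowercase).  For MH-family
    fields, ``descriptor_id`` carries the descriptor the phrase names so the
    local engine can resolve indexing without re-parsing the phrase.
    """

    text: str
    field: Field
    descriptor_id: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("TermClause text must be nonempty")
        if self.text != self.text.lower():
            raise ValueError(f"TermClause text must be lowercase: {self.text!r}")


@dataclass(frozen=True)
class BoolClause:
    """AND/OR over two or more child nodes; child order is preserved."""

    op: str  # "AND" | "OR"
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR"):
            raise ValueError(f"unknown boolean operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("BoolClause requires at least two children")
        object.__setattr__(self, "children", tuple(self.children))


QueryNode = Union[TermClause, BoolClause]

#: Marker for a strategy whose expansion is empty (descriptor skipped).
EMPTY = None

_MEDLINE_SB = TermClause("medline", Field.SB)


def build_gold_query(descriptor: Descriptor, tag_mode: TagMode = TagMode.EXPLODE) -> TermClause:
    """The gold-standard query A: the preferred term under the mode's MH tag."""
    return TermClause(
        descriptor.preferred_term.strip().lower(),
        _GOLD_FIELD[tag_mode],
        descriptor_id=descriptor.id,
    )


def build_retrieved_query(
    descriptor: Descriptor, strategy: Strategy, vocabulary: Vocabulary
) -> QueryNode | None:
    """The retrieved-set query B for one strategy, or ``None`` when the
    strategy has no synonyms for the descriptor.

    ATM searches the preferred term alone in ``[tiab]``; the expansion
    strategies OR their synonym phrases in ``[tiab]``.  Every B query is
    restricted to the indexed corpus with ``medline[sb]``.  A single-synonym
    OR collapses to the bare clause.
    """
    if strategy == Strategy.ATM:
        terms = [descriptor.preferred_term.strip().lower()]
    else:
        terms = synonyms_for(vocabulary, descriptor.id, strategy.value)
    if not terms:
        return EMPTY
    clauses = [TermClause(t, Field.TIAB) for t in terms]
    expansion: QueryNode = clauses[0] if len(clauses) == 1 else BoolClause("OR", tuple(clauses))
    return BoolClause("AND", (expansion, _MEDLINE_SB))


def build_intersection_query(gold: TermClause, retrieved: QueryNode) -> BoolClause:
    """The intersection query C: gold's term clause ANDed into the retrieved
    query, keeping the subset clause exactly once, last."""
    if isinstance(retrieved, BoolClause) and retrieved.op == "AND":
        return BoolClause("AND", (gold, *retrieved.children))
    return BoolClause("AND", (gold, retrieved))


@dataclass
class QuerySet:
    """The per-descriptor query family: one shared gold query plus B and C
    for every strategy with a nonempty expansion."""

    descriptor_id: str
    gold: TermClause
    retrieved: dict[Strategy, QueryNode] = field(default_factory=dict)
    intersection: dict[Strategy, BoolClause] = field(default_factory=dict)
    tag_mode: TagMode = TagMode.EXPLODE

    def rendered_queries(self) -> list[str]:
        """All rendered query strings: 1 gold + 2 per available strategy."""
        out = [render(self.gold)]
        for strategy in self.retrieved:
            out.append(render(self.retrieved[strategy]))
            out.append(render(self.intersection[strategy]))
        return out


def build_query_set(
    descriptor: Descriptor,
    vocabulary: Vocabulary,
    tag_mode: TagMode = TagMode.EXPLODE,
    strategies: tuple[Strategy, ...] = tuple(Strategy),
) -> QuerySet:
    """Build the full query family for one descriptor.

    With all four strategies available the set renders to exactly nine
    distinct strings (1 shared A + 4 B + 4 C).
    """
    gold = build_gold_query(descriptor, tag_mode)
    qs = QuerySet(descriptor_id=descriptor.id, gold=gold, tag_mode=tag_mode)
    for strategy in strategies:
        retrieved = build_retrieved_query(descriptor, strategy, vocabulary)
        if retrieved is EMPTY:
            continue
        qs.retrieved[strategy] = retrieved
        qs.intersection[strategy] = build_intersection_query(gold, retrieved)
    return qs


def render(query: QueryNode) -> str:
    """Render an AST to deterministic PubMed syntax.

    Term clauses render as ``"<text>"[<tag>]`` except the subset clause,
    which renders unquoted as ``medline[sb]``.  Boolean children join with
    `` AND `` / `` OR ``; OR groups nested under AND are parenthesized.
    Rendering the same tree twice is byte-identical.
    """
    return _render(query, parenthesize=False)


def _render(node: QueryNode, parenthesize: bool) -> str:
    if isinstance(node, TermClause):
        if node.field == Field.SB:
            return f"{node.text}[sb]"
        return f'"{node.text}"[{node.field.value}]'
    parts = []
    for child in node.children:
        nested_or = isinstance(child, BoolClause) and child.op == "OR" and node.op == "AND"
        parts.append(_render(child, parenthesize=nested_or))
    joined = f" {node.op} ".join(parts)
    return f"({joined})" if parenthesize else joined
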