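"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-citation boolean evaluation with
sliding-window phrase matching, O(n^2) pairwise tree-descendant tests, and
exact Fraction arithmetic.  None of it shares code paths with the package's
indexes or renderers.
"""

from __future__ import annotations

import re
from fractions import Fraction

_TOKEN = re.compile(r"[^0-9a-z]+")


def naive_tokens(text: str) -> list[str]:
    return [t for t in _TOKEN.split(text.lower()) if t]


def naive_phrase_in(text: str, phrase: str) -> bool:
    hay = naive_tokens(text)
    needle = naive_tokens(phrase)
    if not needle:
        return False
    return any(hay[i : i + len(needle)] == needle for i in range(len(hay) - len(needle) + 1))


def naive_descendants(vocabulary, descriptor_id: str) -> set[str]:
    """Pairwise segment-aligned prefix test over every descriptor."""
    anc = vocabulary[descriptor_id]
    out = {descriptor_id}
    for other in vocabulary.descriptors.values():
        for tn_a in anc.tree_numbers:
            seg_a = tn_a.split(".")
            for tn_b in other.tree_numbers:
                seg_b = tn_b.split(".")
                if len(seg_b) >= len(seg_a) and seg_b[: len(seg_a)] == seg_a:
                    out.add(other.id)
    return out


def naive_matches(citation, node, vocabulary) -> bool:
    """Per-citation boolean evaluation of a query AST."""
    from meshexpand.queries import BoolClause, Field, TermClause

    if isinstance(node, TermClause):
        if node.field == Field.TIAB:
            return naive_phrase_in(citation.text, node.text)
        if node.field == Field.SB:
            return citation.in_subset
        did = node.descriptor_id
        if did is None:
            for cand in vocabulary.descriptors.values():
                if cand.preferred_term.strip().lower() == node.text:
                    did = cand.id
                    break
        if did is None or did not in vocabulary.descriptors:
            return False
        indexed = {d for d, _m in citation.index_terms}
        major = {d for d, m in citation.index_terms if m}
        if node.field == Field.MH_NOEXP:
            return did in indexed
        members = naive_descendants(vocabulary, did)
        if node.field == Field.MH:
            return bool(members & indexed)
        if node.field == Field.MAJR:
            return bool(members & major)
        raise ValueError(node.field)
    assert isinstance(node, BoolClause)
    results = [naive_matches(citation, child, vocabulary) for child in node.children]
    return all(results) if node.op == "AND" else any(results)


def naive_count(citations, node, vocabulary) -> int:
    return sum(1 for c in citations if naive_matches(c, node, vocabulary))


def naive_match_ids(citations, node, vocabulary) -> set[str]:
    return {c.citation_id for c in citations if naive_matches(c, node, vocabulary)}


def exact_metrics(a: int, b: int, c: int):
    """Exact-fraction precision/recall/F (None where undefined)."""
    p = Fraction(c, b) if b else None
    r = Fraction(c, a) if a else None
    if p is None or r is None:
        f = None
    elif c == 0:
        f = Fraction(0)
    else:
        f = 2 * p * r / (p + r)
    return p, r, f
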