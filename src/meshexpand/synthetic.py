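"""Synthetic vocabularies and MEDLINE-like corpora with known expectations.

The generator emulates the structure the evaluation pipeline needs from
MEDLINE — descriptors with entry terms and tree numbers, per-strategy
synonym tables, and citations carrying text, indexing and subset membership
— under a stated probabilistic model that makes precision and recall
analytically tractable:

* each citation is indexed with each descriptor independently with
  probability ``pi`` (indexing defines relevance, the gold standard);
* each synonym phrase of a descriptor appears in a citation's text with
  probability ``alpha`` when the citation is indexed with the descriptor
  and ``beta`` otherwise, independently per phrase;
* subset membership is an independent coin with probability ``subset_prob``.

With k independent synonyms in a query, expected recall is 1 - (1-alpha)^k
and expected precision is pi*p_rel / (pi*p_rel + (1-pi)*p_irr) with
p_rel = 1-(1-alpha)^k and p_irr = 1-(1-beta)^k.

Synonym phrases are two-token strings whose first token is globally unique
and drawn from an alphabet disjoint from the filler tokens separating
phrases, so a phrase occurs in a text if and only if the generator embedded
it — no accidental matches, which keeps the closed-form expectations exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from meshexpand.backends import Citation
from meshexpand.vocabulary import Descriptor, MappingTable, Vocabulary

_FILLER = "qfill zfill"  # filler tokens; alphabet disjoint from phrase tokens


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study conditions.

    ``synonyms_per_strategy`` maps strategy name to an inclusive (lo, hi)
    range for the number of synonym phrases per descriptor; for MESH the
    preferred term counts as the first entry term.  Defaults reflect a
    MeSH-like vocabulary: few entry terms per heading, broader UMLS
    mappings, intermediate custom mappings.
    """

    n_descriptors: int = 50
    n_citations: int = 1000
    seed: int = 0
    pi: float = 0.05
    alpha: float = 0.7
    beta: float = 0.01
    synonyms_per_strategy: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"MESH": (2, 4), "UMLS": (2, 8), "CISMEF": (1, 6)}
    )
    tree_depth: tuple[int, int] = (1, 4)
    subset_prob: float = 1.0
    major_topic_prob: float = 0.3
    categories: Sequence[str] = ("A", "B", "C", "D", "E")

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if not 0 <= self.beta <= self.alpha <= 1:
            raise ValueError("require 0 <= beta <= alpha <= 1")
        if self.n_descriptors < 1 or self.n_citations < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.subset_prob <= 1:
            raise ValueError("subset_prob must be in (0, 1]")
        if len(self.categories) < 3:
            raise ValueError("need at least 3 category letters")
        for strategy, (lo, hi) in self.synonyms_per_strategy.items():
            if not 1 <= lo <= hi:
                raise ValueError(f"{strategy}: invalid synonym count range ({lo}, {hi})")


def _phrase(pid: int) -> str:
    # globally unique first token => a phrase matches only where embedded
    return f"syn{pid:06d}a syn{pid:06d}b"


def generate_vocabulary(config: GeneratorConfig) -> Vocabulary:
    """Generate a descriptor vocabulary with tree structure and mappings.

    Preferred terms are unique two-token phrases; tree numbers form random
    chains within each category letter up to the configured depth, with the
    first three descriptors pinned to distinct categories so stratification
    always has at least three strata.  Each descriptor owns a pool of
    candidate synonym phrases from which the MESH entry terms and the
    UMLS/CISMeF mapping rows are sampled, so the three strategies overlap
    but differ.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    max_depth = max(config.tree_depth)
    pool_size = max(hi for _, hi in config.synonyms_per_strategy.values()) + 2

    descriptors: list[Descriptor] = []
    mappings: dict[str, dict[str, list[str]]] = {
        s: {} for s in config.synonyms_per_strategy if s != "MESH"
    }
    # per-category list of (tree_number, depth) available as parents
    placed: dict[str, list[tuple[str, int]]] = {c: [] for c in config.categories}
    root_counter = 0
    child_counter = 0
    next_pid = 0

    for i in range(config.n_descriptors):
        did = f"D{i:06d}"
        preferred = f"pref{i:06d}a pref{i:06d}b"

        if i < 3:
            cat = config.categories[i]
        else:
            cat = config.categories[rng.integers(len(config.categories))]
        parents = placed[cat]
        if parents and max_depth > 1 and rng.random() < 0.6:
            parent_tn, parent_depth = parents[rng.integers(len(parents))]
            if parent_depth < max_depth:
                child_counter += 1
                tn, depth = f"{parent_tn}.{child_counter:03d}", parent_depth + 1
            else:
                root_counter += 1
                tn, depth = f"{cat}{root_counter:02d}", 1
        else:
            root_counter += 1
            tn, depth = f"{cat}{root_counter:02d}", 1
        placed[cat].append((tn, depth))

        pool = [_phrase(next_pid + j) for j in range(pool_size)]
        next_pid += pool_size

        entry_terms: list[str] = [preferred]
        drawn: dict[str, list[str]] = {}
        for strategy, (lo, hi) in config.synonyms_per_strategy.items():
            k = int(rng.integers(lo, hi + 1))
            if strategy == "MESH":
                extra = rng.choice(pool_size, size=k - 1, replace=False) if k > 1 else []
                entry_terms += [pool[j] for j in extra]
            else:
                chosen = rng.choice(pool_size, size=k, replace=False)
                drawn[strategy] = [pool[j] for j in sorted(chosen)]
        # strategies sample the same pool, so identical lists can be drawn;
        # nudge duplicates apart so every strategy's expansion stays distinct
        seen_lists: list[list[str]] = []
        for strategy, syns in drawn.items():
            if syns in seen_lists:
                spare = next(p for p in pool if p not in syns)
                syns = sorted([*syns[:-1], spare])
            seen_lists.append(syns)
            mappings[strategy][did] = syns

        descriptors.append(
            Descriptor(
                id=did,
                preferred_term=preferred,
                entry_terms=tuple(entry_terms),
                tree_numbers=(tn,),
            )
        )

    tables = [
        MappingTable(strategy=s, synonyms_by_descriptor=m) for s, m in mappings.items()
    ]
    return Vocabulary(descriptors, tables)


def _descriptor_phrases(vocabulary: Vocabulary, descriptor_id: str) -> list[str]:
    """Distinct phrases attached to a descriptor across all strategies."""
    d = vocabulary[descriptor_id]
    phrases = list(d.entry_terms)
    seen = set(phrases)
    for table in vocabulary.mappings.values():
        for p in table.synonyms_by_descriptor.get(descriptor_id, []):
            if p not in seen:
                seen.add(p)
                phrases.append(p)
    return phrases


def generate_corpus(vocabulary: Vocabulary, config: GeneratorConfig) -> list[Citation]:
    """Generate citations under the stated indexing/occurrence model.

    For every (citation, descriptor) pair the indexing flag is an
    independent Bernoulli(pi) draw; each of the descriptor's distinct
    phrases is embedded with probability alpha (indexed) or beta (not
    indexed).  Embedded phrases are joined with filler tokens so phrases
    never bridge.  A post-pass force-indexes any descriptor that drew no
    citation, so every descriptor is eligible (used at least once); the
    vocabulary's ``indexing_use_counts`` is refreshed from the finished
    corpus.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    dids = list(vocabulary.descriptors)
    n_cit, n_desc = config.n_citations, len(dids)

    indexed = rng.random((n_cit, n_desc)) < config.pi
    major = rng.random((n_cit, n_desc)) < config.major_topic_prob
    in_subset = (
        np.ones(n_cit, dtype=bool)
        if config.subset_prob >= 1
        else rng.random(n_cit) < config.subset_prob
    )

    # force-index descriptors that drew no citation (eligibility post-pass);
    # runs before the occurrence draws so forced citations still carry their
    # descriptor's phrases with probability alpha
    per_desc_counts = indexed.sum(axis=0)
    subset_rows = np.nonzero(in_subset)[0]
    for j in np.nonzero(per_desc_counts == 0)[0]:
        row = (
            int(subset_rows[rng.integers(len(subset_rows))])
            if len(subset_rows)
            else int(rng.integers(n_cit))
        )
        indexed[row, j] = True

    # flatten all descriptor phrases into one occurrence matrix
    phrase_text: list[str] = []
    phrase_desc: list[int] = []
    for j, did in enumerate(dids):
        for p in _descriptor_phrases(vocabulary, did):
            phrase_text.append(p)
            phrase_desc.append(j)
    phrase_desc_arr = np.array(phrase_desc, dtype=np.intp)
    occur_prob = np.where(indexed[:, phrase_desc_arr], config.alpha, config.beta)
    occurs = rng.random(occur_prob.shape) < occur_prob

    rows, cols = np.nonzero(occurs)
    boundaries = np.searchsorted(rows, np.arange(n_cit + 1))
    citations: list[Citation] = []
    for i in range(n_cit):
        my_phrases = [phrase_text[c] for c in cols[boundaries[i] : boundaries[i + 1]]]
        text = f" {_FILLER} ".join(my_phrases)
        terms = frozenset(
            (dids[j], bool(major[i, j])) for j in np.nonzero(indexed[i])[0]
        )
        citations.append(
            Citation(
                citation_id=f"c{i:07d}",
                text=text,
                index_terms=terms,
                in_subset=bool(in_subset[i]),
            )
        )

    vocabulary.set_use_counts_from_corpus(citations)
    return citations


def expected_recall(alpha: float, k: int) -> float:
    """Closed-form expected recall for k independent synonyms."""
    return 1.0 - (1.0 - alpha) ** k


def expected_precision(pi: float, alpha: float, beta: float, k: int = 1) -> float:
    """Closed-form expected precision for k independent synonyms.

    P(relevant | retrieved) under the generator's independence assumptions.
    """
    p_rel = expected_recall(alpha, k)
    p_irr = 1.0 - (1.0 - beta) ** k
    return pi * p_rel / (pi * p_rel + (1.0 - pi) * p_irr)
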