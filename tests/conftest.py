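"""Shared fixtures: a hand-built MeSH-like vocabulary and tiny corpora."""

from __future__ import annotations

import random

import pytest

from meshexpand.backends import Citation
from meshexpand.queries import BoolClause, Field, TermClause
from meshexpand.vocabulary import Descriptor, MappingTable, Vocabulary


@pytest.fixture
def diabetes_vocabulary() -> Vocabulary:
    """Four descriptors, including the type-2-diabetes heading with its
    UMLS adult-onset synonyms and a two-level neoplasm chain for explosion."""
    descriptors = [
        Descriptor(
            id="D003924",
            preferred_term="Diabetes Mellitus, Type 2",
            entry_terms=(
                "Diabetes Mellitus, Type 2",
                "Diabetes Mellitus, Noninsulin-Dependent",
                "NIDDM",
            ),
            tree_numbers=("C18.452.394.750.149", "C19.246.300"),
        ),
        Descriptor(
            id="D002908",
            preferred_term="Chronic Disease",
            tree_numbers=("C23.550.291",),
        ),
        Descriptor(
            id="D009369",
            preferred_term="Neoplasms",
            tree_numbers=("C04",),
        ),
        Descriptor(
            id="D001943",
            preferred_term="Breast Neoplasms",
            entry_terms=("Breast Neoplasms", "Breast Cancer"),
            tree_numbers=("C04.588",),
        ),
    ]
    mappings = [
        MappingTable(
            strategy="UMLS",
            synonyms_by_descriptor={
                "D003924": [
                    "adult onset diabetes",
                    "adult onset diabetes mellitus",
                    "adult-onset diabetes",
                    "adult-onset diabetes mellitus",
                ],
                "D002908": ["chronic illness", "chronically ill"],
                "D009369": ["tumors", "tumours"],
                "D001943": ["breast tumors", "mammary cancer"],
            },
        ),
        MappingTable(
            strategy="CISMEF",
            synonyms_by_descriptor={
                "D003924": ["type 2 diabetes"],
                "D002908": ["chronic disease", "chronic"],
                "D009369": ["cancer"],
                "D001943": ["breast carcinoma"],
            },
        ),
    ]
    return Vocabulary(descriptors, mappings)


@pytest.fixture
def small_corpus() -> list[Citation]:
    """Ten hand-written citations over the diabetes vocabulary."""
    return [
        Citation("c01", "adult onset diabetes in older patients", {("D003924", True)}),
        Citation("c02", "type 2 diabetes and chronic disease burden", {("D003924", False), ("D002908", False)}),
        Citation("c03", "niddm outcomes in a cohort", {("D003924", False)}),
        Citation("c04", "chronic illness management", {("D002908", True)}),
        Citation("c05", "tumors of the lung", {("D009369", False)}),
        Citation("c06", "breast cancer screening and mammary cancer rates", {("D001943", True)}),
        Citation("c07", "a note on breast carcinoma", {("D001943", False)}),
        Citation("c08", "diabetes mellitus, type 2 therapy", {("D003924", True)}),
        Citation("c09", "unrelated cardiology report", set()),
        Citation("c10", "chronic disease registry not indexed", {("D002908", False)}, in_subset=False),
    ]


def make_random_citations(rng: random.Random, vocabulary, n: int) -> list[Citation]:
    """Random corpus over a vocabulary's phrase inventory plus filler words."""
    phrases = []
    for d in vocabulary.descriptors.values():
        phrases.extend(d.entry_terms)
    for table in vocabulary.mappings.values():
        for syns in table.synonyms_by_descriptor.values():
            phrases.extend(syns)
    fillers = ["alpha", "beta", "gamma", "delta", "study", "report", "of", "the"]
    dids = list(vocabulary.descriptors)
    citations = []
    for i in range(n):
        parts = []
        for _ in range(rng.randint(0, 6)):
            parts.append(rng.choice(phrases) if rng.random() < 0.5 else rng.choice(fillers))
        terms = set()
        for did in rng.sample(dids, k=rng.randint(0, min(3, len(dids)))):
            terms.add((did, rng.random() < 0.4))
        citations.append(
            Citation(
                citation_id=f"r{i:05d}",
                text=" ".join(parts),
                index_terms=terms,
                in_subset=rng.random() < 0.85,
            )
        )
    return citations


def make_random_query(rng: random.Random, vocabulary, depth: int = 3):
    """Random query AST (depth <= 3) over a vocabulary's terms."""
    dids = list(vocabulary.descriptors)
    phrases = [t for d in vocabulary.descriptors.values() for t in d.entry_terms]
    for table in vocabulary.mappings.values():
        for syns in table.synonyms_by_descriptor.values():
            phrases.extend(syns)

    def leaf():
        roll = rng.random()
        if roll < 0.5:
            return TermClause(rng.choice(phrases), Field.TIAB)
        if roll < 0.65:
            return TermClause("medline", Field.SB)
        did = rng.choice(dids)
        field = rng.choice([Field.MH, Field.MH_NOEXP, Field.MAJR])
        return TermClause(
            vocabulary[did].preferred_term.strip().lower(), field, descriptor_id=did
        )

    def node(d):
        if d <= 1 or rng.random() < 0.3:
            return leaf()
        children = tuple(node(d - 1) for _ in range(rng.randint(2, 3)))
        return BoolClause(rng.choice(["AND", "OR"]), children)

    return node(depth)
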