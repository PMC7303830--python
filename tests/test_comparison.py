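"""Strategy-comparison tables: means, equality counts, wins, stratified means."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from meshexpand.comparison import (
    ComparisonConfig,
    compare,
    equality_counts,
    mean_metrics,
    pairwise_wins,
    stratified_means,
)
from meshexpand.metrics import CountTriple, compute_metrics
from meshexpand.vocabulary import Descriptor, Vocabulary
from oracle import exact_metrics

STRATEGIES = ("ATM", "MESH", "UMLS", "CISMEF")


def random_records(rng: random.Random, n_descriptors: int, max_count: int = 40):
    """Random per-descriptor records with a shared A per descriptor."""
    records = []
    for i in range(n_descriptors):
        a = rng.randint(0, max_count)
        for s in STRATEGIES:
            b = rng.randint(0, max_count)
            c = rng.randint(0, min(a, b))
            records.append(
                compute_metrics(CountTriple(A=a, B=b, C=c), descriptor_id=f"d{i}", strategy=s)
            )
    return records


class TestMeanMetrics:
    def test_two_point_mean_and_sample_sd(self):
        records = [
            compute_metrics(CountTriple(A=10, B=10, C=4), "d1", "ATM"),
            compute_metrics(CountTriple(A=10, B=10, C=6), "d2", "ATM"),
        ]
        table = mean_metrics(records)
        assert table.loc["ATM", "precision_mean"] == pytest.approx(0.5)
        assert table.loc["ATM", "precision_sd"] == pytest.approx(0.141421, abs=1e-6)
        assert table.loc["ATM", "precision_n"] == 2

    def test_single_record_sd_flagged_absent(self):
        table = mean_metrics([compute_metrics(CountTriple(A=5, B=5, C=1), "d1", "ATM")])
        assert math.isnan(table.loc["ATM", "precision_sd"])
        assert table.loc["ATM", "precision_n"] == 1

    def test_undefined_values_excluded_not_imputed(self):
        records = [
            compute_metrics(CountTriple(A=10, B=0, C=0), "d1", "ATM"),  # P undefined
            compute_metrics(CountTriple(A=10, B=10, C=5), "d2", "ATM"),
        ]
        table = mean_metrics(records)
        assert table.loc["ATM", "precision_mean"] == pytest.approx(0.5)
        assert table.loc["ATM", "precision_n"] == 1
        assert table.loc["ATM", "recall_n"] == 2

    def test_matches_two_pass_oracle(self):
        rng = random.Random(3)
        records = random_records(rng, 250)
        table = mean_metrics(records)
        for s in STRATEGIES:
            values = [r.precision for r in records if r.strategy == s and r.precision is not None]
            mean = sum(values) / len(values)
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
            assert table.loc[s, "precision_mean"] == pytest.approx(mean, abs=1e-12)
            assert table.loc[s, "precision_sd"] == pytest.approx(sd, abs=1e-12)


class TestEqualityCounts:
    def test_identical_triples_equal_on_all_metrics(self):
        records = [
            compute_metrics(CountTriple(A=6, B=4, C=2), "d1", "ATM"),
            compute_metrics(CountTriple(A=6, B=4, C=2), "d1", "MESH"),
        ]
        table = equality_counts(records)
        row = table.iloc[0]
        assert (row.precision, row.recall, row.f_measure) == (1, 1, 1)

    def test_cross_product_precision_identity(self):
        # 2/4 == 3/6 exactly, though B and C differ
        records = [
            compute_metrics(CountTriple(A=9, B=4, C=2), "d1", "ATM"),
            compute_metrics(CountTriple(A=9, B=6, C=3), "d1", "MESH"),
        ]
        table = equality_counts(records)
        assert table.iloc[0]["precision"] == 1
        assert table.iloc[0]["recall"] == 0  # 2/9 != 3/9

    def test_undefined_sides_are_not_counted_equal(self):
        records = [
            compute_metrics(CountTriple(A=9, B=0, C=0), "d1", "ATM"),
            compute_metrics(CountTriple(A=9, B=0, C=0), "d1", "MESH"),
        ]
        table = equality_counts(records)
        assert table.iloc[0]["precision"] == 0
        assert table.iloc[0]["recall"] == 1  # both recalls defined and 0

    def test_matches_fraction_oracle_and_symmetry(self):
        rng = random.Random(11)
        records = random_records(rng, 300, max_count=8)
        table = equality_counts(records)
        grouped = {}
        for r in records:
            grouped.setdefault(r.descriptor_id, {})[r.strategy] = r
        for _, row in table.iterrows():
            s1, s2 = row.strategy_1, row.strategy_2
            for metric_idx, metric in enumerate(("precision", "recall", "f_measure")):
                expected = 0
                for per in grouped.values():
                    e1 = exact_metrics(per[s1].counts.A, per[s1].counts.B, per[s1].counts.C)
                    e2 = exact_metrics(per[s2].counts.A, per[s2].counts.B, per[s2].counts.C)
                    if e1[metric_idx] is not None and e1[metric_idx] == e2[metric_idx]:
                        expected += 1
                assert row[metric] == expected

    def test_rounded_mode_counts_rounded_ties(self):
        records = [
            compute_metrics(CountTriple(A=10**6, B=10**6, C=333333), "d1", "ATM"),
            compute_metrics(CountTriple(A=3 * 10**6, B=3 * 10**6, C=10**6), "d1", "MESH"),
        ]
        exact = equality_counts(records, ComparisonConfig(equality_mode="exact_rational"))
        rounded = equality_counts(
            records, ComparisonConfig(equality_mode="rounded", round_digits=4)
        )
        assert exact.iloc[0]["precision"] == 0
        assert rounded.iloc[0]["precision"] == 1


class TestPairwiseWins:
    def test_six_point_gap_is_a_win_at_five_percent(self):
        records = [
            compute_metrics(CountTriple(A=100, B=100, C=60), "d1", "ATM"),
            compute_metrics(CountTriple(A=100, B=100, C=54), "d1", "MESH"),
        ]
        table = pairwise_wins(records)
        wins = {(r.strategy_1, r.strategy_2): r.precision for r in table.itertuples()}
        assert wins[("ATM", "MESH")] == 1
        assert wins[("MESH", "ATM")] == 0

    def test_four_point_gap_is_no_win(self):
        records = [
            compute_metrics(CountTriple(A=100, B=100, C=60), "d1", "ATM"),
            compute_metrics(CountTriple(A=100, B=100, C=56), "d1", "MESH"),
        ]
        table = pairwise_wins(records)
        assert table["precision"].sum() == 0

    def test_matches_brute_force_double_loop(self):
        rng = random.Random(19)
        records = random_records(rng, 300)
        config = ComparisonConfig(cutoff=0.05)
        table = pairwise_wins(records, config)
        grouped = {}
        for r in records:
            grouped.setdefault(r.descriptor_id, {})[r.strategy] = r
        for _, row in table.iterrows():
            for metric in ("precision", "recall", "f_measure"):
                expected = 0
                for per in grouped.values():
                    v1 = getattr(per[row.strategy_1], metric)
                    v2 = getattr(per[row.strategy_2], metric)
                    if v1 is not None and v2 is not None and v1 - v2 >= 0.05:
                        expected += 1
                assert row[metric] == expected

    def test_wins_plus_equality_bounded_by_defined_pairs(self):
        rng = random.Random(23)
        records = random_records(rng, 200)
        config = ComparisonConfig(cutoff=0.05)
        wins = pairwise_wins(records, config)
        equal = equality_counts(records, config)
        grouped = {}
        for r in records:
            grouped.setdefault(r.descriptor_id, {})[r.strategy] = r
        win_map = {(r.strategy_1, r.strategy_2): r for r in wins.itertuples()}
        for row in equal.itertuples():
            s1, s2 = row.strategy_1, row.strategy_2
            for metric in ("precision", "recall", "f_measure"):
                both_defined = sum(
                    1
                    for per in grouped.values()
                    if getattr(per[s1], metric) is not None
                    and getattr(per[s2], metric) is not None
                )
                total = (
                    getattr(row, metric)
                    + getattr(win_map[(s1, s2)], metric)
                    + getattr(win_map[(s2, s1)], metric)
                )
                assert total <= both_defined

    def test_tiny_cutoff_wins_plus_within_cutoff_partition_defined_pairs(self):
        rng = random.Random(29)
        records = random_records(rng, 150, max_count=12)
        config = ComparisonConfig(cutoff=1e-9)
        wins = pairwise_wins(records, config)
        equal = equality_counts(records, config)
        grouped = {}
        for r in records:
            grouped.setdefault(r.descriptor_id, {})[r.strategy] = r
        win_map = {(r.strategy_1, r.strategy_2): r for r in wins.itertuples()}
        for row in equal.itertuples():
            s1, s2 = row.strategy_1, row.strategy_2
            for metric in ("precision", "recall", "f_measure"):
                both_defined = within = 0
                for per in grouped.values():
                    v1 = getattr(per[s1], metric)
                    v2 = getattr(per[s2], metric)
                    if v1 is None or v2 is None:
                        continue
                    both_defined += 1
                    if abs(v1 - v2) < config.cutoff:
                        within += 1
                total = (
                    within
                    + getattr(win_map[(s1, s2)], metric)
                    + getattr(win_map[(s2, s1)], metric)
                )
                assert total == both_defined
                # exact ties are a subset of the within-cutoff pairs
                assert getattr(row, metric) <= within


class TestStratifiedMeans:
    def _vocab(self):
        return Vocabulary(
            [
                Descriptor(id="d0", preferred_term="a b", tree_numbers=("C01",)),
                Descriptor(id="d1", preferred_term="c d", tree_numbers=("C02",)),
                Descriptor(id="d2", preferred_term="e f", tree_numbers=("C03.100", "D01")),
                Descriptor(id="d3", preferred_term="g h"),  # uncategorized
            ]
        )

    def test_single_category_equals_global_means(self):
        vocab = Vocabulary(
            [
                Descriptor(id="d0", preferred_term="a b", tree_numbers=("C01",)),
                Descriptor(id="d1", preferred_term="c d", tree_numbers=("C02",)),
            ]
        )
        records = [
            compute_metrics(CountTriple(A=10, B=10, C=4), "d0", "ATM"),
            compute_metrics(CountTriple(A=10, B=10, C=8), "d1", "ATM"),
        ]
        table = stratified_means(records, vocab)
        global_table = mean_metrics(records)
        row = table[(table.category == "C") & (table.strategy == "ATM")].iloc[0]
        assert row.precision == pytest.approx(global_table.loc["ATM", "precision_mean"])

    def test_multi_category_descriptor_contributes_to_each(self):
        records = [compute_metrics(CountTriple(A=10, B=10, C=5), "d2", "ATM")]
        table = stratified_means(records, self._vocab())
        assert set(table.category) == {"C", "D"}
        assert (table.precision == 0.5).all()

    def test_uncategorized_excluded_and_counted(self):
        records = [
            compute_metrics(CountTriple(A=10, B=10, C=5), "d3", "ATM"),
            compute_metrics(CountTriple(A=10, B=10, C=5), "d0", "ATM"),
        ]
        table = stratified_means(records, self._vocab())
        assert set(table.category) == {"C"}
        assert table.attrs["uncategorized"] == 1

    def test_matches_filter_and_mean_oracle(self):
        rng = random.Random(31)
        from meshexpand.synthetic import GeneratorConfig, generate_vocabulary

        vocab = generate_vocabulary(GeneratorConfig(n_descriptors=60, seed=6))
        dids = list(vocab.descriptors)
        records = []
        for did in dids:
            a = rng.randint(1, 30)
            for s in STRATEGIES:
                b = rng.randint(1, 30)
                c = rng.randint(0, min(a, b))
                records.append(compute_metrics(CountTriple(A=a, B=b, C=c), did, s))
        table = stratified_means(records, vocab)
        from meshexpand.vocabulary import categories_of

        for row in table.itertuples():
            subset = [
                r.recall
                for r in records
                if r.strategy == row.strategy
                and row.category in categories_of(vocab[r.descriptor_id])
                and r.recall is not None
            ]
            assert row.recall == pytest.approx(np.mean(subset), abs=1e-12)


class TestCompare:
    def test_report_saves_all_tables(self, tmp_path):
        rng = random.Random(37)
        from meshexpand.synthetic import GeneratorConfig, generate_vocabulary

        vocab = generate_vocabulary(GeneratorConfig(n_descriptors=20, seed=8))
        records = []
        for did in vocab.descriptors:
            a = rng.randint(1, 20)
            for s in STRATEGIES:
                b = rng.randint(1, 20)
                c = rng.randint(0, min(a, b))
                records.append(compute_metrics(CountTriple(A=a, B=b, C=c), did, s))
        report = compare(records, vocab)
        written = report.save(tmp_path)
        names = {p.name for p in written}
        assert names == {"means.csv", "equality.csv", "wins.csv", "category_means.csv", "report.json"}
        assert report.equality.shape[0] == 6   # unordered pairs of 4 strategies
        assert report.wins.shape[0] == 12      # ordered pairs
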