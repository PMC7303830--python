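"""Aggregation of per-descriptor metrics into strategy-comparison tables.

Four result surfaces are produced, mirroring how expansion strategies are
compared over a whole vocabulary:

* per-strategy mean and sample SD of precision/recall/F over descriptors
  with the metric defined;
* per strategy-pair equality counts — on how many descriptors two
  strategies score exactly the same (exact rational comparison by default,
  so large blocks of tied zero-C descriptors are not lost to float noise);
* per ordered strategy-pair win counts — on how many descriptors one
  strategy beats another by at least a cutoff (default 5 absolute
  percentage points, 0.05 on the unit scale);
* per MeSH-category stratified means, with multi-category descriptors
  contributing to each of their categories.

Undefined metric values are excluded from every table and the exclusions
are countable from the reported n columns.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from meshexpand.metrics import MetricRecord
from meshexpand.vocabulary import Vocabulary, categories_of

METRICS = ("precision", "recall", "f_measure")

_FRACTION_GETTER = {
    "precision": MetricRecord.precision_fraction,
    "recall": MetricRecord.recall_fraction,
    "f_measure": MetricRecord.f_fraction,
}


@dataclass
class ComparisonConfig:
    """Knobs for the comparison tables.

    ``cutoff`` is an absolute difference on the unit metric scale
    (0.05 = 5 percentage points).  ``equality_mode`` selects exact rational
    comparison of count cross-products or rounded-float comparison.
    """

    cutoff: float = 0.05
    equality_mode: str = "exact_rational"  # or "rounded"
    round_digits: int = 6
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if self.equality_mode not in ("exact_rational", "rounded"):
            raise ValueError(f"unknown equality_mode {self.equality_mode!r}")


def _by_descriptor(records: Iterable[MetricRecord]) -> dict[str, dict[str, MetricRecord]]:
    grouped: dict[str, dict[str, MetricRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.descriptor_id, {})[rec.strategy] = rec
    return grouped


def _strategies(records: Iterable[MetricRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.strategy)
    return list(seen)


def mean_metrics(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Unweighted mean and sample SD (n-1 denominator) per strategy-metric.

    Rows are strategies; columns ``<metric>_mean``, ``<metric>_sd``,
    ``<metric>_n`` with n the count of defined values.  A strategy-metric
    with no defined values gets NaN mean/SD and n = 0; n = 1 gets SD NaN.
    """
    records = list(records)
    rows = {}
    for strategy in _strategies(records):
        row: dict[str, float] = {}
        for metric in METRICS:
            values = np.array(
                [
                    getattr(r, metric)
                    for r in records
                    if r.strategy == strategy and getattr(r, metric) is not None
                ]
            )
            n = len(values)
            row[f"{metric}_mean"] = float(values.mean()) if n else float("nan")
            row[f"{metric}_sd"] = float(values.std(ddof=1)) if n > 1 else float("nan")
            row[f"{metric}_n"] = n
        rows[strategy] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "strategy"
    return df


def _equal(a: MetricRecord, b: MetricRecord, metric: str, config: ComparisonConfig) -> bool | None:
    """True/False when both sides defined, None when either is undefined."""
    if config.equality_mode == "exact_rational":
        fa = _FRACTION_GETTER[metric](a)
        fb = _FRACTION_GETTER[metric](b)
        if fa is None or fb is None:
            return None
        return fa == fb
    va, vb = getattr(a, metric), getattr(b, metric)
    if va is None or vb is None:
        return None
    return round(va, config.round_digits) == round(vb, config.round_digits)


def equality_counts(
    records: Iterable[MetricRecord], config: ComparisonConfig | None = None
) -> pd.DataFrame:
    """Per unordered strategy pair: descriptors on which metrics are equal.

    In exact-rational mode precision equality for shared-A records reduces
    to the cross-product identity C1*B2 == C2*B1, avoiding float ties.
    """
    config = config or ComparisonConfig()
    records = list(records)
    grouped = _by_descriptor(records)
    strategies = _strategies(records)
    rows = []
    for s1, s2 in itertools.combinations(strategies, 2):
        row: dict[str, object] = {"strategy_1": s1, "strategy_2": s2}
        for metric in METRICS:
            count = 0
            for per_strategy in grouped.values():
                if s1 in per_strategy and s2 in per_strategy:
                    if _equal(per_strategy[s1], per_strategy[s2], metric, config):
                        count += 1
            row[metric] = count
        rows.append(row)
    return pd.DataFrame(rows, columns=["strategy_1", "strategy_2", *METRICS])


def pairwise_wins(
    records: Iterable[MetricRecord], config: ComparisonConfig | None = None
) -> pd.DataFrame:
    """Per ordered strategy pair: descriptors where s1 beats s2 by >= cutoff.

    The difference is taken in absolute metric units; descriptors with
    either side undefined are excluded.
    """
    config = config or ComparisonConfig()
    records = list(records)
    grouped = _by_descriptor(records)
    strategies = _strategies(records)
    rows = []
    for s1, s2 in itertools.permutations(strategies, 2):
        row: dict[str, object] = {"strategy_1": s1, "strategy_2": s2}
        for metric in METRICS:
            count = 0
            for per_strategy in grouped.values():
                if s1 in per_strategy and s2 in per_strategy:
                    v1 = getattr(per_strategy[s1], metric)
                    v2 = getattr(per_strategy[s2], metric)
                    if v1 is not None and v2 is not None and v1 - v2 >= config.cutoff:
                        count += 1
            row[metric] = count
        rows.append(row)
    return pd.DataFrame(rows, columns=["strategy_1", "strategy_2", *METRICS])


def stratified_means(
    records: Iterable[MetricRecord], vocabulary: Vocabulary
) -> pd.DataFrame:
    """Per MeSH category letter and strategy, mean of each defined metric.

    Multi-category descriptors contribute once to each of their categories.
    Uncategorized descriptors (no tree numbers) are excluded; their count is
    available via the ``uncategorized`` attribute on the returned frame.
    """
    records = list(records)
    values: dict[tuple[str, str], dict[str, list[float]]] = {}
    uncategorized: set[str] = set()
    best: dict[tuple[str, str], str] = {}
    for rec in records:
        if rec.descriptor_id not in vocabulary.descriptors:
            continue
        cats = categories_of(vocabulary[rec.descriptor_id])
        if not cats:
            uncategorized.add(rec.descriptor_id)
            continue
        for cat in cats:
            bucket = values.setdefault((cat, rec.strategy), {m: [] for m in METRICS})
            for metric in METRICS:
                v = getattr(rec, metric)
                if v is not None:
                    bucket[metric].append(v)
    rows = []
    for (cat, strategy), bucket in sorted(values.items()):
        row: dict[str, object] = {"category": cat, "strategy": strategy}
        for metric in METRICS:
            vals = bucket[metric]
            row[metric] = float(np.mean(vals)) if vals else float("nan")
            row[f"{metric}_n"] = len(vals)
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["category", "strategy", *itertools.chain.from_iterable((m, f"{m}_n") for m in METRICS)],
    )
    # flag the best strategy per category and metric
    for metric in METRICS:
        if df.empty:
            break
        idx = df.groupby("category")[metric].idxmax()
        for cat, i in idx.items():
            if not np.isnan(df.loc[i, metric]):
                best[(cat, metric)] = df.loc[i, "strategy"]
    df.attrs["uncategorized"] = len(uncategorized)
    df.attrs["best_strategy"] = {f"{cat}:{metric}": s for (cat, metric), s in best.items()}
    return df


@dataclass
class ComparisonReport:
    """The four comparison tables plus the configuration that produced them."""

    means: pd.DataFrame
    equality: pd.DataFrame
    wins: pd.DataFrame
    category: pd.DataFrame | None
    config: ComparisonConfig = field(default_factory=ComparisonConfig)

    def save(self, output_dir: str | Path) -> list[Path]:
        """Write means/equality/wins/category tables as CSV plus a combined JSON."""
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        written = []
        tables: dict[str, pd.DataFrame | None] = {
            "means": self.means.reset_index(),
            "equality": self.equality,
            "wins": self.wins,
            "category_means": self.category,
        }
        combined: dict[str, object] = {"cutoff": self.config.cutoff}
        for name, table in tables.items():
            if table is None:
                continue
            path = output_dir / f"{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
            combined[name] = json.loads(table.to_json(orient="records"))
        json_path = output_dir / "report.json"
        json_path.write_text(json.dumps(combined, indent=1) + "\n", encoding="utf-8")
        written.append(json_path)
        return written


def compare(
    records: Iterable[MetricRecord],
    vocabulary: Vocabulary | None = None,
    config: ComparisonConfig | None = None,
) -> ComparisonReport:
    """Build the full comparison report from per-descriptor metric records."""
    config = config or ComparisonConfig()
    records = list(records)
    category = (
        stratified_means(records, vocabulary)
        if config.stratify and vocabulary is not None
        else None
    )
    return ComparisonReport(
        means=mean_metrics(records),
        equality=equality_counts(records, config),
        wins=pairwise_wins(records, config),
        category=category,
        config=config,
    )
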