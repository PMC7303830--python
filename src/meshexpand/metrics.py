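"""Precision, recall and F-measure from A/B/C citation counts.

For one descriptor and strategy, A is the number of relevant citations
(those indexed with the descriptor), B the number retrieved by the
strategy's expansion terms, and C the number of relevant citations
retrieved (the intersection).  Then

    precision = C / B        (undefined when B = 0)
    recall    = C / A        (undefined when A = 0)
    F         = 2PR / (P + R)   (harmonic mean; 0 when C = 0)

Undefined values are carried explicitly as ``None`` rather than imputed,
and aggregation excludes them while reporting how many were excluded.
The C = 0 convention follows the harmonic-mean limit: when nothing relevant
is retrieved both P and R are 0 and F is taken as 0, keeping F comparable
across strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction


@dataclass(frozen=True)
class CountTriple:
    """Citation counts for one descriptor-strategy pair.

    Invariants: C <= B always; C <= A whenever the gold set is restricted
    to the same indexed subset as B (the local engine's default).
    """

    A: int
    B: int
    C: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C) < 0:
            raise ValueError("counts must be nonnegative")
        if self.C > self.B:
            raise ValueError(f"C={self.C} exceeds B={self.B}")
        if self.C > self.A:
            raise ValueError(f"C={self.C} exceeds A={self.A}")


@dataclass(frozen=True)
class MetricRecord:
    """Per-descriptor, per-strategy metric values with definedness flags."""

    descriptor_id: str
    strategy: str
    counts: CountTriple
    precision: float | None
    recall: float | None
    f_measure: float | None

    def precision_fraction(self) -> Fraction | None:
        """Exact rational precision, for tie-free equality comparison."""
        return None if self.counts.B == 0 else Fraction(self.counts.C, self.counts.B)

    def recall_fraction(self) -> Fraction | None:
        return None if self.counts.A == 0 else Fraction(self.counts.C, self.counts.A)

    def f_fraction(self) -> Fraction | None:
        """Exact rational F-measure: 2PR/(P+R) simplifies to 2C/(A+B)."""
        if self.counts.A == 0 or self.counts.B == 0:
            return None
        return Fraction(2 * self.counts.C, self.counts.A + self.counts.B)


def compute_metrics(
    counts: CountTriple, descriptor_id: str = "", strategy: str = ""
) -> MetricRecord:
    """Turn an A/B/C triple into a metric record.

    Precision is undefined (``None``) when B = 0 and recall when A = 0;
    F-measure is defined iff both are, and equals 0 when C = 0.
    """
    precision = counts.C / counts.B if counts.B > 0 else None
    recall = counts.C / counts.A if counts.A > 0 else None
    if precision is None or recall is None:
        f_measure = None
    elif counts.C == 0:
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricRecord(
        descriptor_id=descriptor_id,
        strategy=strategy,
        counts=counts,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
    )
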