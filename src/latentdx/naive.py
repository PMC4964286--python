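"""Naive gold-standard accuracy estimation (Model II).

Treats one of the three tests — in the packaged analysis the expert
consensus — as if it were a perfect reference, and estimates the other
tests' sensitivities and specificities as conditional proportions with
Wald 95% intervals, p +/- z*sqrt(p(1-p)/m), z = 1.959964.  When the
reference is itself fallible these estimates are biased (imperfect
gold-standard bias); the latent-class model exists to correct that.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data import PATTERNS, CrossClassifiedCounts

Z_95 = 1.959964


def round_half_up(x: float, digits: int = 3) -> float:
    """Display rounding with ties away from zero, as in printed tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BinomialEstimate:
    """A conditional proportion with its Wald 95% interval."""

    numerator: int
    denominator: int

    @property
    def estimate(self) -> float:
        return self.numerator / self.denominator

    @property
    def interval(self) -> tuple[float, float]:
        p = self.estimate
        half = Z_95 * np.sqrt(p * (1.0 - p) / self.denominator)
        return max(0.0, p - half), min(1.0, p + half)


@dataclass(frozen=True)
class NaiveEstimates:
    """Model II output: accuracy of the non-reference tests plus prevalence."""

    gold: int  # 1-based index of the test used as reference
    sensitivities: dict[int, BinomialEstimate]  # keyed by 1-based test index
    specificities: dict[int, BinomialEstimate]
    prevalence: BinomialEstimate
    labels: tuple[str, str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, est in sorted(self.sensitivities.items()):
            rows.append(("Se%d" % i, est))
        for i, est in sorted(self.specificities.items()):
            rows.append(("Sp%d" % i, est))
        rows.append(("prevalence", self.prevalence))
        return pd.DataFrame(
            {
                "parameter": [name for name, _ in rows],
                "estimate": [e.estimate for _, e in rows],
                "ci_lower": [e.interval[0] for _, e in rows],
                "ci_upper": [e.interval[1] for _, e in rows],
                "numerator": [e.numerator for _, e in rows],
                "denominator": [e.denominator for _, e in rows],
            }
        ).set_index("parameter")

    def summary(self, digits: int = 3) -> pd.DataFrame:
        """Rounded display table (half-up, as conventionally printed)."""
        df = self.to_frame()
        for col in ("estimate", "ci_lower", "ci_upper"):
            df[col] = df[col].map(lambda v: round_half_up(v, digits))
        return df


def naive_accuracy(data: CrossClassifiedCounts, gold: int = 3) -> NaiveEstimates:
    """Estimate test accuracy treating test ``gold`` (1-based) as perfect.

    Sensitivity of test i is #(T_i=1, gold=1)/#(gold=1), specificity is
    #(T_i=0, gold=0)/#(gold=0), and "prevalence" is the proportion
    gold-positive.  Raises if the reference stratum is empty.
    """
    if gold not in (1, 2, 3):
        raise ValueError(f"gold must be 1, 2 or 3, got {gold}")
    g = gold - 1
    n_pos = sum(c for p, c in zip(PATTERNS, data.counts) if p[g] == 1)
    n_neg = data.n - n_pos
    if n_pos == 0:
        raise ValueError(f"empty stratum: no {data.labels[g]}-positive subjects")
    if n_neg == 0:
        raise ValueError(f"empty stratum: no {data.labels[g]}-negative subjects")
    sens, spec = {}, {}
    for i in range(3):
        if i == g:
            continue
        tp = sum(
            c for p, c in zip(PATTERNS, data.counts) if p[g] == 1 and p[i] == 1
        )
        tn = sum(
            c for p, c in zip(PATTERNS, data.counts) if p[g] == 0 and p[i] == 0
        )
        sens[i + 1] = BinomialEstimate(tp, n_pos)
        spec[i + 1] = BinomialEstimate(tn, n_neg)
    return NaiveEstimates(
        gold=gold,
        sensitivities=sens,
        specificities=spec,
        prevalence=BinomialEstimate(n_pos, data.n),
        labels=data.labels,
    )


class NaiveGoldStandardModel:
    """Model II as a fittable object, mirroring :class:`LatentClassModel`."""

    def __init__(self, counts: CrossClassifiedCounts, gold: int = 3):
        self.counts = counts
        self.gold = gold

    def fit(self) -> NaiveEstimates:
        return naive_accuracy(self.counts, gold=self.gold)
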