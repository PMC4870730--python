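"""Descriptive statistics for ordinal traits and group comparisons.

The ordinal summaries (count, percent, median, P5-P95) follow the
inverted-CDF (type-1) quantile convention: the q-quantile is the
smallest level whose cumulative count reaches ``ceil(q*n)``.  For an
even n this coincides with the lower-median rule, which is the
convention that reproduces published MMRC/BODE summary tables of this
form.  Levels need not be contiguous (a score level with zero count may
simply be absent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OrdinalDistribution",
    "GroupComparison",
    "ordinal_distribution",
    "ordinal_quantile",
    "compare_groups",
    "ordinal_summary_table",
    "summarize_phenotypes",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (the convention of printed clinical tables,
    unlike banker's rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OrdinalDistribution:
    """Counts of an integer-valued trait, by sorted level."""

    levels: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.counts):
            raise ValueError("levels and counts must have equal length")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("levels must be unique")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty distribution")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    def percentages(self, decimals: int = 1) -> tuple[float, ...]:
        """Per-level percentages, rounded half-up."""
        return tuple(
            round_half_up(100.0 * c / self.n, decimals) for c in self.counts
        )


def ordinal_distribution(values) -> OrdinalDistribution:
    """Tabulate an integer-valued trait into an :class:`OrdinalDistribution`."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.isnan(arr).any():
        raise ValueError("input contains missing values")
    if (np.floor(arr) != arr).any():
        raise ValueError("input must be integer-valued")
    levels, counts = np.unique(arr.astype(int), return_counts=True)
    return OrdinalDistribution(tuple(int(v) for v in levels),
                               tuple(int(c) for c in counts))


def ordinal_quantile(dist: OrdinalDistribution, q: float) -> int:
    """Type-1 (inverted CDF) quantile of an ordinal distribution.

    Returns the smallest level whose cumulative count reaches rank
    ``ceil(q*n)`` (rank clamped to [1, n], so q=0 gives the minimum and
    q=1 the maximum observed level).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    n = dist.n
    # tolerance guards float artefacts like 0.1*310 = 31.000000000000004
    rank = int(math.ceil(q * n - 1e-9))
    rank = min(max(rank, 1), n)
    cum = 0
    for level, count in zip(dist.levels, dist.counts):
        cum += count
        if cum >= rank:
            return level
    raise AssertionError("unreachable: counts sum to n")


@dataclass(frozen=True)
class GroupComparison:
    """Result of an across-group trait comparison."""

    test: str  # "anova" or "kruskal-wallis"
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(values, labels, kind: str = "continuous") -> GroupComparison:
    """Compare a trait across genotype (or other) groups.

    Continuous traits use one-way ANOVA; ordinal traits use
    Kruskal-Wallis.  Significance is judged at alpha = 0.05.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if kind == "continuous":
        if any(g.size < 2 for g in groups):
            raise ValueError("ANOVA needs >= 2 members per group")
        if np.ptp(values) == 0:
            raise ValueError("zero variance: ANOVA undefined")
        stat, p = stats.f_oneway(*groups)
        return GroupComparison("anova", float(stat), float(p))
    if kind == "ordinal":
        if np.ptp(values) == 0:
            raise ValueError("all values identical: Kruskal-Wallis undefined")
        stat, p = stats.kruskal(*groups)
        return GroupComparison("kruskal-wallis", float(stat), float(p))
    raise ValueError(f"unknown trait kind '{kind}'")


def ordinal_summary_table(dist: OrdinalDistribution) -> pd.DataFrame:
    """One row per observed level: count and percent (printed style)."""
    return pd.DataFrame(
        {
            "level": list(dist.levels),
            "count": list(dist.counts),
            "percent": list(dist.percentages()),
        }
    )


def summarize_phenotypes(pheno, traits: tuple[str, ...] = ("mmrc", "bode")) -> dict:
    """Summaries of the ordinal traits of a phenotype table (cases only,
    since controls do not carry them): counts, percentages, median and
    the P5-P95 range."""
    out: dict[str, dict] = {}
    df = pheno.df
    cases = df[df["status"] == "case"]
    for trait in traits:
        vals = cases[trait].dropna()
        if vals.empty:
            continue
        dist = ordinal_distribution(vals)
        out[trait] = {
            "n": dist.n,
            "levels": list(dist.levels),
            "counts": list(dist.counts),
            "percent": list(dist.percentages()),
            "median": ordinal_quantile(dist, 0.5),
            "p5": ordinal_quantile(dist, 0.05),
            "p95": ordinal_quantile(dist, 0.95),
        }
    return out
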