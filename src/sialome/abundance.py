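"""Cross-library transcript-class frequency analysis.

Given per-library observed counts of a focal transcript class (e.g.
apyrase ESTs) and library totals, the pooled rate p = sum(observed) /
sum(total) yields expected counts E_i = p * total_i, and heterogeneity is
tested by chi-square. Two modes are reported side by side: the default
2 x k contingency table (class and non-class cells) and a class-cells-only
goodness of fit, both with df = k - 1. Percent-of-group reporting matches
abundance-table conventions (1 decimal, half-up).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

__all__ = [
    "LibraryCount",
    "ChiSquareResult",
    "pooled_expected",
    "chi_square_gof",
    "percent_of_group",
]


@dataclass(frozen=True)
class LibraryCount:
    library: str
    observed: int
    total: int

    def __post_init__(self):
        if self.total < 1:
            raise ValueError(f"library {self.library!r}: total must be >= 1")
        if not 0 <= self.observed <= self.total:
            raise ValueError(
                f"library {self.library!r}: observed must lie in [0, total]")


@dataclass
class ChiSquareResult:
    libraries: list[str]
    observed: list[int]
    expected: list[float]  # class-cell expected counts under the pooled rate
    chi_square: float
    df: int
    p: float
    mode: str  # "contingency" | "class_only"
    low_expected_warning: bool = False


def pooled_expected(counts) -> list[float]:
    """Expected class counts per library under the pooled rate.

    p = sum(observed) / sum(total); E_i = p * total_i. The expectations
    conserve the pooled total exactly. Requires >= 2 libraries.
    """
    counts = list(counts)
    if len(counts) < 2:
        raise ValueError("at least 2 libraries required")
    grand_total = sum(c.total for c in counts)
    if grand_total == 0:
        raise ValueError("zero total library size")
    rate = sum(c.observed for c in counts) / grand_total
    return [rate * c.total for c in counts]


def chi_square_gof(counts, mode: str = "contingency",
                   yates: bool = False) -> ChiSquareResult:
    """Chi-square test of homogeneity of the class rate across libraries.

    ``contingency`` (default) sums (O-E)^2/E over both the class and
    non-class cells of the 2 x k table; ``class_only`` uses the class
    cells alone. df = k - 1 in both modes. Any expected class cell < 1
    sets a validity warning flag rather than refusing. ``yates`` applies
    the continuity correction |O-E| - 0.5 (off by default).
    """
    counts = list(counts)
    if mode not in ("contingency", "class_only"):
        raise ValueError(f"unknown mode {mode!r}")
    expected = pooled_expected(counts)
    if any(e <= 0 for e in expected):
        # pooled rate 0: every observed is 0 too, chi-square trivially 0
        return ChiSquareResult(
            libraries=[c.library for c in counts],
            observed=[c.observed for c in counts],
            expected=expected, chi_square=0.0, df=len(counts) - 1, p=1.0,
            mode=mode, low_expected_warning=True)

    def cell(o, e):
        d = abs(o - e)
        if yates:
            d = max(d - 0.5, 0.0)
        return d * d / e

    chi2 = 0.0
    for c, e in zip(counts, expected):
        chi2 += cell(c.observed, e)
        if mode == "contingency":
            chi2 += cell(c.total - c.observed, c.total - e)
    df = len(counts) - 1
    p = float(stats.chi2.sf(chi2, df))
    return ChiSquareResult(
        libraries=[c.library for c in counts],
        observed=[c.observed for c in counts],
        expected=expected, chi_square=float(chi2), df=df, p=p, mode=mode,
        low_expected_warning=any(e < 1 for e in expected))


def percent_of_group(count: int, group_total: int) -> float:
    """100 * count / group_total, half-up rounded to 1 decimal."""
    if group_total < 1:
        raise ValueError("group_total must be >= 1")
    if not 0 <= count <= group_total:
        raise ValueError("count must lie in [0, group_total]")
    pct = Decimal(count) * 100 / Decimal(group_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
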