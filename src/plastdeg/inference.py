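"""Nonparametric inference on group differences across genera.

The question is whether, across the selected genera, the C-C and C-X
group-proportion statistics differ systematically. The per-genus differences
prop_CC - prop_CX are paired by construction, bounded, and typically
non-normal (a Kolmogorov-Smirnov check against the fitted normal makes this
explicit), so a Wilcoxon signed-rank test is used: zero differences are
dropped (Wilcoxon's original treatment; Pratt's is available), absolute
differences are mid-ranked, and the statistic is min(W+, W-). The exact null
distribution is used for small tie-free samples; otherwise the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import EnrichmentRow

EXACT_MAX_N = 25  # above this (or with ties) the normal approximation is used


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_effective: int
    mode: str  # exact | approximate | asymptotic

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        return asdict(self)


def proportion_differences(rows: Sequence[EnrichmentRow]) -> list[Fraction]:
    """Signed per-genus difference prop_cc - prop_cx, as exact fractions."""
    if not rows:
        raise ValueError("no enrichment rows")
    return [r.prop_cc - r.prop_cx for r in rows]


def count_differences(rows: Sequence[EnrichmentRow]) -> list[int]:
    """Signed per-genus difference of raw report counts, n_cc - n_cx."""
    if not rows:
        raise ValueError("no enrichment rows")
    return [r.n_cc - r.n_cx for r in rows]


def ks_normality(diffs: Sequence[float | Fraction]) -> TestResult:
    """One-sample KS test of the standardized differences against N(0, 1).

    Differences are standardized with the sample mean and SD (estimated
    parameters; the classical KS p-value is therefore conservative about
    normality — treat it as a descriptive check, the spirit in which it is
    used here). The asymptotic KS distribution supplies the p-value.
    """
    x = np.asarray([float(d) for d in diffs])
    if len(x) < 3:
        raise ValueError("KS normality check requires at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) differences: variance is zero")
    z = (x - x.mean()) / sd
    res = stats.kstest(z, "norm", method="asymp")
    return TestResult(
        method="ks_normality",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_effective=len(x),
        mode="asymptotic",
    )


def signed_rank_test(
    diffs: Sequence[float | Fraction],
    alternative: str = "two-sided",
    zero_policy: str = "drop",
) -> TestResult:
    """Wilcoxon signed-rank test of symmetry about zero.

    Zeros are dropped before ranking (``zero_policy='pratt'`` ranks them and
    drops afterwards). With at most 25 effective pairs and no tied absolute
    values the exact null distribution is enumerated; otherwise the normal
    approximation with tie correction and continuity correction is used. The
    mode actually used is recorded in the result.
    """
    if zero_policy not in ("drop", "pratt"):
        raise ValueError(f"zero_policy must be 'drop' or 'pratt', got {zero_policy!r}")
    x = np.asarray([float(d) for d in diffs])
    nonzero = x[x != 0]
    if len(nonzero) == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")
    n_eff = len(nonzero)
    has_ties = len(np.unique(np.abs(nonzero))) < n_eff
    exact = n_eff <= EXACT_MAX_N and not has_ties and zero_policy == "drop"
    res = stats.wilcoxon(
        x,
        alternative=alternative,
        zero_method="wilcox" if zero_policy == "drop" else "pratt",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return TestResult(
        method="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_effective=n_eff,
        mode="exact" if exact else "approximate",
    )


@dataclass(frozen=True)
class GroupTestResults:
    """Bundle: normality check plus the two paired tests of the analysis."""

    ks_proportions: TestResult
    proportion_test: TestResult
    count_test: TestResult
    n_genera: int

    def to_dict(self) -> dict:
        return {
            "n_genera": self.n_genera,
            "ks_proportions": self.ks_proportions.to_dict(),
            "proportion_test": self.proportion_test.to_dict(),
            "count_test": self.count_test.to_dict(),
        }


def run_group_tests(rows: Sequence[EnrichmentRow]) -> GroupTestResults:
    """KS normality check on proportion differences, then signed-rank tests on
    both the proportion differences and the raw count differences."""
    pd_diffs = proportion_differences(rows)
    cd_diffs = count_differences(rows)
    return GroupTestResults(
        ks_proportions=ks_normality(pd_diffs),
        proportion_test=signed_rank_test(pd_diffs),
        count_test=signed_rank_test(cd_diffs),
        n_genera=len(rows),
    )
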