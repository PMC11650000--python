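"""Cohort statistics: t-tests, chi-square, Bonferroni, normality checks.

Conventions: unpaired t defaults to Student's equal-variance variant with
the statistic positive when the first group's mean is larger; Cohen's d uses
the pooled SD.  Pearson chi-square on 2x2 tables carries no continuity
correction.  Degenerate zero-variance inputs return boundary p-values with
a warning flag instead of raising, so large parameter sweeps never abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sst

from .ratio import AlphaRatioTable, global_mean_ratio, hemisphere_mean


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size: float | None = None
    n_per_group: tuple[int, ...] = ()
    correction: str = "none"
    m_corrections: int = 1
    p_adjusted: float | None = None
    comparison: str = ""
    warning: str | None = None

    def with_bonferroni(self, m: int) -> "TestResult":
        (adj,) = bonferroni([self.p_value], m=m)
        return replace(
            self, correction="bonferroni", m_corrections=m, p_adjusted=adj
        )


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def unpaired_t(
    group_a: Sequence[float], group_b: Sequence[float], variant: str = "student"
) -> TestResult:
    """Two-sided unpaired t-test; positive statistic means mean(a) > mean(b)."""
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    a = _as_1d(group_a, "group_a")
    b = _as_1d(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2, got {a.size} and {b.size}")
    name = f"unpaired_t_{variant}"
    diff = a.mean() - b.mean()
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # Degenerate contract: constant groups.
        if diff == 0:
            stat, p, warn = 0.0, 1.0, "zero_variance"
        else:
            stat, p, warn = math.copysign(math.inf, diff), 0.0, "zero_variance"
        d = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return TestResult(name, stat, float(a.size + b.size - 2), p,
                          effect_size=d, n_per_group=(a.size, b.size), warning=warn)
    res = sst.ttest_ind(a, b, equal_var=(variant == "student"))
    df = float(res.df)
    d = diff / math.sqrt(pooled_var) if pooled_var > 0 else math.copysign(math.inf, diff)
    return TestResult(
        name, float(res.statistic), df, float(res.pvalue),
        effect_size=float(d), n_per_group=(a.size, b.size),
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t on positionwise differences x - y (df = n - 1)."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValueError("paired t needs at least 2 pairs")
    d = xa - ya
    if d.var(ddof=1) == 0:
        if d.mean() == 0:
            stat, p, warn = 0.0, 1.0, "zero_variance"
        else:
            stat, p, warn = math.copysign(math.inf, d.mean()), 0.0, "zero_variance"
        return TestResult("paired_t", stat, float(xa.size - 1), p,
                          effect_size=0.0 if d.mean() == 0 else None,
                          n_per_group=(xa.size,), warning=warn)
    res = sst.ttest_rel(xa, ya)
    dz = d.mean() / d.std(ddof=1)
    return TestResult(
        "paired_t", float(res.statistic), float(xa.size - 1), float(res.pvalue),
        effect_size=float(dz), n_per_group=(xa.size,),
    )


def chi_square_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got shape {tab.shape}")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    res = sst.chi2_contingency(tab, correction=False)
    return TestResult(
        "chi_square_2x2", float(res.statistic), 1.0, float(res.pvalue),
        n_per_group=tuple(int(n) for n in tab.sum(axis=1)),
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p), order-preserving."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"m ({m}) must be >= number of p-values ({len(ps)})")
    for p in ps:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]


# ---------------------------------------------------------------------------
# Normality tests

_lilliefors_null_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_statistic(sample: np.ndarray) -> float:
    """KS distance to the normal with estimated mean and SD (ddof=1)."""
    x = np.sort(sample)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sst.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def _lilliefors_null(n: int, replicates: int, seed: int) -> np.ndarray:
    key = (n, replicates, seed)
    if key not in _lilliefors_null_cache:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((replicates, n))
        draws.sort(axis=1)
        z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
        cdf = sst.norm.cdf(z)
        grid_hi = np.arange(1, n + 1) / n
        grid_lo = np.arange(0, n) / n
        d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
        _lilliefors_null_cache[key] = np.sort(d)
    return _lilliefors_null_cache[key]


def _anderson_darling_p(a2: float, n: int) -> float:
    """Small-sample-adjusted p for the normal case with estimated parameters."""
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s > 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return min(max(p, 0.0), 1.0)


def normality(
    sample: Sequence[float],
    test: str = "lilliefors",
    replicates: int = 10_000,
    null_seed: int = 0,
) -> TestResult:
    """Test deviation from normality (mean and SD estimated from the sample).

    ``lilliefors``: KS statistic against the fitted normal, p from a seeded
    Monte-Carlo null distribution (cached per sample size).
    ``anderson_darling``: A^2 statistic with the standard small-sample-
    adjusted p approximation.
    """
    x = _as_1d(sample, "sample")
    if x.size < 8:
        raise ValueError(f"normality tests need n >= 8, got {x.size}")
    if x.std(ddof=1) == 0:
        return TestResult(test, math.inf, float(x.size), 0.0,
                          n_per_group=(x.size,), warning="zero_variance")
    if test == "lilliefors":
        d = _lilliefors_statistic(x)
        null = _lilliefors_null(x.size, replicates, null_seed)
        p = (1 + int(np.sum(null >= d))) / (null.size + 1)
        return TestResult("lilliefors", d, float(x.size), float(p), n_per_group=(x.size,))
    if test == "anderson_darling":
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        cdf = np.clip(sst.norm.cdf(z), 1e-300, 1 - 1e-16)
        i = np.arange(1, x.size + 1)
        a2 = float(
            -x.size
            - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
        )
        return TestResult(
            "anderson_darling", a2, float(x.size), _anderson_darling_p(a2, x.size),
            n_per_group=(x.size,),
        )
    raise ValueError(f"unknown normality test {test!r}")


# ---------------------------------------------------------------------------
# Cohort-level dispatch

def cohort_comparison(
    table: AlphaRatioTable,
    level: str = "hemisphere",
    variant: str = "student",
) -> list[TestResult]:
    """Patient-vs-control comparisons at a chosen aggregation level.

    ``hemisphere``: per hemisphere, unpaired t on subject-level hemisphere
    means (family m = 2).
    ``region_paired``: per hemisphere, paired t over that hemisphere's 34
    (control-mean, patient-mean) region pairs (family m = 2).
    ``region_unpaired``: per region, unpaired t across subjects; one
    Bonferroni family of 34 per hemisphere.

    The positive direction is patients minus controls throughout, so a
    positive statistic means more alpha slowing in patients.
    """
    pat = table.group_mask("left_TLE", "right_TLE")
    con = table.group_mask("control")
    if not pat.any() or not con.any():
        raise ValueError("cohort_comparison needs both controls and patients")
    hemi = table.regions["hemisphere"].to_numpy()
    results: list[TestResult] = []
    if level == "hemisphere":
        for side in ("left", "right"):
            means = hemisphere_mean(table, side)
            res = unpaired_t(means[pat], means[con], variant=variant)
            results.append(
                replace(res, comparison=f"patient_vs_control_{side}_hemisphere")
                .with_bonferroni(2)
            )
    elif level == "region_paired":
        for side in ("left", "right"):
            mask = hemi == side
            con_means = table.values[con][:, mask].mean(axis=0)
            pat_means = table.values[pat][:, mask].mean(axis=0)
            res = paired_t(pat_means, con_means)
            results.append(
                replace(res, comparison=f"regionwise_paired_{side}_hemisphere")
                .with_bonferroni(2)
            )
    elif level == "region_unpaired":
        for side in ("left", "right"):
            idx = np.flatnonzero(hemi == side)
            for j in idx:
                res = unpaired_t(table.values[pat, j], table.values[con, j],
                                 variant=variant)
                results.append(
                    replace(res, comparison=f"region_{table.regions['label'][j]}")
                    .with_bonferroni(len(idx))
                )
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    return results


def results_to_frame(results: list[TestResult]):
    """Flatten TestResults to a tidy table for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "test_name": r.test_name,
                "comparison": r.comparison,
                "statistic": r.statistic,
                "df": r.df if not isinstance(r.df, tuple) else f"{r.df[0]},{r.df[1]}",
                "p_raw": r.p_value,
                "p_adjusted": r.p_adjusted if r.p_adjusted is not None else r.p_value,
                "m": r.m_corrections,
                "effect_size": r.effect_size,
                "n": ",".join(str(n) for n in r.n_per_group),
                "warning": r.warning or "",
            }
            for r in results
        ]
    )
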