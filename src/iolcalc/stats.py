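"""Refractive outcome metrics and the statistical comparison battery.

The unit of analysis is the signed prediction error PE = observed MRSE −
predicted refraction (positive = hyperopic outcome). Summaries follow the
conventions of the IOL-formula literature: mean ± SD of signed errors,
median absolute error (MedAE), the proportions of eyes within ±0.25, ±0.50
and ±1.00 D, and the proportion beyond +0.50 D (hyperopic surprises are the
clinically costly ones). Bands are inclusive (|PE| ≤ bound) and the
hyperopic tail is strict (PE > +0.50), so the ±0.50 band and the tail
partition the hyperopic side cleanly.

Method comparisons over the same validation eyes are paired throughout:
repeated-measures ANOVA with Holm-adjusted paired t-tests for signed
errors, the Friedman rank test with Scheffé-type rank-sum pairwise
comparisons for absolute errors, and chi-squared tests with adjusted
standardized residuals for the error-band proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ErrorSummary",
    "TestResult",
    "PairwiseComparison",
    "RegressionResult",
    "summarize_errors",
    "compare_mean_errors",
    "compare_absolute_errors",
    "compare_band_proportions",
    "regress_error_on_covariate",
    "two_sample_t_test",
    "holm_adjust",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class ErrorSummary:
    """Outcome metrics for one calculation method."""

    n: int
    mean_pe: float
    sd_pe: float
    medae: float
    pct_within_025: float
    pct_within_050: float
    pct_within_100: float
    pct_over_plus_050: float


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    note: str = ""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    pairwise: tuple[PairwiseComparison, ...] | None = None
    residuals: np.ndarray | None = None
    flagged: np.ndarray | None = None


@dataclass(frozen=True)
class RegressionResult:
    """OLS of prediction error on one biometric covariate."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    zero_crossing: float | None


def summarize_errors(pe) -> ErrorSummary:
    """Standard outcome summary of a vector of signed prediction errors (D)."""
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error vector")
    ae = np.abs(pe)
    n = pe.size
    return ErrorSummary(
        n=int(n),
        mean_pe=float(np.mean(pe)),
        sd_pe=float(np.std(pe, ddof=1)) if n > 1 else 0.0,
        medae=float(np.median(ae)),
        pct_within_025=float(100.0 * np.mean(ae <= 0.25)),
        pct_within_050=float(100.0 * np.mean(ae <= 0.50)),
        pct_within_100=float(100.0 * np.mean(ae <= 1.00)),
        pct_over_plus_050=float(100.0 * np.mean(pe > 0.50)),
    )


def _aligned_matrix(pe_by_method: dict) -> tuple[list[str], np.ndarray]:
    methods = list(pe_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    cols = [np.asarray(pe_by_method[m], dtype=float) for m in methods]
    lengths = {c.size for c in cols}
    if len(lengths) != 1:
        raise ValueError(f"misaligned error vectors: lengths {sorted(lengths)}")
    return methods, np.column_stack(cols)  # eyes x methods


def compare_mean_errors(pe_by_method: dict) -> TestResult:
    """One-way repeated-measures ANOVA over methods (eyes are the subjects),
    followed by Holm-adjusted paired t-tests for every method pair.

    ``pe_by_method`` maps method name to a vector of signed errors over the
    same eyes in the same order.
    """
    methods, mat = _aligned_matrix(pe_by_method)
    n, k = mat.shape

    # Degenerate geometry is resolved from the sums of squares directly.
    grand = mat.mean()
    col_means = mat.mean(axis=0)
    row_means = mat.mean(axis=1, keepdims=True)
    ss_treat = n * float(np.sum((col_means - grand) ** 2))
    ss_resid = float(np.sum((mat - row_means - col_means + grand) ** 2))
    if ss_treat == 0.0:
        stat, p = 0.0, 1.0
    elif ss_resid == 0.0:
        stat, p = np.inf, _P_FLOOR
    else:
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "method": np.tile(methods, n),
                "pe": mat.ravel(),
            }
        )
        res = AnovaRM(long, depvar="pe", subject="subject", within=["method"]).fit()
        stat = float(res.anova_table["F Value"].iloc[0])
        p = float(res.anova_table["Pr > F"].iloc[0])

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw_ps, t_stats, notes = [], [], []
    for i, j in pairs:
        diff = mat[:, i] - mat[:, j]
        sd = np.std(diff, ddof=1)
        # an (effectively) constant difference makes the paired t degenerate
        if sd <= 1e-12 * max(1.0, abs(float(diff.mean()))):
            if np.allclose(diff, 0.0):
                t_stats.append(0.0)
                raw_ps.append(1.0)
                notes.append("identical columns")
            else:
                t_stats.append(np.inf if diff.mean() > 0 else -np.inf)
                raw_ps.append(_P_FLOOR)
                notes.append("degenerate pair: constant nonzero difference")
        else:
            t, pt = sp_stats.ttest_rel(mat[:, i], mat[:, j])
            t_stats.append(float(t))
            raw_ps.append(float(pt))
            notes.append("")
    adj = holm_adjust(raw_ps)
    pairwise = tuple(
        PairwiseComparison(
            pair=(methods[i], methods[j]),
            statistic=t_stats[m],
            p_raw=raw_ps[m],
            p_adjusted=adj[m],
            note=notes[m],
        )
        for m, (i, j) in enumerate(pairs)
    )
    return TestResult(
        statistic=stat,
        p_value=p,
        method="repeated-measures ANOVA + Holm-adjusted paired t-tests",
        pairwise=pairwise,
    )


def friedman_statistic(mat: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """Tie-corrected Friedman statistic for an eyes × methods matrix.

    Returns (statistic, p_value, rank_sums, pair_variance) where
    ``pair_variance`` is Var(R_i − R_j) under the null, used by the Scheffé
    pairwise step. Mid-ranks are used for within-row ties; with every row
    fully tied the statistic is defined as 0 (p = 1).
    """
    n, k = mat.shape
    ranks = np.vstack([sp_stats.rankdata(row) for row in mat])
    rank_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks**2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a <= c:  # all rows completely tied
        return 0.0, 1.0, rank_sums, np.nan
    stat = (k - 1) * float(np.sum((rank_sums - n * (k + 1) / 2.0) ** 2)) / (a - c)
    p = float(sp_stats.chi2.sf(stat, k - 1))
    pair_var = 2.0 * (a - c) / (k - 1)
    return stat, p, rank_sums, pair_var


def compare_absolute_errors(abs_pe_by_method: dict) -> TestResult:
    """Friedman rank test over methods, then Scheffé-type pairwise
    comparisons on the rank sums.

    The pairwise statistic for methods (i, j) is
    ``(R_i − R_j)² / Var(R_i − R_j)`` referred to a chi-squared distribution
    with k−1 degrees of freedom (the Scheffé simultaneous criterion), which
    controls the family-wise error over all pairs.
    """
    methods, mat = _aligned_matrix(abs_pe_by_method)
    n, k = mat.shape
    stat, p, rank_sums, pair_var = friedman_statistic(mat)

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            if not np.isfinite(pair_var):
                s, p_raw, p_adj = 0.0, 1.0, 1.0
            else:
                s = float((rank_sums[i] - rank_sums[j]) ** 2 / pair_var)
                p_raw = float(sp_stats.chi2.sf(s, 1))
                p_adj = float(sp_stats.chi2.sf(s, k - 1))
            pairwise.append(
                PairwiseComparison(
                    pair=(methods[i], methods[j]),
                    statistic=s,
                    p_raw=p_raw,
                    p_adjusted=p_adj,
                )
            )
    return TestResult(
        statistic=stat,
        p_value=p,
        method="Friedman + Scheffé rank-sum pairwise",
        pairwise=tuple(pairwise),
    )


def compare_band_proportions(counts) -> TestResult:
    """Pearson chi-squared test on a methods × {in-band, out-of-band}
    contingency table, with per-cell adjusted standardized residuals.

    The residual for cell (i, j) is
    ``(O − E) / sqrt(E (1 − row_i/N)(1 − col_j/N))``; |residual| > 1.96 flags
    the cell as driving the overall association (the "residual test").
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a 2-D table with at least 2 rows and columns")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    expected = row @ col / total
    if np.any(expected <= 0):
        raise ValueError("degenerate table: zero expected count")
    stat, p, _, _ = sp_stats.chi2_contingency(counts, correction=False)
    resid = (counts - expected) / np.sqrt(expected * (1 - row / total) * (1 - col / total))
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method="Pearson chi-squared + adjusted standardized residuals",
        residuals=resid,
        flagged=np.abs(resid) > 1.96,
    )


def regress_error_on_covariate(pe, covariate) -> RegressionResult:
    """OLS of signed prediction error on one biometric covariate.

    ``zero_crossing`` is the covariate value at which the fitted error is
    zero (−intercept/slope), e.g. the corneal diameter at which a formula is
    unbiased.
    """
    pe = np.asarray(pe, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if pe.size != cov.size or pe.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(cov) == 0.0:
        raise ValueError("covariate is constant; regression is degenerate")
    fit = sp_stats.linregress(cov, pe)
    slope = float(fit.slope)
    return RegressionResult(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        zero_crossing=(-float(fit.intercept) / slope) if slope != 0.0 else None,
    )


def two_sample_t_test(a, b) -> TestResult:
    """Welch's unequal-variance unpaired t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult(statistic=0.0, p_value=1.0, method="Welch t-test")
        return TestResult(
            statistic=np.inf if a.mean() > b.mean() else -np.inf,
            p_value=_P_FLOOR,
            method="Welch t-test",
        )
    t, p = sp_stats.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(t), p_value=float(p), method="Welch t-test")


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(x) for x in multipletests(p, method="holm")[1]]
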