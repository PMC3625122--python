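"""Group-level statistics: t-tests, repeated-measures ANOVA with
Greenhouse-Geisser correction, and within-subject standard errors.

The within-subject SEM uses Cousineau subject-centering with Morey's
sqrt(k/(k-1)) bias correction, matching error bars "adjusted for repeated
measurements".  All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class RMAnovaResult:
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    epsilon: float
    p_gg: float
    #: epsilon-corrected degrees of freedom
    df1_gg: float = 0.0
    df2_gg: float = 0.0


def t_test(values, mu0: float = 0.0, pairs=None) -> TTestResult:
    """One-sample (vs ``mu0``) or paired two-sided t-test.

    ``pairs`` may hold a second sample of equal length, in which case the
    test is paired and ``mu0`` is the hypothesised mean difference.  With
    zero variance the p-value is defined by convention: 0 if the mean
    differs from ``mu0``, else 1 (logged via a warning).
    """
    x = np.asarray(values, dtype=float)
    if pairs is not None:
        y = np.asarray(pairs, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        x = x - y
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance in t-test; p defined by convention")
        diff = x.mean() - mu0
        t = np.inf * np.sign(diff) if diff else 0.0
        return TTestResult(float(t), n - 1, 0.0 if diff else 1.0)
    res = stats.ttest_1samp(x, mu0)
    return TTestResult(float(res.statistic), n - 1, float(res.pvalue))


def _gg_epsilon(table: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of measures."""
    n, k = table.shape
    s = np.cov(table, rowvar=False, ddof=1)
    # double-center the covariance matrix
    row = s.mean(axis=0, keepdims=True)
    col = s.mean(axis=1, keepdims=True)
    c = s - row - col + s.mean()
    denom = (k - 1) * np.sum(c ** 2)
    lower = 1.0 / (k - 1)
    if denom <= 1e-300:
        warnings.warn("rank-deficient covariance; epsilon set to its lower bound")
        return lower
    eps = np.trace(c) ** 2 / denom
    return float(np.clip(eps, lower, 1.0))


def rm_anova_gg(table) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``table`` is (n_subjects x k conditions) with no missing cells.
    Returns the sphericity-assuming F and p, the epsilon estimate
    (bounded to [1/(k-1), 1]; forced to 1 when k = 2, where sphericity
    holds trivially), and the epsilon-corrected p with corrected degrees
    of freedom eps*(k-1) and eps*(k-1)*(n-1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    n, k = table.shape
    if k < 2:
        raise ValueError("need at least two conditions")
    if n < k:
        raise ValueError("need at least as many subjects as conditions")
    if np.any(~np.isfinite(table)):
        raise ValueError("missing cells in within-subject table")

    grand = table.mean()
    subj = table.mean(axis=1)
    cond = table.mean(axis=0)
    ss_cond = n * np.sum((cond - grand) ** 2)
    resid = table - subj[:, None] - cond[None, :] + grand
    ss_err = np.sum(resid ** 2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = np.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
        eps = 1.0
        return RMAnovaResult(float(f), df1, df2, p, eps, p, df1, df2)
    f = ms_cond / ms_err
    p_unc = float(stats.f.sf(f, df1, df2))
    eps = 1.0 if k == 2 else _gg_epsilon(table)
    df1_gg, df2_gg = eps * df1, eps * df2
    p_gg = float(stats.f.sf(f, df1_gg, df2_gg))
    return RMAnovaResult(float(f), df1, df2, p_unc, eps, p_gg, df1_gg, df2_gg)


def within_subject_sem(table) -> np.ndarray:
    """Per-condition SEM adjusted for repeated measurements.

    Subject-centres the table (subtract each subject's mean, add the
    grand mean), takes the per-condition SD / sqrt(n), and applies
    Morey's sqrt(k/(k-1)) correction.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    centered = table - table.mean(axis=1, keepdims=True) + table.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(k / (k - 1))
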