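"""Significance machinery used throughout the pipeline.

All tests are two-tailed and return a common :class:`TestResult`.  The
implementations delegate to scipy.stats, statsmodels and lifelines; the
module fixes the exact variants used everywhere in the package (exact
Mann-Whitney when feasible, exact binomial McNemar for small discordance,
two-group log-rank for survival curves) so that every caller goes through a
single, consistent call path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    two_tailed: bool = True

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def mann_whitney(
    x: Iterable[float], y: Iterable[float], mode: str = "auto"
) -> TestResult:
    """Two-sample Mann-Whitney U test (two-tailed).

    ``mode='auto'`` uses the exact null distribution when n1*n2 <= 400 and
    there are no ties across the pooled sample, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (xa.size * ya.size <= 400 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=f"mann-whitney ({method})",
        n1=xa.size,
        n2=ya.size,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on a 2x2 table of non-negative integer counts.

    Two-tailed p by summing hypergeometric probabilities no larger than the
    observed table's.  The statistic is the sample odds ratio (0 and inf
    allowed); the all-zero table returns p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("cells must be non-negative integers")
    t = t.astype(int)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        p_value=min(1.0, float(p)),
        method="fisher exact",
        n1=int(t[0].sum()),
        n2=int(t[1].sum()),
    )


def pearson_correlation(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Pearson product-moment correlation with two-tailed t-transform p.

    Binary covariates on a 0/1 coding are accepted (point-biserial is
    Pearson on the coded values).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(xa, ya)
    return TestResult(
        statistic=float(r),
        p_value=min(1.0, float(p)),
        method="pearson",
        n1=xa.size,
        n2=ya.size,
    )


def mcnemar(b: int, c: int, mode: str = "auto") -> TestResult:
    """McNemar's test from the two discordant-pair counts.

    ``b`` counts pairs positive under model A only, ``c`` pairs positive
    under model B only.  ``mode='exact'`` is the two-tailed binomial(b+c, 1/2)
    test; ``'cc_chi2'`` the continuity-corrected chi-square.  ``'auto'``
    picks exact when b + c < 25.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be non-negative integers")
    b, c = int(b), int(c)
    n = b + c
    if n == 0:
        logger.warning("mcnemar: no discordant pairs; p = 1 by convention")
        return TestResult(0.0, 1.0, "mcnemar (degenerate)", 0, 0)
    if mode == "auto":
        mode = "exact" if n < 25 else "cc_chi2"
    table = [[0, b], [c, 0]]  # concordant cells do not enter the test
    if mode == "exact":
        res = _sm_mcnemar(table, exact=True)
        method = "mcnemar (exact binomial)"
    elif mode == "cc_chi2":
        res = _sm_mcnemar(table, exact=False, correction=True)
        method = "mcnemar (cc chi2)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=method,
        n1=b,
        n2=c,
    )


def paired_t(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Paired t-test on the differences x - y (two-tailed, n-1 df)."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 2:
        raise ValueError("need at least 2 pairs")
    d = xa - ya
    if np.ptp(d) == 0:
        raise ValueError("degenerate paired t-test: all differences identical")
    t, p = sps.ttest_rel(xa, ya)
    return TestResult(
        statistic=float(t),
        p_value=min(1.0, float(p)),
        method="paired t",
        n1=xa.size,
        n2=xa.size,
    )


def logrank(
    group1: Sequence[tuple[float, bool]], group2: Sequence[tuple[float, bool]]
) -> TestResult:
    """Two-group log-rank test on (time, event) pairs, 1 df chi-square."""
    g1 = list(group1)
    g2 = list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    t1 = np.array([t for t, _ in g1], dtype=float)
    e1 = np.array([bool(e) for _, e in g1])
    t2 = np.array([t for t, _ in g2], dtype=float)
    e2 = np.array([bool(e) for _, e in g2])
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("times must be >= 0")
    if not (e1.any() or e2.any()):
        logger.warning("logrank: no events in either group; p = 1 by convention")
        return TestResult(0.0, 1.0, "logrank (no events)", t1.size, t2.size)
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=min(1.0, float(res.p_value)),
        method="logrank",
        n1=t1.size,
        n2=t2.size,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (off by default in the pipeline; raw p reported)."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adj]
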