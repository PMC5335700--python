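"""Hypothesis tests, correlations and effect sizes used throughout the analyses.

Thin, uniformly-typed wrappers around :mod:`scipy.stats` that return a single
:class:`StatResult` record (statistic, degrees of freedom, p-value, effect
size) so every analysis stage reports its inference the same way.

Conventions
-----------
* All tests are two-tailed at ``alpha = 0.05`` unless a Bonferroni-corrected
  level is attached.
* The effect size attached to t-tests is ``r = sqrt(t^2 / (t^2 + df))``,
  a sign-free correlation-scale measure in [0, 1].
* Partial correlations are first-order (one controlling variable) with the
  p-value from a t transform on ``n - 3`` degrees of freedom.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "t_test_independent",
    "effect_size_from_t",
    "pearson",
    "spearman",
    "partial_correlation",
    "kruskal_wallis",
    "bonferroni",
    "pairwise_posthoc_ttests",
]


@dataclass(frozen=True)
class StatResult:
    """One hypothesis test or correlation outcome.

    Attributes
    ----------
    statistic_name : str
        One of ``{"t", "H", "r", "rho", "partial_r"}``.
    statistic : float
        Value of the test statistic or correlation coefficient.
    df : float | None
        Degrees of freedom where the test has them.
    p_value : float
        Two-tailed p-value.
    effect_size_r : float | None
        Correlation-scale effect size in [0, 1]; populated for t-tests.
    n : int | None
        Number of observations the statistic was computed on.
    alpha : float
        Pre-assigned two-tailed significance level.
    alpha_corrected : float | None
        Bonferroni-adjusted level, when the result is part of a family.
    """

    statistic_name: str
    statistic: float
    df: float | None
    p_value: float
    effect_size_r: float | None = None
    n: int | None = None
    alpha: float = 0.05
    alpha_corrected: float | None = None

    @property
    def significant(self) -> bool:
        level = self.alpha_corrected if self.alpha_corrected is not None else self.alpha
        return bool(self.p_value < level)


def effect_size_from_t(t: float, df: float) -> float:
    """Correlation-scale effect size of a t statistic, ``sqrt(t^2/(t^2+df))``.

    Monotone increasing in ``|t|`` for fixed ``df`` and decreasing in ``df``
    for fixed ``t``; the sign of ``t`` is discarded.
    """
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    t2 = float(t) ** 2
    return math.sqrt(t2 / (t2 + df))


def t_test_independent(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    alpha_corrected: float | None = None,
) -> StatResult:
    """Two-tailed independent-samples t-test of ``group_a`` vs ``group_b``.

    Pooled-variance by default; set ``welch=True`` for unequal variances.
    The sign of ``t`` follows ``mean(group_a) - mean(group_b)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("t statistic undefined: both groups constant and equal")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    t = float(res.statistic)
    return StatResult(
        statistic_name="t",
        statistic=t,
        df=df,
        p_value=float(res.pvalue),
        effect_size_r=effect_size_from_t(t, df),
        n=a.size + b.size,
        alpha_corrected=alpha_corrected,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson product-moment correlation with a two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_corr_input(x, y)
    res = sps.pearsonr(x, y)
    return StatResult("r", float(res.statistic), float(x.size - 2), float(res.pvalue), n=x.size)


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation (midranks for ties), two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_corr_input(x, y)
    rho, p = sps.spearmanr(x, y)
    return StatResult("rho", float(rho), float(x.size - 2), float(p), n=x.size)


def _check_corr_input(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlation input must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")


def partial_correlation(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> StatResult:
    """First-order partial correlation of ``x`` and ``y`` controlling ``z``.

    Equals the Pearson correlation of the residuals of ``x`` and ``y`` after
    linear regression on ``z``; inference via ``t = r sqrt((n-3)/(1-r^2))``
    on ``n - 3`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs at least 4 observations")
    rxy = _plain_r(x, y)
    rxz = _plain_r(x, z)
    ryz = _plain_r(y, z)
    denom = math.sqrt(max(0.0, 1 - rxz**2) * max(0.0, 1 - ryz**2))
    if denom < 1e-4:  # a variable is (numerically) collinear with the control
        raise ValueError("degenerate covariance: a variable is collinear with the control")
    r = (rxy - rxz * ryz) / denom
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
    return StatResult("partial_r", r, float(df), float(p), n=n)


def _plain_r(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = np.var(a), np.var(b)
    if va == 0 or vb == 0:
        raise ValueError("partial correlation undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H test across two or more groups (tie-corrected).

    Degenerate all-identical data yields ``H = 0, p = 1`` rather than an
    error, so omnibus scans over flat synthetic data do not abort.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    total = sum(a.size for a in arrays)
    if total < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return StatResult("H", 0.0, float(len(arrays) - 1), 1.0, n=total)
    h, p = sps.kruskal(*arrays)
    return StatResult("H", float(h), float(len(arrays) - 1), float(p), n=total)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level ``alpha / m`` for m comparisons."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def pairwise_posthoc_ttests(
    groups: dict[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> list[tuple[str, str, StatResult]]:
    """All pairwise t-tests between named groups at the Bonferroni level.

    Intended as the post hoc follow-up to a Kruskal-Wallis omnibus; each
    returned :class:`StatResult` carries ``alpha_corrected = alpha / n_pairs``.
    """
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    if not pairs:
        raise ValueError("need at least 2 groups for pairwise comparisons")
    alpha_corr = bonferroni(alpha, len(pairs))
    out = []
    for a, b in pairs:
        res = t_test_independent(groups[a], groups[b], welch=welch, alpha_corrected=alpha_corr)
        out.append((a, b, res))
    return out
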