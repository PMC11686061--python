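"""Self-contained statistical primitives shared by all analysis stages.

Paired Wilcoxon signed-rank test (exact null distribution for small samples,
normal approximation with continuity and tie correction for larger ones),
least-squares covariate residualization, Spearman partial correlation,
Benjamini-Hochberg FDR control, and confusion-matrix metrics.

Conventions
-----------
* Zero paired differences are dropped before ranking (Wilcoxon's original
  treatment); the reported ``n`` is the post-drop sample size.
* Tied absolute differences receive mid-ranks.
* Covariates enter the paired test by residualizing the difference vector on
  the covariates (plus intercept) and testing the residuals against zero;
  rank tests have no native covariate mechanism.
* Gender/other categorical covariates are expected as 0/1 indicator columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ConfusionCounts",
    "wilcoxon_signed_rank",
    "residualize",
    "covariate_adjust",
    "spearman_partial",
    "fdr_bh",
    "confusion_metrics",
]

EXACT_N_MAX = 25  # exact signed-rank null up to this many nonzero pairs


@dataclass(frozen=True)
class StatResult:
    """Outcome of a single hypothesis test or correlation.

    ``effect`` is rho for correlations and the signed-rank statistic W+
    (sum of positive ranks) for paired tests. ``degenerate`` flags tests in
    which every paired difference was zero (p is reported as 1, not raised).
    """

    statistic: float
    p_value: float
    effect: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def _exact_signed_rank_sf_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact sign-flip null.

    Works with mid-ranks by doubling to integers and convolving the
    two-point (0, 2r) distributions; equivalent to enumerating all 2^n sign
    assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in r2:
        new = counts.copy()
        new[r : upper + r + 1] += counts[: upper + 1]
        counts = new
        upper += int(r)
    counts /= counts.sum()
    w2 = 2.0 * w
    lo = counts[np.arange(total + 1) <= w2 + 1e-9].sum()
    hi = counts[np.arange(total + 1) >= w2 - 1e-9].sum()
    return float(lo), float(hi)


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test of ``x`` vs ``y``.

    Exact null distribution for n <= 25 nonzero pairs, normal approximation
    with continuity correction and tie correction above. All-zero differences
    yield a degenerate result (p = 1) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return StatResult(statistic=0.0, p_value=1.0, effect=0.0, n=0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        lo, hi = _exact_signed_rank_sf_cdf(ranks, w_pos)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        z = (abs(w_pos - mu) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(z))
    return StatResult(statistic=w_pos, p_value=p, effect=w_pos, n=n)


def _design_with_intercept(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariate rows must match the number of observations")
    return np.column_stack([np.ones(n), c])


def residualize(values, covariates) -> np.ndarray:
    """Residuals of ``values`` after least-squares removal of covariates.

    An intercept is always included, so the output is mean-zero and orthogonal
    to every covariate column. Rank-deficient designs raise a ``ValueError``
    naming the first collinear column.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    X = _design_with_intercept(covariates, v.size)
    # locate collinearity by incremental rank
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            raise ValueError(
                f"covariate column {j - 1} is collinear with the preceding columns"
            )
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def covariate_adjust(values, covariates) -> np.ndarray:
    """Remove covariate-explained variance while keeping the grand mean.

    Used to adjust a paired-difference vector before a signed-rank test:
    full residualization would also remove the mean difference — the very
    effect under test — so the covariates are centered and only their fitted
    contribution is subtracted.
    """
    v = np.asarray(values, dtype=float)
    if covariates is None:
        return v.copy()
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    c = c - c.mean(axis=0, keepdims=True)
    return v.mean() + residualize(v, c)


def spearman_partial(x, y, covariates=None) -> StatResult:
    """Spearman correlation of ``x`` and ``y`` controlling for covariates.

    Both variables are rank-transformed (mid-ranks), residualized on the
    covariates (with intercept), and the Pearson correlation of the residuals
    is tested against a t distribution with n - 2 - k degrees of freedom.
    With no covariates this reduces to plain Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    k = 0
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        k = 1 if c.ndim == 1 else c.shape[1]
    if n < 4 + k:
        raise ValueError(f"need at least {4 + k} observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: ranks are undefined")
    rx = residualize(sps.rankdata(x), covariates)
    ry = residualize(sps.rankdata(y), covariates)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("residual variance is zero after covariate removal")
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(statistic=rho, p_value=min(1.0, p), effect=rho, n=n)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    Rejects all hypotheses with p <= p(k*) where k* is the largest k with
    p(k) <= k*q/m; the mask is aligned to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(sorted_p <= thresh)[0]
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """PPV, NPV, sensitivity, specificity; NaN marks a zero-denominator metric."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
    }
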