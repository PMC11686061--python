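"""Whole-brain connectivity analyses.

Edge vectorization (upper triangle of the ROI x ROI matrix; 4005 edges at
90 ROIs), per-edge paired ON/OFF signed-rank testing under FDR across all
edges, PCA of stimulation-ON edge vectors across subjects into whole-brain
connectivity patterns, scree-based selection of the number of patterns by a
repeated randomized 1-D k-means elbow rule, and Spearman partial correlation
of pattern scores with neuropsychological T-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fdr_bh, spearman_partial, wilcoxon_signed_rank

log = logging.getLogger(__name__)

__all__ = [
    "EdgeVector",
    "PatternResult",
    "vectorize_edges",
    "devectorize_edges",
    "edge_index_map",
    "edgewise_on_off_test",
    "pca_patterns",
    "elbow_components",
    "correlate_patterns_with_cognition",
]


@dataclass
class EdgeVector:
    """Upper-triangle edge values plus the edge-position -> (i, j) map."""

    values: np.ndarray
    index_map: tuple  # tuple of (roi_i, roi_j), row-major upper triangle

    @property
    def n_edges(self) -> int:
        return self.values.size


@dataclass
class PatternResult:
    """PCA connectivity patterns: loadings, subject scores, scree."""

    loadings: np.ndarray  # components x edges
    scores: np.ndarray  # subjects x components
    variance_explained: np.ndarray  # per-component fractions, non-increasing
    band: str = ""
    n_selected: int | None = None


def edge_index_map(n_rois: int) -> tuple:
    iu = np.triu_indices(n_rois, k=1)
    return tuple(zip(iu[0].tolist(), iu[1].tolist()))


def vectorize_edges(matrix: np.ndarray, atol: float = 1e-10) -> EdgeVector:
    """Row-major upper-triangle vectorization of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(m.shape[0], k=1)
    return EdgeVector(values=m[iu].copy(), index_map=edge_index_map(m.shape[0]))


def devectorize_edges(edges: EdgeVector | np.ndarray, n_rois: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (zero diagonal)."""
    vals = edges.values if isinstance(edges, EdgeVector) else np.asarray(edges, dtype=float)
    if n_rois is None:
        n_rois = int(round((1 + np.sqrt(1 + 8 * vals.size)) / 2))
    if n_rois * (n_rois - 1) // 2 != vals.size:
        raise ValueError("edge vector length does not match any ROI count")
    m = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = vals
    return m + m.T


def edgewise_on_off_test(
    subjects, band: str, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Paired signed-rank test per edge, FDR across all edges of the band."""
    on_rows, off_rows = [], []
    for sub in subjects:
        if (band, "ON") in sub.fc and (band, "OFF") in sub.fc:
            on_rows.append(vectorize_edges(sub.fc[(band, "ON")].values).values)
            off_rows.append(vectorize_edges(sub.fc[(band, "OFF")].values).values)
    if len(on_rows) < 5:
        raise ValueError("need at least 5 paired subjects")
    on = np.asarray(on_rows)
    off = np.asarray(off_rows)
    p = np.empty(on.shape[1])
    for e in range(on.shape[1]):
        p[e] = wilcoxon_signed_rank(on[:, e], off[:, e]).p_value
    return p, fdr_bh(p, q)


def pca_patterns(on_vectors: np.ndarray, band: str = "") -> PatternResult:
    """Column-centered PCA (via SVD) of subjects-x-edges ON vectors."""
    X = np.asarray(on_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in the edge matrix")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("edge vectors are identical across subjects")
    return PatternResult(
        loadings=Vt,
        scores=U * s,
        variance_explained=s**2 / total,
        band=band,
    )


def _lloyd_1d(values: np.ndarray, centers: np.ndarray, n_iter: int = 50):
    """(within-cluster SS, assignments, centers) after 1-D Lloyd iterations."""
    for _ in range(n_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[assign == c].mean() if np.any(assign == c) else centers[c]
             for c in range(centers.size)]
        )
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    return float(np.sum((values - centers[assign]) ** 2)), assign, centers


def elbow_components(
    variance_explained,
    repetitions: int = 100,
    seed: int = 0,
    cutoff: float = 0.95,
    k_max: int = 10,
) -> int:
    """Number of leading components, by a repeated randomized k-means elbow.

    Each repetition clusters the scree values in 1-D with randomly seeded
    k-means for k = 1, 2, ...; the elbow is the smallest k whose within-
    cluster variance reduction relative to k = 1 reaches ``cutoff``; the
    repetition's answer is the size of the cluster containing the largest
    scree value. The mode over repetitions is returned, ties broken toward
    the smaller count.
    """
    v = np.asarray(variance_explained, dtype=float)
    v = v[v > 0]
    if v.size < 3:
        return 1
    rng = np.random.default_rng(seed)
    kmax = min(k_max, np.unique(v).size)
    answers = []
    for _ in range(repetitions):
        w1 = float(np.sum((v - v.mean()) ** 2))
        chosen = None
        for k in range(1, kmax + 1):
            centers = rng.choice(np.unique(v), size=k, replace=False)
            wk, assign, centers = _lloyd_1d(v, centers.astype(float))
            if w1 == 0.0 or 1.0 - wk / w1 >= cutoff or k == kmax:
                top_cluster = assign[int(np.argmax(v))]
                chosen = int(np.sum(assign == top_cluster))
                break
        answers.append(chosen)
    counts = pd.Series(answers).value_counts()
    best = counts[counts == counts.max()].index.min()
    return int(best)


def correlate_patterns_with_cognition(
    scores: np.ndarray,
    t_scores: pd.DataFrame,
    covariates=None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman partial correlation of each pattern score with each T-score.

    Missing T-scores are dropped pairwise (with the matching covariate rows);
    constant tests are skipped with a warning. FDR is applied across the full
    computed component-x-test grid; the returned frame has columns
    component, test, rho, p, n, significant.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    rows = []
    for comp in range(S.shape[1]):
        for test in t_scores.columns:
            t = t_scores[test].to_numpy(dtype=float)
            ok = np.isfinite(t) & np.isfinite(S[:, comp])
            if ok.sum() < 6:
                log.warning("component %d vs %s: fewer than 6 complete cases", comp, test)
                continue
            if np.ptp(t[ok]) == 0:
                warnings.warn(f"T-score {test} is constant; skipped", stacklevel=2)
                continue
            cov = None
            if covariates is not None:
                cov = np.asarray(covariates, dtype=float)
                cov = cov[ok] if cov.ndim == 1 else cov[ok, :]
            res = spearman_partial(S[ok, comp], t[ok], cov)
            rows.append(
                {"component": comp, "test": test, "rho": res.effect,
                 "p": res.p_value, "n": res.n}
            )
    grid = pd.DataFrame(rows)
    if not grid.empty:
        grid["significant"] = fdr_bh(grid["p"].to_numpy(), q)
    return grid
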