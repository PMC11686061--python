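"""Motor-subnetwork connectivity analyses.

Extracts the 14-ROI bilateral motor subnetwork from whole-brain FC matrices,
summarizes its 91 within-subnetwork connections per subject and condition by
the first eigenvariate (first right singular vector of the centered
subjects-x-connections matrix), tests the stimulation ON vs OFF difference
per band with a covariate-adjusted signed-rank test under FDR control, runs
per-region seed-connectivity post-hoc tests, and correlates the OFF-state
eigenvariate scores with motor improvement (UPDRS_diff = UPDRS ON - OFF;
more negative means greater benefit).

ON and OFF rows of all subjects are pooled into a single decomposition per
band so both conditions are scored on one shared loading basis. Columns are
mean-centered but not variance-standardized: PLI edges share a scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .aal import MotorROISet
from .stats import StatResult, covariate_adjust, fdr_bh, spearman_partial, \
    wilcoxon_signed_rank

log = logging.getLogger(__name__)

__all__ = [
    "EigenvariateSummary",
    "extract_submatrix",
    "first_eigenvariate",
    "motor_eigenvariate_scores",
    "on_off_subnetwork_test",
    "seed_connectivity",
    "seed_posthoc_tests",
    "correlate_off_with_updrs",
]


@dataclass
class EigenvariateSummary:
    """First-eigenvariate summary of a rows-x-connections matrix.

    ``scores`` are row projections onto the first right singular vector,
    ``loadings`` is that unit-norm vector with its sign fixed so that
    mean(loadings) >= 0, and ``variance_explained`` is the first squared
    singular value over the total sum of squared singular values.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: float
    band: str = ""

    def loading_matrix(self, n_rois: int = 14) -> np.ndarray:
        """Loadings reshaped to a symmetric ROI-x-ROI layout (zero diagonal)."""
        m = np.zeros((n_rois, n_rois))
        iu = np.triu_indices(n_rois, k=1)
        m[iu] = self.loadings
        return m + m.T


def extract_submatrix(fc_values: np.ndarray, rois: MotorROISet) -> np.ndarray:
    """The motor-subnetwork block, rows/cols in MotorROISet order."""
    v = np.asarray(fc_values)
    idx = np.asarray(rois.indices)
    if idx.max() >= v.shape[0]:
        raise IndexError(
            f"ROI index {int(idx.max())} outside a {v.shape[0]}-ROI matrix"
        )
    return v[np.ix_(idx, idx)]


def _vectorize_upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def first_eigenvariate(connection_matrix: np.ndarray, band: str = "") -> EigenvariateSummary:
    """First-eigenvariate decomposition of a rows-x-connections matrix."""
    X = np.asarray(connection_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in the connection matrix")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("connection matrix is constant across rows")
    _U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[0]
    if loadings.mean() < 0:
        loadings = -loadings
    # explicit projection (= U*s up to sign): identical rows map to
    # bitwise-identical scores, which keeps paired tests exactly degenerate
    scores = Xc @ loadings
    return EigenvariateSummary(
        scores=scores,
        loadings=loadings,
        variance_explained=float(s[0] ** 2 / np.sum(s**2)),
        band=band,
    )


def motor_eigenvariate_scores(
    subjects, band: str, rois: MotorROISet
) -> tuple[np.ndarray, np.ndarray, EigenvariateSummary]:
    """Per-subject ON and OFF eigenvariate scores for one band.

    Subjects lacking either condition are excluded with a log entry. Returns
    (scores_on, scores_off, summary) with scores aligned to the retained
    subject order.
    """
    rows, keep = [], []
    for i, sub in enumerate(subjects):
        if (band, "ON") not in sub.fc or (band, "OFF") not in sub.fc:
            log.warning("subject %s lacks a condition in band %s; excluded",
                        getattr(sub, "id", i), band)
            continue
        keep.append(i)
        rows.append(_vectorize_upper(extract_submatrix(sub.fc[(band, "ON")].values, rois)))
        rows.append(_vectorize_upper(extract_submatrix(sub.fc[(band, "OFF")].values, rois)))
    if len(keep) < 2:
        raise ValueError("need at least 2 paired subjects")
    summary = first_eigenvariate(np.asarray(rows), band=band)
    scores = summary.scores.reshape(-1, 2)
    return scores[:, 0].copy(), scores[:, 1].copy(), summary


def _paired_covariate_test(on: np.ndarray, off: np.ndarray, covariates) -> StatResult:
    diff = np.asarray(on, dtype=float) - np.asarray(off, dtype=float)
    diff = covariate_adjust(diff, covariates)
    return wilcoxon_signed_rank(diff, np.zeros_like(diff))


def on_off_subnetwork_test(
    subjects,
    bands,
    rois: MotorROISet,
    covariates=None,
    q: float = 0.05,
) -> tuple[dict, np.ndarray, dict]:
    """Per-band paired ON vs OFF test of eigenvariate scores, FDR across bands.

    Returns ({band: StatResult}, rejection mask aligned to ``bands``,
    {band: EigenvariateSummary}).
    """
    results: dict[str, StatResult] = {}
    summaries: dict[str, EigenvariateSummary] = {}
    for band in bands:
        name = band if isinstance(band, str) else band.name
        s_on, s_off, summ = motor_eigenvariate_scores(subjects, name, rois)
        results[name] = _paired_covariate_test(s_on, s_off, covariates)
        summaries[name] = summ
    mask = fdr_bh([results[b if isinstance(b, str) else b.name].p_value for b in bands], q)
    return results, mask, summaries


def seed_connectivity(sub_matrix: np.ndarray, roi: str, rois: MotorROISet) -> float:
    """Mean connectivity of one motor region with the other 13."""
    if roi not in rois.labels:
        raise KeyError(f"{roi!r} is not a motor-subnetwork label")
    m = np.asarray(sub_matrix, dtype=float)
    pos = rois.labels.index(roi)
    n = m.shape[0]
    return float((m[pos].sum() - m[pos, pos]) / (n - 1))


def seed_posthoc_tests(
    subjects,
    band: str,
    rois: MotorROISet,
    covariates=None,
    q: float = 0.05,
) -> tuple[dict, np.ndarray]:
    """Per-region paired ON vs OFF seed-connectivity tests, FDR across regions."""
    per_roi_on = {lab: [] for lab in rois.labels}
    per_roi_off = {lab: [] for lab in rois.labels}
    n_pairs = 0
    for sub in subjects:
        if (band, "ON") not in sub.fc or (band, "OFF") not in sub.fc:
            log.warning("subject %s lacks a condition; excluded", getattr(sub, "id", "?"))
            continue
        n_pairs += 1
        on_sub = extract_submatrix(sub.fc[(band, "ON")].values, rois)
        off_sub = extract_submatrix(sub.fc[(band, "OFF")].values, rois)
        for lab in rois.labels:
            per_roi_on[lab].append(seed_connectivity(on_sub, lab, rois))
            per_roi_off[lab].append(seed_connectivity(off_sub, lab, rois))
    if n_pairs < 5:
        raise ValueError("insufficient paired subjects for post-hoc testing")
    results = {
        lab: _paired_covariate_test(
            np.array(per_roi_on[lab]), np.array(per_roi_off[lab]), covariates
        )
        for lab in rois.labels
    }
    mask = fdr_bh([results[lab].p_value for lab in rois.labels], q)
    return results, mask


def correlate_off_with_updrs(off_scores, updrs_diff, covariates=None) -> StatResult:
    """Spearman partial correlation of OFF-state scores with UPDRS_diff."""
    off_scores = np.asarray(off_scores, dtype=float)
    if off_scores.size < 6:
        raise ValueError("need at least 6 subjects")
    return spearman_partial(off_scores, np.asarray(updrs_diff, dtype=float), covariates)
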