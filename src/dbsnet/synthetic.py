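"""Synthetic cohorts with the statistical structure the analysis assumes.

Every downstream stage is testable without patient data: the generator
produces oddball-paradigm event streams, demographics and clinical scores,
per-band per-condition PLI-like FC matrices with planted effects, and
(optionally) trial-level coupled-oscillator ROI time series for the
signal-to-connectivity stage.

Planted structure
-----------------
* OFF-state motor pattern: a fixed loading pattern over the 91 motor-
  subnetwork connections (low within-cortical, high subcortical and
  cortico-subcortical coupling) is added to the stimulation-OFF matrices of
  the chosen band, scaled by ``motor_effect_size`` times each subject's
  normalized motor improvement, so better responders show the pattern more
  prominently even with the stimulator off.
* ON-state motor increase: a uniform connectivity increase over the motor
  subnetwork in the ON condition (``on_motor_increase``), the group-level
  stimulation effect.
* Responder profile: for optimal responders only, the ON-OFF difference at
  ``profile_edges`` is shifted by ``direction * profile_effect_size``; their
  OFF-state values at the same edges are shifted by
  ``direction * profile_off_effect``, which is what makes pre-stimulation
  classification possible at all.
* Cognition pattern: a unit-norm whole-brain edge pattern whose per-subject
  expression (in the ON state) correlates with one designated
  neuropsychological T-score at ``cognition_effect_size``; the remaining
  T-scores are pure noise.

Ground truth (labels, planted loadings, profile, pattern) is emitted next to
the data and is never read by any analysis module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aal import AAL90_LABELS, MOTOR_CORTICAL_COUNT, motor_indices_for
from .connectivity import CANONICAL_BANDS, BandSpec, FCMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "SubjectRecord",
    "T_SCORE_NAMES",
    "generate_paradigm",
    "generate_metadata",
    "generate_fc_cohort",
    "generate_coupled_timeseries",
    "default_motor_loading",
    "default_profile_edges",
]

T_SCORE_NAMES = (
    "digit_span",
    "word_list_1",
    "word_list_2",
    "stroop_interference",
    "mattis_total",
)
COGNITION_T_SCORE = "stroop_interference"  # the one channel carrying the planted effect


@dataclass
class SubjectRecord:
    """One subject: demographics, clinical scores, and FC matrices."""

    id: str
    age: float
    gender: str  # "F" or "M"
    updrs_on: int
    updrs_off: int
    t_scores: dict
    fc: dict = field(default_factory=dict)  # (band_name, condition) -> FCMatrix

    @property
    def updrs_diff(self) -> int:
        return self.updrs_on - self.updrs_off


@dataclass
class SyntheticCohort:
    subjects: list
    bands: tuple
    roi_labels: tuple
    metadata: pd.DataFrame
    ground_truth: dict
    spec: "CohortSpec"


def default_motor_loading(n_motor: int = 14,
                          cortical: int = MOTOR_CORTICAL_COUNT) -> np.ndarray:
    """Unit-norm loading over the C(n,2) within-subnetwork connections.

    Low weight on cortico-cortical links, high weight on subcortical and
    cortico-subcortical links — the two-module layout of the motor pattern.
    """
    iu = np.triu_indices(n_motor, k=1)
    w = np.where((iu[0] < cortical) & (iu[1] < cortical), 0.15, 1.0)
    return w / np.linalg.norm(w)


def default_profile_edges(roi_count: int, band_names) -> tuple:
    """Ten deterministic (band, edge, direction) entries outside delta."""
    rng = np.random.default_rng(20240101)  # fixed: part of the planted truth
    eligible = [b for b in band_names if b != "delta"] or list(band_names)
    entries, seen = [], set()
    while len(entries) < 10:
        band = eligible[rng.integers(len(eligible))]
        i, j = sorted(rng.choice(roi_count, size=2, replace=False).tolist())
        if (band, i, j) in seen:
            continue
        seen.add((band, i, j))
        direction = 1 if rng.random() < 0.6 else -1
        entries.append((band, (int(i), int(j)), direction))
    return tuple(entries)


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Effect sizes: ``motor_effect_size`` multiplies the unit-norm motor loading
    (per-edge PLI shift = size * loading * responsiveness in [0,1]);
    ``profile_effect_size`` / ``profile_off_effect`` are per-edge PLI shifts;
    ``cognition_pattern_sd`` is the across-subject SD of the cognition-pattern
    score and ``cognition_effect_size`` the target correlation with the
    designated T-score; ``noise_sd`` is the per-edge SD of the ON-OFF noise.
    """

    n_subjects: int = 43
    roi_count: int = 90
    band_set: tuple = CANONICAL_BANDS
    motor_roi_indices: tuple = ()
    planted_motor_loading: np.ndarray | None = None
    motor_effect_size: float = 2.0
    motor_band: str = "high_gamma"
    on_motor_increase: float = 0.01
    profile_edges: tuple | None = None
    profile_effect_size: float = 0.15
    profile_off_effect: float = 0.1
    cognition_pattern: np.ndarray | None = None
    cognition_effect_size: float = 0.7
    cognition_pattern_sd: float = 2.5
    cognition_band: str = "high_gamma"
    noise_sd: float = 0.02
    updrs_diff_range: tuple = (-41, -9)
    responder_threshold: float = -18.0
    female_fraction: float = 14 / 43
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motor_roi_indices:
            self.motor_roi_indices = motor_indices_for(self.roi_count)
        idx = self.motor_roi_indices
        if len(set(idx)) != len(idx) or min(idx) < 0 or max(idx) >= self.roi_count:
            raise ValueError("motor_roi_indices must be distinct and in range")
        lo, hi = self.updrs_diff_range
        if not (lo < hi < 0):
            raise ValueError("updrs_diff_range must satisfy lo < hi < 0")
        for name in ("motor_effect_size", "on_motor_increase",
                     "profile_effect_size", "profile_off_effect",
                     "cognition_effect_size", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_motor_loading is None:
            self.planted_motor_loading = default_motor_loading(len(idx))
        if self.profile_edges is None:
            self.profile_edges = default_profile_edges(
                self.roi_count, [b.name for b in self.band_set]
            )
        if self.cognition_pattern is None:
            n_edges = self.roi_count * (self.roi_count - 1) // 2
            rng = np.random.default_rng(20240102)  # fixed planted truth
            v = rng.standard_normal(n_edges)
            self.cognition_pattern = v / np.linalg.norm(v)

    @property
    def band_names(self) -> tuple:
        return tuple(b.name for b in self.band_set)

    def roi_labels(self) -> tuple:
        if self.roi_count == 90:
            return AAL90_LABELS
        return tuple(f"ROI_{i:03d}" for i in range(self.roi_count))


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-stream so cohorts are extensible without reshuffling."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_paradigm(
    n_target: int = 30,
    n_frequent: int = 140,
    n_distractor: int = 30,
    stim_dur: float = 0.2,
    isi: float = 4.0,
    seed: int = 0,
) -> list:
    """Randomized oddball event stream: [(onset_seconds, type), ...].

    Onsets are strictly increasing with spacing ``stim_dur + isi``; the
    default 30/140/30 design lasts 200 * 4.2 s = 14 min.
    """
    if min(n_target, n_frequent, n_distractor) < 0:
        raise ValueError("stimulus counts must be >= 0")
    types = (["target"] * n_target + ["frequent"] * n_frequent
             + ["distractor"] * n_distractor)
    rng = _rng(seed, 0)
    order = rng.permutation(len(types))
    spacing = stim_dur + isi
    return [(i * spacing, types[j]) for i, j in enumerate(order)]


def generate_metadata(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject demographics, UPDRS scores, and T-scores.

    UPDRS_diff (ON - OFF) covers ``updrs_diff_range`` uniformly (integers);
    ages are normal(61, 7); the OFF score is uniform over [30, 70], raised
    where needed so the ON score stays non-negative. T-scores are filled in
    here as noise; the cognition-linked channel is overwritten by
    :func:`generate_fc_cohort` once pattern scores exist.
    """
    rng = _rng(spec.seed, 1)
    n = spec.n_subjects
    lo, hi = spec.updrs_diff_range
    diffs = rng.integers(int(lo), int(hi) + 1, size=n)
    ages = rng.normal(61.0, 7.0, size=n)
    genders = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    updrs_off = rng.integers(30, 71, size=n)
    updrs_off = np.maximum(updrs_off, -diffs)  # keep the ON score >= 0
    t = {name: rng.normal(50.0, 10.0, size=n) for name in T_SCORE_NAMES}
    return pd.DataFrame(
        {
            "id": [f"sub-{i + 1:02d}" for i in range(n)],
            "age": np.round(ages, 1),
            "gender": genders,
            "updrs_off": updrs_off,
            "updrs_on": updrs_off + diffs,
            "updrs_diff": diffs,
            **{f"t_{k}": np.round(v, 1) for k, v in t.items()},
        }
    )


def _symmetrize_plant(mat: np.ndarray, i, j, value) -> None:
    mat[i, j] += value
    mat[j, i] += value


def _edge_matrix_from_vector(vec: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vec
    return m + m.T


def generate_fc_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full synthetic cohort of FC matrices with planted effects.

    Baseline edges are Beta(2, 5) draws (sparse right-skewed coupling); all
    planting is additive, then matrices are clipped to [0, 1] (clipping of
    more than 20% of edges is logged as a warning).
    """
    meta = generate_metadata(spec)
    n, r = spec.n_subjects, spec.roi_count
    iu = np.triu_indices(r, k=1)
    lo, hi = spec.updrs_diff_range
    # responsiveness in [0, 1]: 1 at the best improvement (most negative diff)
    w = (meta["updrs_diff"].to_numpy() - hi) / (lo - hi)
    responder = meta["updrs_diff"].to_numpy() < spec.responder_threshold

    motor_idx = np.asarray(spec.motor_roi_indices)
    motor_iu = np.triu_indices(len(motor_idx), k=1)
    motor_rows = motor_idx[motor_iu[0]]
    motor_cols = motor_idx[motor_iu[1]]

    cog_rng = _rng(spec.seed, 2)
    cog_scores = cog_rng.standard_normal(n)  # pattern expression per subject
    cog_mat = _edge_matrix_from_vector(spec.cognition_pattern, r)

    subjects: list[SubjectRecord] = []
    clipped_total = 0
    edges_total = 0
    for s in range(n):
        rng = _rng(spec.seed, 3, s)
        row = meta.iloc[s]
        fc: dict = {}
        for band in spec.band_set:
            base = np.zeros((r, r))
            base[iu] = rng.beta(2.0, 5.0, size=iu[0].size)
            base += base.T

            off = base.copy()
            if band.name == spec.motor_band and spec.motor_effect_size > 0:
                plant = spec.motor_effect_size * w[s] * spec.planted_motor_loading
                off[motor_rows, motor_cols] += plant
                off[motor_cols, motor_rows] += plant
            for pband, (i, j), direction in spec.profile_edges:
                if pband == band.name and responder[s]:
                    _symmetrize_plant(off, i, j, direction * spec.profile_off_effect)

            delta = np.zeros((r, r))
            noise = rng.normal(0.0, spec.noise_sd, size=iu[0].size)
            delta[iu] = noise
            delta += delta.T
            if band.name == spec.motor_band and spec.on_motor_increase > 0:
                delta[motor_rows, motor_cols] += spec.on_motor_increase
                delta[motor_cols, motor_rows] += spec.on_motor_increase
            for pband, (i, j), direction in spec.profile_edges:
                if pband == band.name and responder[s]:
                    _symmetrize_plant(delta, i, j, direction * spec.profile_effect_size)
            if band.name == spec.cognition_band and spec.cognition_pattern_sd > 0:
                delta += spec.cognition_pattern_sd * cog_scores[s] * cog_mat
            on = off + delta

            for mat in (off, on):
                clipped_total += int(np.count_nonzero((mat[iu] < 0) | (mat[iu] > 1)))
                edges_total += iu[0].size
                np.clip(mat, 0.0, 1.0, out=mat)
                np.fill_diagonal(mat, 0.0)
            fc[(band.name, "OFF")] = FCMatrix(off, band=band, condition="OFF")
            fc[(band.name, "ON")] = FCMatrix(on, band=band, condition="ON")
        subjects.append(
            SubjectRecord(
                id=row["id"],
                age=float(row["age"]),
                gender=str(row["gender"]),
                updrs_on=int(row["updrs_on"]),
                updrs_off=int(row["updrs_off"]),
                t_scores={k: float(row[f"t_{k}"]) for k in T_SCORE_NAMES},
                fc=fc,
            )
        )

    if edges_total and clipped_total / edges_total > 0.20:
        log.warning(
            "planted effects pushed %.1f%% of edges to the [0, 1] bounds",
            100.0 * clipped_total / edges_total,
        )

    # inject the cognition-linked T-score: target correlation with the
    # pattern expression, remaining variance independent noise
    rho = spec.cognition_effect_size
    z = (cog_scores - cog_scores.mean()) / (cog_scores.std() or 1.0)
    eps = _rng(spec.seed, 4).standard_normal(n)
    eps = (eps - eps.mean()) / (eps.std() or 1.0)
    si = 50.0 + 10.0 * (rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * eps)
    meta[f"t_{COGNITION_T_SCORE}"] = np.round(si, 1)
    for s, sub in enumerate(subjects):
        sub.t_scores[COGNITION_T_SCORE] = float(meta.iloc[s][f"t_{COGNITION_T_SCORE}"])

    ground_truth = {
        "responder_labels": responder.astype(bool).tolist(),
        "responder_threshold": spec.responder_threshold,
        "planted_motor_loading": np.asarray(spec.planted_motor_loading).tolist(),
        "motor_band": spec.motor_band,
        "profile_edges": [
            {"band": b, "roi_i": e[0], "roi_j": e[1], "direction": d}
            for b, e, d in spec.profile_edges
        ],
        "cognition_pattern": np.asarray(spec.cognition_pattern).tolist(),
        "cognition_band": spec.cognition_band,
        "cognition_t_score": COGNITION_T_SCORE,
        "cognition_scores": cog_scores.tolist(),
    }
    return SyntheticCohort(
        subjects=subjects,
        bands=tuple(spec.band_set),
        roi_labels=spec.roi_labels(),
        metadata=meta,
        ground_truth=ground_truth,
        spec=spec,
    )


def generate_coupled_timeseries(
    pair_lags: dict,
    n_rois: int,
    n_trials: int = 30,
    fs: float = 1000.0,
    trial_len: float = 3.0,
    band: BandSpec = BandSpec("alpha", 8.0, 12.0),
    snr: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Narrowband coupled oscillators: trials x rois x samples.

    Edges listed in ``pair_lags`` (edge (i, j) -> phase lag in radians) share
    one phase-diffusing generator with a constant offset; all other channels
    carry independent random phase trajectories. White noise is added at
    amplitude ``1/snr`` relative to the unit-amplitude oscillation
    (``snr=np.inf`` for noise-free signals).
    """
    rng = _rng(seed, 5)
    n_samp = int(round(trial_len * fs))
    t = np.arange(n_samp) / fs
    f0 = 0.5 * (band.lo + band.hi)
    out = np.empty((n_trials, n_rois, n_samp))
    # channels coupled to a shared generator, keyed by their offset
    offsets = {}
    for (i, j), lag in pair_lags.items():
        offsets.setdefault(i, 0.0)
        offsets[j] = offsets[i] - lag  # phi_i - phi_j = lag
    for trial in range(n_trials):
        shared = np.cumsum(rng.normal(0.0, 0.05, size=n_samp)) + 2 * np.pi * f0 * t
        for roi in range(n_rois):
            if roi in offsets:
                phase = shared + offsets[roi]
            else:
                phase = (np.cumsum(rng.normal(0.0, 0.3, size=n_samp))
                         + 2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
            x = np.cos(phase)
            if np.isfinite(snr):
                x = x + rng.normal(0.0, 1.0 / snr, size=n_samp)
            out[trial, roi] = x
    return out
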