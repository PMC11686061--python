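"""Nested leave-one-out responder classification from DBS-OFF connectivity.

The procedure sweeps response thresholds on UPDRS_diff (= UPDRS ON - OFF;
a subject is a possibly-optimal responder when UPDRS_diff < threshold),
extracts a connectivity profile from the possibly-optimal training subjects
— the edges whose subset-mean ON-OFF difference deviates at least four
standard deviations from the band's average edge difference — and trains a
linear SVM on the OFF-state values of the profile's edges.

Nested design: the outer loop holds out one test subject; the inner loop
runs a second leave-one-out over the remaining subjects, scoring every
candidate threshold (each distinct observed UPDRS_diff in the inner-train
set) by the mean of the defined confusion metrics aggregated across inner
folds. The winning threshold (ties broken uniformly at random, seeded) is
used to rebuild the profile and SVM on all non-test subjects and classify
the held-out subject. The whole procedure is repeated (default 100 times;
repetition variability stems solely from the seeded random tie-breaking),
metrics are averaged over folds and repetitions, and the most frequent
threshold across folds and repetitions fixes the final reported profile.

The held-out subject never influences profile extraction, threshold choice,
feature standardization, or SVM fitting in its own fold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .stats import ConfusionCounts, confusion_metrics
from .patterns import vectorize_edges

log = logging.getLogger(__name__)

__all__ = [
    "ProfileEntry",
    "ConnectivityProfile",
    "ClassificationReport",
    "label_responders",
    "profile_from_subset",
    "extract_features",
    "inner_threshold_sweep",
    "nested_loocv",
    "cohort_design",
]

SD_RULE = 4.0  # profile edges deviate >= 4 SD from the band's mean difference


@dataclass(frozen=True)
class ProfileEntry:
    band: str
    edge: tuple  # (roi_i, roi_j), i < j
    direction: int  # sign of the subset-mean ON-OFF difference


@dataclass
class ConnectivityProfile:
    entries: tuple
    source_threshold: float

    def __post_init__(self) -> None:
        keys = [(e.band, e.edge) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (band, edge) in connectivity profile")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClassificationReport:
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    final_threshold: float
    final_profile: ConnectivityProfile
    chosen_thresholds: list  # most frequent inner threshold, one per repetition
    fold_counts: list  # ConfusionCounts per (repetition, outer fold)
    repetition_metrics: list = field(default_factory=list)
    n_unclassifiable: int = 0


@dataclass
class _Design:
    """Flat numeric view of a cohort for the classification loops."""

    off: np.ndarray  # subjects x (bands * edges), band-major columns
    diff: np.ndarray  # ON - OFF, same layout
    updrs: np.ndarray  # UPDRS_diff per subject
    band_slices: dict  # band name -> slice into columns
    band_names: tuple
    edge_map: tuple  # (roi_i, roi_j) per within-band edge position


def cohort_design(subjects, bands) -> _Design:
    """Stack per-subject OFF and ON-OFF edge vectors, band-major."""
    band_names = tuple(b if isinstance(b, str) else b.name for b in bands)
    off_rows, diff_rows, updrs = [], [], []
    edge_map = None
    for sub in subjects:
        offs, diffs = [], []
        for name in band_names:
            off_v = vectorize_edges(sub.fc[(name, "OFF")].values)
            on_v = vectorize_edges(sub.fc[(name, "ON")].values)
            offs.append(off_v.values)
            diffs.append(on_v.values - off_v.values)
            edge_map = off_v.index_map
        off_rows.append(np.concatenate(offs))
        diff_rows.append(np.concatenate(diffs))
        updrs.append(sub.updrs_diff)
    n_edges = len(edge_map)
    slices = {
        name: slice(k * n_edges, (k + 1) * n_edges) for k, name in enumerate(band_names)
    }
    return _Design(
        off=np.asarray(off_rows),
        diff=np.asarray(diff_rows),
        updrs=np.asarray(updrs, dtype=float),
        band_slices=slices,
        band_names=band_names,
        edge_map=edge_map,
    )


def label_responders(updrs_diff, threshold: float) -> np.ndarray:
    """True where UPDRS_diff < threshold (optimal = larger improvement)."""
    return np.asarray(updrs_diff, dtype=float) < threshold


def _profile_columns(d_mean: np.ndarray, design: _Design) -> np.ndarray:
    """Column indices passing the 4-SD rule, applied within each band."""
    cols = []
    for name in design.band_names:
        sl = design.band_slices[name]
        d = d_mean[sl]
        sigma = float(d.std())  # population SD over edges within the band
        if sigma == 0.0:
            log.debug("band %s: zero edge-difference SD; no profile edges", name)
            continue
        sel = np.nonzero(np.abs(d - d.mean()) >= SD_RULE * sigma)[0]
        cols.extend(sel + sl.start)
    return np.asarray(cols, dtype=int)


def _columns_to_profile(cols, d_mean, design: _Design, threshold: float) -> ConnectivityProfile:
    n_edges = len(design.edge_map)
    entries = []
    for c in cols:
        band = design.band_names[c // n_edges]
        i, j = design.edge_map[c % n_edges]
        entries.append(ProfileEntry(band=band, edge=(int(i), int(j)),
                                    direction=int(np.sign(d_mean[c]) or 1)))
    return ConnectivityProfile(entries=tuple(entries), source_threshold=threshold)


def profile_from_subset(subjects, subset, bands, threshold: float = float("nan")) -> ConnectivityProfile:
    """Connectivity profile of a possibly-optimal subject subset.

    ``subset`` is an index array into ``subjects``; the profile keeps, per
    band, the edges whose subset-mean ON-OFF difference deviates at least
    four standard deviations from the band's mean edge difference.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    design = cohort_design([subjects[i] for i in subset], bands)
    d_mean = design.diff.mean(axis=0)
    cols = _profile_columns(d_mean, design)
    return _columns_to_profile(cols, d_mean, design, threshold)


def extract_features(subjects, profile: ConnectivityProfile, bands) -> np.ndarray:
    """OFF-state PLI values of the profile's edges, subjects x entries."""
    if len(profile) == 0:
        raise ValueError("empty profile: skip this threshold level")
    out = np.empty((len(subjects), len(profile)))
    for s, sub in enumerate(subjects):
        for k, entry in enumerate(profile.entries):
            i, j = entry.edge
            out[s, k] = sub.fc[(entry.band, "OFF")].values[i, j]
    return out


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Standardize with training statistics and fit a linear SVM."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    clf = LinearSVC(C=C, class_weight="balanced", tol=1e-4, max_iter=5000)
    clf.fit((X - mu) / sd, y)
    return clf, mu, sd

def _score_counts(counts: ConfusionCounts, criterion: str) -> float:
    m = confusion_metrics(counts)
    vals = [v for v in m.values() if np.isfinite(v)]
    if not vals:
        return -np.inf
    if criterion == "mean":
        return float(np.mean(vals))
    if criterion == "harmonic":
        if any(v == 0 for v in vals):
            return 0.0
        return float(len(vals) / np.sum([1.0 / v for v in vals]))
    if criterion == "youden":
        sens = m["sensitivity"] if np.isfinite(m["sensitivity"]) else 0.0
        spec = m["specificity"] if np.isfinite(m["specificity"]) else 0.0
        return float(sens + spec - 1.0)
    raise ValueError(f"unknown criterion {criterion!r}")


def _sweep_fold(
    off: np.ndarray,
    diff: np.ndarray,
    updrs: np.ndarray,
    design: _Design,
    train_idx: np.ndarray,
    held_idx: int,
    per_threshold: "dict[float, ConfusionCounts]",
    C: float,
) -> None:
    """One inner fold: classify ``held_idx`` at every feasible threshold."""
    tr_updrs = updrs[train_idx]
    order = np.argsort(tr_updrs, kind="stable")
    sorted_idx = train_idx[order]
    sorted_updrs = tr_updrs[order]
    # prefix means of the ON-OFF differences in sorted UPDRS order: the
    # possibly-optimal subset at threshold t is always a prefix
    prefix = np.cumsum(diff[sorted_idx], axis=0)
    thresholds = np.unique(tr_updrs)
    for t in thresholds:
        m = int(np.searchsorted(sorted_updrs, t, side="left"))
        labels = sorted_updrs < t
        n_opt = int(labels.sum())
        n_sub = labels.size - n_opt
        if n_opt < 2 or n_sub < 2:
            continue
        d_mean = prefix[m - 1] / m
        cols = _profile_columns(d_mean, design)
        if cols.size == 0:
            continue
        clf, mu, sd = _fit_svm(off[sorted_idx][:, cols], labels, C)
        pred = bool(clf.predict(((off[held_idx, cols] - mu) / sd)[None, :])[0])
        truth = bool(updrs[held_idx] < t)
        key = float(t)
        c = per_threshold.get(key, ConfusionCounts())
        per_threshold[key] = c + ConfusionCounts(
            tp=int(pred and truth),
            fp=int(pred and not truth),
            tn=int(not pred and not truth),
            fn=int(not pred and truth),
        )


def inner_threshold_sweep(
    design: _Design,
    train_idx: np.ndarray,
    rng: np.random.Generator,
    criterion: str = "mean",
    C: float = 1.0,
) -> tuple[float, dict]:
    """Inner leave-one-out threshold sweep over ``train_idx``.

    Returns (best threshold, {threshold: aggregated ConfusionCounts}); the
    best threshold maximizes the criterion over the aggregated inner-fold
    confusion counts, ties broken uniformly at random.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size < 6:
        raise ValueError("need at least 6 training subjects")
    per_threshold: dict[float, ConfusionCounts] = {}
    for k in range(train_idx.size):
        inner_train = np.delete(train_idx, k)
        _sweep_fold(
            design.off, design.diff, design.updrs, design,
            inner_train, int(train_idx[k]), per_threshold, C,
        )
    if not per_threshold:
        raise ValueError("no feasible response threshold in the inner sweep")
    scores = {t: _score_counts(c, criterion) for t, c in per_threshold.items()}
    best = max(scores.values())
    candidates = sorted(t for t, s in scores.items() if s == best)
    chosen = candidates[int(rng.integers(len(candidates)))] if len(candidates) > 1 else candidates[0]
    return float(chosen), per_threshold


def _outer_fold(
    design: _Design,
    test_idx: int,
    rng: np.random.Generator,
    criterion: str,
    C: float,
):
    """Train on all non-test subjects; classify the test subject.

    Returns (threshold, ConfusionCounts or None, profile columns).
    """
    train_idx = np.array([i for i in range(design.updrs.size) if i != test_idx])
    best_t, _ = inner_threshold_sweep(design, train_idx, rng, criterion, C)
    labels = design.updrs[train_idx] < best_t
    subset = train_idx[labels]
    counts = None
    cols = np.empty(0, dtype=int)
    if subset.size == 0 or labels.sum() < 1 or (~labels).sum() < 1:
        log.warning("outer fold %d: degenerate labels at threshold %g", test_idx, best_t)
        return best_t, None, cols, None
    d_mean = design.diff[subset].mean(axis=0)
    cols = _profile_columns(d_mean, design)
    if cols.size == 0:
        log.warning("outer fold %d: empty profile at threshold %g", test_idx, best_t)
        return best_t, None, cols, None
    clf, mu, sd = _fit_svm(design.off[train_idx][:, cols], labels, C)
    pred = bool(clf.predict(((design.off[test_idx, cols] - mu) / sd)[None, :])[0])
    truth = bool(design.updrs[test_idx] < best_t)
    counts = ConfusionCounts(
        tp=int(pred and truth),
        fp=int(pred and not truth),
        tn=int(not pred and not truth),
        fn=int(not pred and truth),
    )
    return best_t, counts, cols, (clf.coef_.copy(), float(clf.intercept_[0]), mu, sd)


def outer_fold_model(subjects, bands, test_idx: int, seed: int = 0,
                     repetition: int = 0, criterion: str = "mean", C: float = 1.0):
    """The fully trained model of one outer fold (for leakage probing).

    Returns (chosen threshold, profile column indices, (coef, intercept,
    feature means, feature SDs) or None). Randomness is keyed only by
    (seed, repetition, fold), never by the data.
    """
    design = cohort_design(subjects, bands)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(repetition, test_idx)))
    best_t, _counts, cols, model = _outer_fold(design, test_idx, rng, criterion, C)
    return best_t, cols, model


def nested_loocv(
    subjects,
    bands,
    repetitions: int = 100,
    seed: int = 0,
    criterion: str = "mean",
    C: float = 1.0,
) -> ClassificationReport:
    """Nested leave-one-out responder classification over a cohort.

    Confusion counts are aggregated across outer folds within a repetition;
    the four metrics are averaged over repetitions, skipping undefined
    (zero-denominator) values. The most frequent threshold across all folds
    and repetitions defines the final reported connectivity profile,
    extracted from the full cohort.
    """
    if len(subjects) < 10:
        raise ValueError("need at least 10 subjects with both conditions")
    design = cohort_design(subjects, bands)
    fold_counts: list = []
    all_thresholds: list[float] = []
    rep_modes: list[float] = []
    rep_metrics: list[dict] = []
    n_unclassifiable = 0
    for rep in range(repetitions):
        rep_counts = ConfusionCounts()
        rep_thresholds = []
        for test_idx in range(len(subjects)):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(rep, test_idx))
            )
            best_t, counts, _cols, _model = _outer_fold(design, test_idx, rng, criterion, C)
            rep_thresholds.append(best_t)
            all_thresholds.append(best_t)
            if counts is None:
                n_unclassifiable += 1
                continue
            fold_counts.append(counts)
            rep_counts = rep_counts + counts
        rep_metrics.append(confusion_metrics(rep_counts))
        mode_count = Counter(rep_thresholds).most_common()
        top = max(c for _, c in mode_count)
        rep_modes.append(min(t for t, c in mode_count if c == top))

    def _avg(key: str) -> float:
        vals = [m[key] for m in rep_metrics if np.isfinite(m[key])]
        return float(np.mean(vals)) if vals else float("nan")

    mode_all = Counter(all_thresholds).most_common()
    top = max(c for _, c in mode_all)
    final_threshold = min(t for t, c in mode_all if c == top)
    subset = np.nonzero(label_responders(design.updrs, final_threshold))[0]
    final_profile = profile_from_subset(subjects, subset, bands, final_threshold)
    return ClassificationReport(
        ppv=_avg("ppv"),
        npv=_avg("npv"),
        sensitivity=_avg("sensitivity"),
        specificity=_avg("specificity"),
        final_threshold=float(final_threshold),
        final_profile=final_profile,
        chosen_thresholds=rep_modes,
        fold_counts=fold_counts,
        repetition_metrics=rep_metrics,
        n_unclassifiable=n_unclassifiable,
    )
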