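"""From source-space ROI time series to phase-lag-index connectivity matrices.

The processing chain mirrors a task EEG pipeline: FFT notch removal of
stimulator-artifact spectral lines on the continuous signal, zero-phase
second-order Butterworth band filtering into six canonical EEG bands,
epoching into 3 s trials around stimulus onsets, extraction of the
200-600 ms post-stimulus window, per-trial PLI between all ROI pairs, and
trial averaging into one FC matrix per subject, band, and condition.

The phase-lag index between channels i and j is
``PLI = | mean_t sign(wrap(phi_i(t) - phi_j(t))) |`` with the phase
difference wrapped into (-pi, pi] and sign(0) = 0, so zero-lag
(volume-conducted) coupling contributes nothing. PLI lies in [0, 1].

Index conventions are 0-based with half-open windows: at 1 kHz the
200-600 ms window of a 3000-sample trial with onset at sample 1000 is
samples 1200..1599. The analytic signal is computed on the full filtered
trial and only then cropped, keeping Hilbert edge artifacts outside the
analysis window. Continuous data are always filtered before epoching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig

log = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "ROITimeSeries",
    "FCMatrix",
    "fft_line_filter",
    "bandpass",
    "epoch",
    "crop_window",
    "pli",
    "pli_from_phases",
    "average_fc",
    "timeseries_to_fc",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with inclusive low and high corners in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band corners ({self.lo}, {self.hi})")


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.1, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("low_gamma", 30.0, 50.0),
    BandSpec("high_gamma", 50.0, 100.0),
)


@dataclass
class ROITimeSeries:
    """Trial-segmented ROI activity: ``data`` is trials x rois x samples."""

    data: np.ndarray
    fs: float = 1000.0
    roi_labels: tuple[str, ...] = ()
    events: tuple = ()  # (onset_sample_within_trial, type) per trial
    condition: str = ""
    onset_index: int = 0  # sample index of stimulus onset within each trial

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x rois x samples")
        if self.roi_labels and len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("roi_labels length must match the ROI axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric zero-diagonal PLI matrix for one band and DBS condition."""

    values: np.ndarray
    band: BandSpec
    condition: str
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > atol):
            raise ValueError("FC matrix diagonal must be zero")
        if np.any((v < -atol) | (v > 1 + atol)):
            bad = np.argwhere((v < -atol) | (v > 1 + atol))[:5]
            raise ValueError(f"FC entries outside [0, 1] at {bad.tolist()}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def fft_line_filter(sig, fs: float, line_freqs, bin_halfwidth: float = 0.5) -> np.ndarray:
    """Zero spectral bins around stimulator-artifact line frequencies.

    Forward FFT, zeroing of all bins within ``bin_halfwidth`` Hz of each line
    (conjugate-symmetric mirrors handled by the real FFT), inverse FFT.
    """
    x = np.asarray(sig, dtype=float)
    if x.ndim != 1:
        raise ValueError("fft_line_filter operates on a single channel")
    line_freqs = list(line_freqs)
    nyq = fs / 2.0
    for f in line_freqs:
        if f >= nyq:
            raise ValueError(f"line frequency {f} Hz is at or above Nyquist ({nyq} Hz)")
    if len(line_freqs) > 5:
        warnings.warn(
            f"{len(line_freqs)} spectral lines suppressed; more than five in one "
            "recording is unusual",
            stacklevel=2,
        )
    if not line_freqs:
        return x.copy()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    for f in line_freqs:
        spec[np.abs(freqs - f) <= bin_halfwidth] = 0.0
    return np.fft.irfft(spec, n=x.size)


def _band_sos(band: BandSpec, fs: float):
    nyq = fs / 2.0
    if band.lo >= nyq:
        raise ValueError(f"band {band.name} lies entirely above Nyquist")
    hi = min(band.hi, nyq * 0.999)
    # second-order-sections form keeps narrow low bands at 1 kHz numerically stable
    return spsig.butter(2, [band.lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(ts: ROITimeSeries, band: BandSpec) -> ROITimeSeries:
    """Zero-phase (forward-backward) order-2 Butterworth bandpass per channel."""
    sos = _band_sos(band, ts.fs)
    out = spsig.sosfiltfilt(sos, ts.data, axis=-1)
    return ROITimeSeries(
        data=out,
        fs=ts.fs,
        roi_labels=ts.roi_labels,
        events=ts.events,
        condition=ts.condition,
        onset_index=ts.onset_index,
    )


def bandpass_continuous(data: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Zero-phase bandpass of continuous rois x samples data."""
    sos = _band_sos(band, fs)
    return spsig.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def epoch(
    continuous: np.ndarray,
    events,
    fs: float = 1000.0,
    pre: float = 1.0,
    post: float = 2.0,
    roi_labels: tuple[str, ...] = (),
    condition: str = "",
) -> ROITimeSeries:
    """Segment continuous rois x samples data into trials around stimuli.

    Each trial spans [-pre, +post) s around the event onset; events without
    full support within the recording are dropped with a log entry.
    """
    x = np.asarray(continuous, dtype=float)
    if x.ndim != 2:
        raise ValueError("continuous data must be rois x samples")
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    trials, kept = [], []
    for onset, etype in events:
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > x.shape[1]:
            log.warning("event at sample %d too close to recording edge; dropped", onset)
            continue
        trials.append(x[:, start:stop])
        kept.append((n_pre, etype))
    if not trials:
        data = np.empty((0, x.shape[0], n_pre + n_post))
    else:
        data = np.stack(trials)
    return ROITimeSeries(
        data=data,
        fs=fs,
        roi_labels=roi_labels,
        events=tuple(kept),
        condition=condition,
        onset_index=n_pre,
    )


def crop_window(
    trial: np.ndarray,
    fs: float = 1000.0,
    onset_index: int = 1000,
    start: float = 0.2,
    stop: float = 0.6,
) -> np.ndarray:
    """The [start, stop) s post-stimulus samples of one rois x samples trial."""
    x = np.asarray(trial)
    i0 = onset_index + int(round(start * fs))
    i1 = onset_index + int(round(stop * fs))
    if i0 < 0 or i1 > x.shape[-1]:
        raise ValueError(
            f"trial of {x.shape[-1]} samples does not contain the "
            f"[{start}, {stop}) s window at onset {onset_index}"
        )
    return x[..., i0:i1]


def _wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    w = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    w[w == -np.pi] = np.pi
    return w


def pli_from_phases(phases: np.ndarray) -> np.ndarray:
    """PLI matrix from instantaneous phases (rois x samples)."""
    ph = np.asarray(phases, dtype=float)
    d = ph[:, None, :] - ph[None, :, :]
    m = np.mean(np.sign(_wrap_phase(d)), axis=-1)
    out = np.abs(m)
    np.fill_diagonal(out, 0.0)
    return out


def pli(window: np.ndarray) -> np.ndarray:
    """Phase-lag index between all channel pairs of a band-limited window.

    Phases come from the analytic (Hilbert) signal of each channel. Constant
    channels have undefined phase; their edges are set to 0 with a warning.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("window must be rois x samples with >= 2 samples")
    sd = x.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn("constant channel(s); their PLI edges set to 0", stacklevel=2)
    phases = np.angle(spsig.hilbert(x, axis=1))
    out = pli_from_phases(phases)
    out[flat, :] = 0.0
    out[:, flat] = 0.0
    return out


def average_fc(matrices: "list[FCMatrix]") -> FCMatrix:
    """Element-wise mean of per-trial FC matrices."""
    if not matrices:
        raise ValueError("cannot average an empty list of FC matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("FC matrices differ in shape")
        if m.band != first.band or m.condition != first.condition:
            raise ValueError("FC matrices differ in band or condition")
    mean = np.mean([m.values for m in matrices], axis=0)
    n = sum(m.n_trials_averaged for m in matrices)
    return FCMatrix(values=mean, band=first.band, condition=first.condition,
                    n_trials_averaged=n)


def timeseries_to_fc(
    recordings: "dict[str, tuple[np.ndarray, list]]",
    bands=CANONICAL_BANDS,
    fs: float = 1000.0,
    roi_labels: tuple[str, ...] = (),
    line_freqs=(),
    bin_halfwidth: float = 0.5,
    target_type: str = "target",
    pre: float = 1.0,
    post: float = 2.0,
    min_target_trials: int = 20,
) -> "dict[tuple[str, str], FCMatrix]":
    """Full per-subject pipeline: continuous data -> band x condition FC map.

    ``recordings`` maps condition ("ON"/"OFF") to (rois x samples array,
    [(onset_sample, type), ...]). The same artifact-line settings are applied
    to every condition of the subject. Only trials of ``target_type`` enter
    the connectivity computation; fewer than ``min_target_trials`` of them
    triggers a warning.
    """
    out: dict[tuple[str, str], FCMatrix] = {}
    for cond, (raw, events) in recordings.items():
        x = np.asarray(raw, dtype=float)
        if line_freqs:
            x = np.stack([fft_line_filter(ch, fs, line_freqs, bin_halfwidth) for ch in x])
        targets = [(o, t) for o, t in events if t == target_type]
        if len(targets) < min_target_trials:
            warnings.warn(
                f"condition {cond}: only {len(targets)} target trials "
                f"(< {min_target_trials})",
                stacklevel=2,
            )
        for band in bands:
            filt = bandpass_continuous(x, fs, band)
            ep = epoch(filt, targets, fs=fs, pre=pre, post=post,
                       roi_labels=roi_labels, condition=cond)
            if ep.n_trials == 0:
                raise ValueError(f"condition {cond}: no usable target trials")
            per_trial = []
            for trial in ep.data:
                phases = np.angle(spsig.hilbert(trial, axis=1))
                win = crop_window(phases, fs=fs, onset_index=ep.onset_index)
                per_trial.append(
                    FCMatrix(pli_from_phases(win), band=band, condition=cond)
                )
            out[(band.name, cond)] = average_fc(per_trial)
    return out
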