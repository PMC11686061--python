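"""Signal chain: line filter, band filter, epoching, windowing, PLI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsnet.connectivity import (
    CANONICAL_BANDS,
    BandSpec,
    FCMatrix,
    average_fc,
    bandpass,
    ROITimeSeries,
    crop_window,
    epoch,
    fft_line_filter,
    pli,
    timeseries_to_fc,
)
from dbsnet.synthetic import generate_coupled_timeseries

FS = 1000.0


def tone(freq, dur=2.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return np.cos(2 * np.pi * freq * t + phase)


class TestLineFilter:
    def test_line_removed(self):
        x = tone(63.0)
        y = fft_line_filter(x, FS, [63.0])
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        assert spec[np.argmin(np.abs(freqs - 63.0))] ** 2 < 1e-10 * np.sum(x**2)

    def test_empty_lines_is_identity(self):
        x = np.random.default_rng(0).normal(size=4096)
        assert np.allclose(fft_line_filter(x, FS, []), x, atol=1e-10)

    def test_other_frequencies_preserved(self):
        x = tone(10.0) + tone(63.0)
        y = fft_line_filter(x, FS, [63.0])
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        a10 = spec[np.argmin(np.abs(freqs - 10.0))]
        ref = np.abs(np.fft.rfft(tone(10.0)))[np.argmin(np.abs(freqs - 10.0))]
        assert a10 == pytest.approx(ref, rel=0.01)

    def test_line_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fft_line_filter(tone(10.0), FS, [600.0])

    def test_more_than_five_lines_warns(self):
        with pytest.warns(UserWarning, match="five"):
            fft_line_filter(tone(10.0), FS, [50, 60, 63, 70, 80, 90])


class TestBandpass:
    def band_ts(self, x):
        return ROITimeSeries(data=x[None, None, :], fs=FS)

    def test_center_tone_preserved_zero_phase(self):
        band = BandSpec("alpha", 8.0, 12.0)
        x = tone(10.0, dur=4.0)
        y = bandpass(self.band_ts(x), band).data[0, 0]
        core = slice(500, 3500)  # avoid filter edges
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.05)
        # zero-phase: cross-correlation peak at zero lag
        xc = np.correlate(y[core], x[core], mode="full")
        assert np.argmax(xc) == len(xc) // 2

    def test_stopband_matches_analytic_two_pass_response(self):
        band = BandSpec("alpha", 8.0, 12.0)
        f_test = 48.0  # 4x the upper corner
        x = tone(f_test, dur=8.0)
        y = bandpass(self.band_ts(x), band).data[0, 0]
        measured = np.max(np.abs(y[2000:6000]))
        # closed-form order-2 Butterworth bandpass magnitude
        # |H(f)|^2 = 1/(1 + u^4) with u = (f^2 - f1 f2)/((f2 - f1) f);
        # the forward-backward pass squares the single-pass amplitude
        u = (f_test**2 - band.lo * band.hi) / ((band.hi - band.lo) * f_test)
        expected = 1.0 / (1.0 + u**4)
        assert measured == pytest.approx(expected, rel=0.1, abs=1e-3)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(self.band_ts(tone(10.0)), BandSpec("x", 600.0, 700.0))


class TestEpochAndWindow:
    def test_ten_events_give_ten_3s_trials(self):
        x = np.random.default_rng(1).normal(size=(3, 50000))
        events = [(2000 + 4200 * k, "target") for k in range(10)]
        ts = epoch(x, events, fs=FS)
        assert ts.data.shape == (10, 3, 3000)
        assert ts.onset_index == 1000

    def test_event_near_edge_dropped(self):
        x = np.zeros((2, 5000))
        ts = epoch(x, [(500, "target"), (3000, "target")], fs=FS)
        assert ts.n_trials == 1

    def test_window_samples_1200_to_1599(self):
        trial = np.arange(3000.0)[None, :]
        win = crop_window(trial, fs=FS, onset_index=1000)
        assert win.shape == (1, 400)
        assert win[0, 0] == 1200 and win[0, -1] == 1599

    def test_window_scales_with_sampling_rate(self):
        trial = np.zeros((2, 1500))
        assert crop_window(trial, fs=500.0, onset_index=500).shape == (2, 200)

    def test_onset_at_start(self):
        trial = np.arange(1000.0)[None, :]
        win = crop_window(trial, fs=FS, onset_index=0)
        assert win[0, 0] == 200 and win.shape[1] == 400

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            crop_window(np.zeros((2, 100)), fs=FS, onset_index=1000)


class TestPLI:
    def test_constant_quarter_cycle_lag_gives_one(self):
        x = np.vstack([tone(10.0, 0.4), tone(10.0, 0.4, phase=-np.pi / 2)])
        assert pli(x)[0, 1] == pytest.approx(1.0)

    def test_zero_lag_gives_zero(self):
        x = tone(10.0, 0.4)
        assert pli(np.vstack([x, x]))[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_random_phases_near_folded_normal_bound(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(30):
            ph = np.cumsum(rng.normal(0, 1.0, size=(2, 400)), axis=1)
            vals.append(np.abs(np.mean(np.sign(np.sin(ph[0] - ph[1])))))
        # E|mean of n random signs| = sqrt(2/(pi n)) ~ 0.04 at n=400
        assert np.mean(vals) < 0.15

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 400))
        gains = np.array([0.1, 3.0, 42.0, 1e-3])[:, None]
        assert np.allclose(pli(x), pli(x * gains), atol=1e-12)

    def test_symmetry_and_range(self):
        x = np.random.default_rng(6).normal(size=(5, 300))
        m = pli(x)
        assert np.allclose(m, m.T)
        assert np.all((m >= 0) & (m <= 1))
        assert np.all(np.diag(m) == 0)

    def test_constant_channel_zeroed_with_warning(self):
        x = np.vstack([tone(10.0, 0.4), np.ones(400)])
        with pytest.warns(UserWarning, match="constant"):
            m = pli(x)
        assert m[0, 1] == 0.0


class TestAverageFC:
    def band(self):
        return CANONICAL_BANDS[2]

    def test_two_matrix_mean(self):
        a = np.array([[0, 0.2], [0.2, 0]])
        b = np.array([[0, 0.6], [0.6, 0]])
        fa = FCMatrix(a, self.band(), "ON")
        fb = FCMatrix(b, self.band(), "ON")
        out = average_fc([fa, fb])
        assert out.values[0, 1] == pytest.approx(0.4)
        assert out.n_trials_averaged == 2

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 12))
    def test_average_preserves_invariants(self, n_mats):
        rng = np.random.default_rng(n_mats)
        mats = []
        for _ in range(n_mats):
            m = np.triu(rng.random((6, 6)), k=1)
            mats.append(FCMatrix(m + m.T, self.band(), "OFF"))
        out = average_fc(mats)
        out.validate()  # symmetry, range, zero diagonal

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_fc([])


class TestFullPipeline:
    def make_recording(self, rng, n_rois=6, n_events=24, lag_edge=None):
        spacing = 4200
        n_samp = spacing * (n_events + 1)
        if lag_edge:
            data = generate_coupled_timeseries(
                {lag_edge: np.pi / 2}, n_rois=n_rois, n_trials=1,
                fs=FS, trial_len=n_samp / FS,
                band=BandSpec("alpha", 8.0, 12.0), snr=10.0, seed=1,
            )[0]
        else:
            data = rng.normal(size=(n_rois, n_samp))
        events = [(spacing * (k + 1), "target") for k in range(n_events)]
        return data, events

    def test_planted_lag_edge_is_maximal(self):
        rng = np.random.default_rng(7)
        rec = {"ON": self.make_recording(rng, lag_edge=(2, 4))}
        out = timeseries_to_fc(rec, bands=[BandSpec("alpha", 8.0, 12.0)], fs=FS)
        m = out[("alpha", "ON")].values
        iu = np.triu_indices(6, k=1)
        assert (m[2, 4]) == pytest.approx(m[iu].max())

    def test_noise_fixture_low_pli_wide_band(self):
        # The mean PLI between independent channels is bounded by the folded-
        # normal mean over the effective number of independent phase stretches
        # (window x bandwidth); for the 50 Hz wide high-gamma band and a
        # 400 ms window that is sqrt(2/(pi*20)) ~ 0.18. Narrow low bands mix
        # too slowly within the window for any such bound to apply.
        rng = np.random.default_rng(8)
        rec = {"OFF": self.make_recording(rng)}
        out = timeseries_to_fc(rec, bands=[BandSpec("high_gamma", 50.0, 100.0)], fs=FS)
        m = out[("high_gamma", "OFF")].values
        iu = np.triu_indices(6, k=1)
        assert m[iu].mean() < 0.25

    def test_low_trial_count_warns(self):
        rng = np.random.default_rng(9)
        data, events = self.make_recording(rng, n_events=5)
        with pytest.warns(UserWarning, match="target trials"):
            timeseries_to_fc({"ON": (data, events)},
                             bands=[BandSpec("alpha", 8.0, 12.0)], fs=FS)

    def test_one_band_one_condition_pair(self):
        rng = np.random.default_rng(10)
        rec = {"ON": self.make_recording(rng), "OFF": self.make_recording(rng)}
        out = timeseries_to_fc(rec, bands=[BandSpec("beta", 12.0, 30.0)], fs=FS)
        assert set(out) == {("beta", "ON"), ("beta", "OFF")}
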