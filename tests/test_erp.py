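"""EEG preprocessing, epoching, peaks, and difference waves."""

import numpy as np
import pandas as pd
import pytest

from mobipipe.erp import (
    average_reference,
    bandpass,
    detect_and_interpolate_bad,
    difference_wave,
    epoch,
    find_peak,
    grand_average,
    spline_interpolation_matrix,
    topo_segments,
    two_pass_peak_windows,
)
from mobipipe.io_core import Recording

RATE = 512.0


def _recording(samples, labels=None):
    samples = np.atleast_2d(samples)
    labels = labels or [f"ch{i}" for i in range(samples.shape[0])]
    return Recording(samples, RATE, labels)


def _fft_amplitude(x, freq):
    n = len(x)
    spec = np.abs(np.fft.rfft(x * np.hanning(n))) / n * 4
    freqs = np.fft.rfftfreq(n, 1 / RATE)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestBandpass:
    def test_dc_rejected(self):
        rec = _recording(np.full((2, 4096), 10.0))
        out = bandpass(rec)
        trim = out.samples[:, 1024:-1024]
        assert np.abs(trim).max() < 0.1

    def test_60hz_attenuated_20db(self):
        t = np.arange(8192) / RATE
        rec = _recording(np.sin(2 * np.pi * 60 * t))
        out = bandpass(rec)
        a_in = _fft_amplitude(rec.samples[0], 60)
        a_out = _fft_amplitude(out.samples[0], 60)
        assert 20 * np.log10(a_in / a_out) >= 20

    def test_10hz_passband_amplitude_and_zero_phase(self):
        t = np.arange(8192) / RATE
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass(_recording(x))
        mid = slice(2048, 6144)
        amp = _fft_amplitude(out.samples[0][mid], 10) / \
            _fft_amplitude(x[mid], 10)
        assert amp == pytest.approx(1.0, abs=0.05)
        # zero-phase: cross-correlation peak at zero lag (< 1 ms shift)
        xc = np.correlate(out.samples[0][mid], x[mid], "full")
        lag = np.argmax(xc) - (len(x[mid]) - 1)
        assert abs(lag) / RATE * 1000 < 1.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_recording(np.zeros((1, 100))), 40, 0.25)


class TestAverageReference:
    def test_column_means_zero(self, rng):
        rec = _recording(rng.normal(0, 10, (8, 1000)))
        out = average_reference(rec)
        np.testing.assert_allclose(out.samples.mean(axis=0), 0, atol=1e-9)

    def test_idempotent(self, rng):
        rec = _recording(rng.normal(0, 10, (8, 1000)))
        once = average_reference(rec)
        twice = average_reference(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            average_reference(_recording(np.zeros((1, 100))))


class TestBadChannels:
    def _dipolar(self, layout, rng, n=2048):
        """Smooth dipolar field times a random time course, plus small noise."""
        names = list(layout)
        pos = np.array([layout[ch] for ch in names])
        field = pos @ np.array([0.5, 1.0, 0.3])
        tc = np.sin(2 * np.pi * 5 * np.arange(n) / RATE)
        data = 10 * np.outer(field, tc) + rng.normal(0, 1.0, (len(names), n))
        return Recording(data, RATE, names)

    def test_clean_data_has_empty_bad_list(self, layout, rng):
        rec = self._dipolar(layout, rng)
        _out, bad = detect_and_interpolate_bad(rec, layout)
        assert bad == []

    def test_noise_blasted_channel_flagged(self, layout, rng):
        rec = self._dipolar(layout, rng)
        i = rec.channel_labels.index("Pz")
        rec.samples[i] = rng.normal(0, 100, rec.n_samples)
        out, bad = detect_and_interpolate_bad(rec, layout)
        assert bad == ["Pz"]
        assert out.samples[i].std() < 30

    def test_interpolation_recovers_smooth_field(self, layout, rng):
        rec = self._dipolar(layout, rng)
        i = rec.channel_labels.index("Cz")
        clean = 10 * (layout["Cz"] @ np.array([0.5, 1.0, 0.3])) * \
            np.sin(2 * np.pi * 5 * np.arange(rec.n_samples) / RATE)
        rec.samples[i] = 0.0
        out, bad = detect_and_interpolate_bad(rec, layout)
        assert bad == ["Cz"]
        rms_err = np.sqrt(np.mean((out.samples[i] - clean) ** 2))
        rms_clean = np.sqrt(np.mean(clean**2))
        assert rms_err < 0.10 * rms_clean

    def test_quality_floor(self, layout, rng):
        rec = self._dipolar(layout, rng)
        rec.samples[:20] = rng.normal(0, 500, (20, rec.n_samples))
        with pytest.raises(ValueError, match="quality floor"):
            detect_and_interpolate_bad(rec, layout)

    def test_spline_matrix_agrees_loosely_with_reference(self, layout):
        # cross-check against an independent spherical-spline implementation
        from mne.channels.interpolation import _make_interpolation_matrix

        names = list(layout)
        pos = np.array([layout[ch] for ch in names])
        good, bad = pos[:60], pos[60:]
        ours = spline_interpolation_matrix(good, bad)
        theirs = _make_interpolation_matrix(good, bad)
        field = good @ np.array([0.3, 0.9, 0.2])
        np.testing.assert_allclose(ours @ field, theirs @ field, atol=0.05)


class TestEpoching:
    def test_sample_span_convention(self):
        data = np.zeros((1, 2000))
        data[0, 949] = 1.0      # first sample of the epoch
        data[0, 1409] = 2.0     # last sample of the epoch
        data[0, 948] = -5.0     # just outside
        data[0, 1410] = -5.0
        rec = _recording(data)
        es = epoch(rec, [1000], baseline=False)
        assert es.data.shape == (1, 1, 461)
        assert es.data[0, 0, 0] == 1.0
        assert es.data[0, 0, -1] == 2.0
        assert -5.0 not in es.data

    def test_window_is_900ms_461_samples(self, rng):
        rec = _recording(rng.normal(0, 1, (2, 3000)))
        es = epoch(rec, [1000])
        assert es.data.shape[-1] == 461
        assert es.time_ms[0] == pytest.approx(-51 / 512 * 1000)
        assert es.time_ms[-1] == pytest.approx(409 / 512 * 1000)

    def test_baseline_mean_zero(self, rng):
        rec = _recording(rng.normal(3, 1, (4, 3000)))
        es = epoch(rec, [1000, 1500])
        bmask = es.time_ms <= 0
        np.testing.assert_allclose(
            es.data[:, :, bmask].mean(axis=2), 0, atol=1e-9)

    def test_out_of_bounds_trials_dropped_with_warning(self, rng):
        rec = _recording(rng.normal(0, 1, (1, 2000)))
        meta = pd.DataFrame({"subject": ["a", "b"]})
        with pytest.warns(UserWarning, match="dropped 1 epoch"):
            es = epoch(rec, [1000, 1995], metadata=meta)
        assert es.n_trials == 1
        assert list(es.metadata["subject"]) == ["a"]


class TestGrandAverage:
    def _epochs(self, waves, meta):
        data = np.stack(waves)[:, None, :]
        time = np.linspace(-100, 800, data.shape[-1])
        return __import__("mobipipe.erp", fromlist=["EpochSet"]).EpochSet(
            data, time, ["Cz"], pd.DataFrame(meta))

    def test_identical_trials_average_to_any_trial(self):
        wave = np.sin(np.linspace(0, 6, 461))
        es = self._epochs([wave] * 4, {
            "subject": ["a", "a", "b", "b"], "group": ["G"] * 4,
            "condition": ["c"] * 4, "response_type": ["Hit"] * 4})
        out = grand_average(es)
        np.testing.assert_allclose(out[("G", "c", "Hit")]["waveform"][0],
                                   wave)
        assert out[("G", "c", "Hit")]["n_subjects"] == 2

    def test_equal_and_opposite_trials_cancel(self):
        wave = np.sin(np.linspace(0, 6, 461))
        es = self._epochs([wave, -wave], {
            "subject": ["a", "b"], "group": ["G"] * 2,
            "condition": ["c"] * 2, "response_type": ["Hit"] * 2})
        out = grand_average(es)
        np.testing.assert_allclose(out[("G", "c", "Hit")]["waveform"], 0,
                                   atol=1e-12)

    def test_subject_then_group_weighting(self):
        # subject a contributes 3 trials of +3, subject b one trial of +1:
        # trial pooling would give 2.5, subject-first averaging gives 2.0
        es = self._epochs([np.full(461, 3.0)] * 3 + [np.full(461, 1.0)], {
            "subject": ["a", "a", "a", "b"], "group": ["G"] * 4,
            "condition": ["c"] * 4, "response_type": ["Hit"] * 4})
        out = grand_average(es)
        np.testing.assert_allclose(out[("G", "c", "Hit")]["waveform"], 2.0)


class TestPeaks:
    def _bump(self, amp, center_ms, sd=20.0):
        t = np.linspace(-100, 800, 461)
        return t, amp * np.exp(-((t - center_ms) ** 2) / (2 * sd**2))

    def test_positive_bump(self):
        t, w = self._bump(5.0, 240.0)
        peak = find_peak(w, t, (200, 280), 1)
        assert peak.peak_amplitude_uv == pytest.approx(5.0, abs=0.01)
        assert peak.peak_latency_ms == pytest.approx(240.0, abs=2.0)
        assert not peak.at_edge

    def test_negative_bump_with_n2_polarity(self):
        t, w = self._bump(-4.0, 320.0)
        peak = find_peak(w, t, (280, 380), -1)
        assert peak.peak_amplitude_uv == pytest.approx(-4.0, abs=0.01)
        assert peak.peak_latency_ms == pytest.approx(320.0, abs=2.0)

    def test_monotone_ramp_flags_edge(self):
        t = np.linspace(-100, 800, 461)
        peak = find_peak(t.copy(), t, (200, 280), 1)
        assert peak.at_edge
        assert peak.peak_latency_ms == pytest.approx(280, abs=2.0)

    def test_two_pass_windows_around_group_latency(self):
        layout_names = ["FCz", "CPz"]
        t = np.linspace(-100, 800, 461)
        fcz = (4 * np.exp(-((t - 244) ** 2) / (2 * 20**2))
               - 3 * np.exp(-((t - 320) ** 2) / (2 * 25**2)))
        cpz = 6 * np.exp(-((t - 405) ** 2) / (2 * 40**2))
        wins = two_pass_peak_windows(np.vstack([fcz, cpz]), t, layout_names)
        lo, hi = wins["P2"]["window_ms"]
        assert (lo, hi) == (pytest.approx(219, abs=2), pytest.approx(269, abs=2))
        lo, hi = wins["P3"]["window_ms"]
        assert (lo, hi) == (pytest.approx(355, abs=2), pytest.approx(455, abs=2))

    def test_flat_average_has_no_identifiable_peak(self):
        t = np.linspace(-100, 800, 461)
        with pytest.raises(ValueError, match="flat"):
            find_peak(np.zeros(461), t, (200, 280), 1)

    def test_peak_recovery_across_seeded_runs(self):
        """Injected latency within 4 ms, amplitude within 2 SE, 20 seeds.

        The full 50-seed sweep runs in the acceptance suite; this spot
        check keeps the unit suite fast.
        """
        from helpers import erp_peak_recovery_errors

        amp_errors, lat_errors, se = erp_peak_recovery_errors(n_seeds=20)
        assert np.max(np.abs(lat_errors)) <= 4.0
        assert abs(np.mean(amp_errors)) <= 2 * se
        assert np.max(np.abs(amp_errors)) <= 4 * se


class TestDifferenceWaves:
    def test_zero_for_identical_inputs(self, rng):
        w = rng.normal(0, 1, (4, 461))
        np.testing.assert_array_equal(difference_wave(w, w), 0 * w)

    def test_antisymmetry(self, rng):
        cr = rng.normal(0, 1, (4, 461))
        hit = rng.normal(0, 1, (4, 461))
        np.testing.assert_allclose(difference_wave(cr, hit),
                                   -difference_wave(hit, cr))

    def test_constant_wave_constant_bins(self):
        w = np.full((3, 461), 2.0)
        t = np.linspace(-100, 800, 461)
        means, edges = topo_segments(w, t)
        assert means.shape == (10, 3)
        np.testing.assert_allclose(means, 2.0)
        assert edges[0] == 100.0 and edges[-1] == 600.0


def test_pipeline_linearity_scaling(rng):
    """Scaling input voltages by c scales averages and difference waves by c."""
    data = rng.normal(0, 5, (6, 2, 461))
    t = np.linspace(-100, 800, 461)
    from mobipipe.erp import EpochSet

    meta = pd.DataFrame({
        "subject": ["a", "a", "b", "b", "c", "c"],
        "group": ["G"] * 6, "condition": ["c"] * 6,
        "response_type": ["Hit", "CR"] * 3})
    es1 = EpochSet(data, t, ["Cz", "Pz"], meta)
    es2 = EpochSet(3.0 * data, t, ["Cz", "Pz"], meta)
    g1 = grand_average(es1)
    g2 = grand_average(es2)
    for key in g1:
        np.testing.assert_allclose(3.0 * g1[key]["waveform"],
                                   g2[key]["waveform"], rtol=1e-12)
    d1 = difference_wave(g1[("G", "c", "CR")]["waveform"],
                         g1[("G", "c", "Hit")]["waveform"])
    d2 = difference_wave(g2[("G", "c", "CR")]["waveform"],
                         g2[("G", "c", "Hit")]["waveform"])
    np.testing.assert_allclose(3.0 * d1, d2, rtol=1e-12)
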