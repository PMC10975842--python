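"""Amplitude, spectral and matching metrics: identities and toy cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonecg.fiducials import MatchReport, match_fiducials
from sonecg.metrics import (carrier_peaks, normalized_psd_error, prd, rmse,
                            spectrogram)
from sonecg.records import AudioStream, Fiducial


class TestRMSE:
    def test_identical_signals_give_zero(self):
        x = np.array([1.0, -2.0, 3.0])
        assert rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros(100)
        assert rmse(x, x + 5.0) == pytest.approx(5.0)

    def test_hand_computed_case(self):
        # sqrt(((3-0)^2 + (4-0)^2) / 2) = 5 / sqrt(2)
        assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == \
            pytest.approx(5.0 / np.sqrt(2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse(np.zeros(3), np.zeros(4))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 50))
        assert rmse(x, y) == rmse(y, x) >= 0.0


class TestPRD:
    def test_identity_reconstruction(self):
        x = np.sin(np.linspace(0, 10, 300))
        assert prd(x, x) == 0.0

    def test_zero_reconstruction_is_100_percent(self):
        x = np.sin(np.linspace(0, 10, 300))
        assert prd(np.zeros_like(x), x) == pytest.approx(100.0)

    def test_scaling_identity(self):
        x = np.sin(np.linspace(0, 10, 300))
        assert prd(1.1 * x, x) == pytest.approx(10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            prd(np.ones(10), np.zeros(10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.01, 5.0), seed=st.integers(0, 1000))
    def test_scale_factor_maps_to_percent(self, alpha, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200) + 0.1
        assert prd(alpha * x, x) == pytest.approx(abs(alpha - 1) * 100.0,
                                                  rel=1e-9)


class TestPSDError:
    def test_identical_signals_zero_everywhere(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2500)
        res = normalized_psd_error(x, x, fs=250.0)
        np.testing.assert_array_equal(res.error_pct, 0.0)
        assert res.freqs_hz[-1] <= 100.0
        assert res.freqs_hz[1] - res.freqs_hz[0] == pytest.approx(0.2)

    def test_sinusoid_versus_zero_is_100_at_peak(self):
        t = np.arange(2500) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        res = normalized_psd_error(x, np.zeros_like(x), fs=250.0)
        peak_bin = np.argmax(res.psd_x)
        assert res.freqs_hz[peak_bin] == pytest.approx(10.0, abs=0.2)
        assert res.error_pct[peak_bin] == pytest.approx(100.0)

    def test_half_amplitude_gives_75_percent_peak_error(self):
        t = np.arange(5000) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        res = normalized_psd_error(x, 0.5 * x, fs=250.0)
        peak_bin = np.argmax(res.psd_x)
        assert res.error_pct[peak_bin] == pytest.approx(75.0, abs=0.5)

    def test_error_bounded_by_construction(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 3000))
        res = normalized_psd_error(x, y, fs=300.0)
        assert np.all(res.error_pct >= 0.0)
        assert np.all(res.error_pct <= 100.0)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="short"):
            normalized_psd_error(np.zeros(100), np.zeros(100), fs=250.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            normalized_psd_error(np.zeros(5000), np.zeros(5000), fs=150.0)


class TestSpectrogram:
    def test_ten_second_stream_gives_19_frames(self, zero_sonified):
        _, t, mag = spectrogram(zero_sonified)
        assert mag.shape[1] == 19

    def test_zero_ecg_sonification_shows_carrier_ridges(self, zero_sonified):
        f, _, mag = spectrogram(zero_sonified)
        mean_mag = mag.mean(axis=1)
        floor = 0.05 * mean_mag.max()
        ridge_freqs = f[mean_mag > floor]
        clusters = np.split(ridge_freqs,
                            np.nonzero(np.diff(ridge_freqs) > 50)[0] + 1)
        centers = np.array([c.mean() for c in clusters])
        np.testing.assert_allclose(
            centers, (450, 750, 1050, 1350, 1650, 1950, 2250, 2550), atol=5)

    def test_pure_tone_single_ridge(self):
        fs = 11_000.0
        t = np.arange(22_000) / fs
        stream = AudioStream(np.sin(2 * np.pi * 1000.0 * t), fs)
        f, _, mag = spectrogram(stream)
        assert f[np.argmax(mag.mean(axis=1))] == pytest.approx(1000.0, abs=1)

    def test_too_short_audio_rejected(self):
        with pytest.raises(ValueError, match="short"):
            spectrogram(AudioStream(np.zeros(1000), 11_000.0))


def _set(times_ms, lead="II", wave="R-peak"):
    return [Fiducial(lead, wave, t) for t in times_ms]


class TestMatching:
    def test_match_within_tolerance(self):
        rep = match_fiducials(_set([1000.0]), _set([1040.0]))
        tp, fp, fn = rep.counts()
        assert (tp, fp, fn) == (1, 0, 0)
        assert rep.mad_ms()[0] == pytest.approx(40.0)

    def test_outside_tolerance_counts_fn_and_fp(self):
        rep = match_fiducials(_set([1000.0]), _set([1060.0]))
        assert rep.counts() == (0, 1, 1)

    def test_hand_computed_assignment(self):
        rep = match_fiducials(_set([1000.0, 2000.0]),
                              _set([1010.0, 1990.0, 3000.0]))
        tp, fp, fn = rep.counts()
        assert (tp, fp, fn) == (2, 1, 0)
        assert rep.mad_ms()[0] == pytest.approx(10.0)
        assert rep.sensitivity() == pytest.approx(100.0)
        assert rep.ppv() == pytest.approx(100.0 * 2 / 3)

    def test_se_ppv_arithmetic_on_constructed_counts(self):
        rep = MatchReport(tol_ms=50.0,
                          pairs={("II", "R-peak"): [(0.0, 0.0)] * 9},
                          fn={("II", "R-peak"): 1},
                          fp={("II", "R-peak"): 0})
        assert rep.sensitivity() == pytest.approx(90.0)
        assert rep.ppv() == pytest.approx(100.0)

    def test_one_to_one_consumption(self):
        # two test points near one reference: only one may match
        rep = match_fiducials(_set([1000.0]), _set([990.0, 1010.0]))
        assert rep.counts() == (1, 1, 0)

    def test_leads_and_waves_do_not_cross_match(self):
        ref = _set([1000.0], lead="I") + _set([1000.0], wave="T-peak")
        test = _set([1000.0], lead="V3")
        rep = match_fiducials(ref, test)
        assert rep.counts() == (0, 1, 2)

    def test_empty_sets_give_undefined_rates(self):
        rep = match_fiducials([], [])
        assert np.isnan(rep.sensitivity())
        assert np.isnan(rep.ppv())


def test_carrier_peaks_on_zero_sonification(zero_sonified):
    peaks = carrier_peaks(zero_sonified)
    np.testing.assert_allclose(
        peaks, (450, 750, 1050, 1350, 1650, 1950, 2250, 2550), atol=1e-9)
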