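"""FM modulator: modulation law, band layout, audio stream contract."""

import numpy as np
import pytest

from sonecg.fm import (DEFAULT_CARRIERS_HZ, FMConfig, instantaneous_frequency,
                       modulate_lead, sonify)
from sonecg.records import CANONICAL_8, ECGRecord


@pytest.mark.parametrize("amp_mv,lead,expected_hz", [
    (0.0, 0, 450.0),       # lead I at baseline sits on its carrier
    (2.5, 0, 575.0),       # full-scale positive swing: +deviation
    (1.0, 1, 800.0),       # 50 Hz/mV modulation index on lead II
    (-2.5, 7, 2425.0),     # full-scale negative swing on V6
])
def test_instantaneous_frequency_law(amp_mv, lead, expected_hz):
    assert instantaneous_frequency(amp_mv, lead) == pytest.approx(expected_hz)


def test_instantaneous_frequency_lead_out_of_range():
    with pytest.raises(IndexError):
        instantaneous_frequency(0.0, 8)


def _tone_spectrum(samples, fs):
    spec = np.abs(np.fft.rfft(samples))
    freqs = np.fft.rfftfreq(samples.size, 1.0 / fs)
    return freqs, spec


@pytest.mark.parametrize("amp_mv,expected_hz", [(0.0, 450.0), (2.5, 575.0)])
def test_constant_input_gives_pure_tone(amp_mv, expected_hz):
    cfg = FMConfig()
    n = 110_000
    s = modulate_lead(np.full(n, amp_mv), 0, cfg)
    freqs, spec = _tone_spectrum(s, cfg.audio_fs)
    peak = np.argmax(spec)
    assert freqs[peak] == pytest.approx(expected_hz, abs=0.1)
    # sidebands below -60 dB relative to the carrier line
    mask = np.abs(freqs - freqs[peak]) > 5.0
    assert np.max(spec[mask]) < 1e-3 * spec[peak]
    assert np.max(np.abs(s)) <= cfg.carrier_amp + 1e-12


def test_zero_record_sonification_shows_exactly_eight_carriers(zero_sonified):
    freqs, spec = _tone_spectrum(zero_sonified.samples, zero_sonified.fs)
    floor = 1e-3 * np.max(spec)
    strong = freqs[spec > floor]
    clusters = np.split(strong, np.nonzero(np.diff(strong) > 50)[0] + 1)
    centers = [c.mean() for c in clusters]
    np.testing.assert_allclose(centers, DEFAULT_CARRIERS_HZ, atol=0.2)


def test_sonify_output_length_and_bound(sonified):
    assert sonified.n_samples == 110_000
    assert sonified.fs == 11_000.0
    assert np.max(np.abs(sonified.samples)) <= 1.0


def test_sonify_rejects_non_canonical_records():
    rec = ECGRecord(np.zeros((3, 100)), 250.0, ("I", "II", "V1"))
    with pytest.raises(ValueError, match="canonical"):
        sonify(rec)


def test_guard_band_is_50_hz():
    cfg = FMConfig()
    assert cfg.guard_gap_hz() == pytest.approx(50.0)
    for lo, hi in zip(range(7), range(1, 8)):
        top = instantaneous_frequency(cfg.amp_range_mv, lo, cfg)
        bottom = instantaneous_frequency(-cfg.amp_range_mv, hi, cfg)
        assert bottom - top == pytest.approx(50.0)


def test_instantaneous_frequency_confined_to_band():
    cfg = FMConfig()
    amps = np.linspace(-cfg.amp_range_mv, cfg.amp_range_mv, 101)
    for lead, carrier in enumerate(cfg.carriers_hz):
        f = instantaneous_frequency(amps, lead, cfg)
        assert np.all(f >= carrier - cfg.deviation_hz - 1e-9)
        assert np.all(f <= carrier + cfg.deviation_hz + 1e-9)


@pytest.mark.parametrize("kwargs,match", [
    ({"carriers_hz": (450, 650)}, "overlap"),          # spacing < 2*F_D
    ({"carrier_amp": 0.2}, "WAV-safe"),                # 8 * 0.2 > 1
    ({"audio_fs": 5000.0}, "Nyquist"),                 # 2550+125 >= 2500
    ({"carriers_hz": (750, 450, 1050, 1350, 1650, 1950, 2250, 2550)},
     "increasing"),
])
def test_invalid_fm_configs_rejected(kwargs, match):
    with pytest.raises(ValueError, match=match):
        FMConfig(**kwargs)


def test_sonification_is_time_equivariant():
    """Delaying the ECG delays the demodulated output by the same amount."""
    from sonecg.demod_dsp import demodulate, trim_edges
    fs = 250.0
    t = np.arange(2500) / fs
    x = np.zeros((8, 2500))
    x[1] = np.exp(-0.5 * ((t - 4.0) / 0.05) ** 2)  # single bump on lead II
    shift = 125  # 0.5 s at 250 Hz
    rec = ECGRecord(x, fs, CANONICAL_8)
    rec_shifted = ECGRecord(np.roll(x, shift, axis=1), fs, CANONICAL_8)
    d = trim_edges(demodulate(sonify(rec)).samples[1], fs)
    ds = trim_edges(demodulate(sonify(rec_shifted)).samples[1], fs)
    assert int(np.argmax(ds)) - int(np.argmax(d)) == shift
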