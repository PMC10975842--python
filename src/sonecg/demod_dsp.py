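"""Classical FM demodulation of the sonified ECG stream.

A training-free, reference-quality inverse of the modulator: each lead's
band is isolated with a zero-phase band-pass filter, converted to its
analytic signal, and the instantaneous frequency is read off the phase
derivative.  Inverting the modulation law

    ecg_L[n] = (f_inst[n] - F_C^L) * A_R / F_D       [mV]

recovers the lead amplitude, which is then anti-alias filtered and
decimated to the output ECG rate.  This demodulator serves as the
verification baseline for the trained CNN and for cross-talk measurements;
it is not constrained to be causal or lightweight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .fm import FMConfig
from .records import CANONICAL_8, AudioStream, ECGRecord

#: Leading/trailing span dominated by filter transients; excluded from
#: round-trip error metrics.
EDGE_TRANSIENT_S = 0.1


@dataclass
class BandSpec:
    """One lead's FM band: centre frequency and half-width in Hz."""

    center_hz: float
    half_width_hz: float = 150.0
    lead_index: int = 0

    def validate(self, fs: float) -> None:
        if self.center_hz - self.half_width_hz <= 0:
            raise ValueError("band extends below 0 Hz")
        if self.center_hz + self.half_width_hz >= fs / 2:
            raise ValueError(
                f"band {self.center_hz}+/-{self.half_width_hz} Hz exceeds "
                f"Nyquist {fs / 2} Hz")


def bands_from_config(config: FMConfig) -> list:
    """Disjoint band specs covering each carrier +/- (F_D + guard/2)."""
    half = config.deviation_hz + config.guard_gap_hz() / 2.0
    return [BandSpec(c, half, i) for i, c in enumerate(config.carriers_hz)]


def isolate_band(audio: AudioStream, band: BandSpec) -> np.ndarray:
    """Band-pass one FM band and return its complex analytic signal.

    Uses a zero-phase 5th-order Butterworth band-pass (10th-order magnitude
    response after forward-backward application) so adjacent carriers
    300 Hz away are suppressed by more than 40 dB.
    """
    band.validate(audio.fs)
    lo = band.center_hz - band.half_width_hz
    hi = band.center_hz + band.half_width_hz
    sos = sps.butter(5, [lo, hi], btype="bandpass", fs=audio.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, audio.samples)
    return sps.hilbert(filtered)


def _instantaneous_frequency_hz(analytic: np.ndarray, fs: float,
                                smooth_samples: int = 23) -> np.ndarray:
    """Discrete phase-difference discriminator with short moving average."""
    phase = np.unwrap(np.angle(analytic))
    f_inst = np.gradient(phase) * fs / (2.0 * np.pi)
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        pad = smooth_samples // 2
        padded = np.pad(f_inst, pad, mode="edge")
        f_inst = np.convolve(padded, kernel, mode="same")[pad:pad + f_inst.size]
    return f_inst


def demodulate(audio: AudioStream, config: FMConfig = None,
               out_fs: float = 250.0) -> ECGRecord:
    """Demodulate all eight bands of a sonified stream back to an ECG record.

    Returns a canonical 8-lead :class:`ECGRecord` in mV at ``out_fs``.  The
    first and last 100 ms are dominated by filter transients and should be
    trimmed before computing error metrics (see ``EDGE_TRANSIENT_S``).
    """
    config = config or FMConfig()
    min_samples = int(0.25 * audio.fs)
    if audio.n_samples < min_samples:
        raise ValueError(
            f"audio too short for band filtering: {audio.n_samples} samples "
            f"(< {min_samples})")
    if abs(audio.fs - config.audio_fs) > 1e-6:
        raise ValueError(
            f"audio at {audio.fs} Hz but config expects {config.audio_fs} Hz")
    n_out = int(round(audio.duration_s * out_fs))
    up, down = _resample_ratio(out_fs, audio.fs)
    leads = []
    for band in bands_from_config(config):
        analytic = isolate_band(audio, band)
        f_inst = _instantaneous_frequency_hz(analytic, audio.fs)
        amp_mv = (f_inst - band.center_hz) * config.amp_range_mv \
            / config.deviation_hz
        # polyphase anti-alias decimation to the ECG rate
        y = sps.resample_poly(amp_mv, up, down, padtype="line")
        if y.size < n_out:
            y = np.pad(y, (0, n_out - y.size), mode="edge")
        leads.append(y[:n_out])
    return ECGRecord(np.vstack(leads), out_fs, CANONICAL_8, units="mV")


def _resample_ratio(fs_out: float, fs_in: float):
    from math import gcd
    a, b = int(round(fs_out * 1000)), int(round(fs_in * 1000))
    g = gcd(a, b)
    return a // g, b // g


def trim_edges(x: np.ndarray, fs: float,
               edge_s: float = EDGE_TRANSIENT_S) -> np.ndarray:
    """Drop ``edge_s`` seconds from both ends (transient exclusion)."""
    k = int(round(edge_s * fs))
    return x[..., k:x.shape[-1] - k] if k > 0 else x
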