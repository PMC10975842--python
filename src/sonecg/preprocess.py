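"""Monitoring-band conditioning: Butterworth filtering, clipping, resampling.

The patient-module front end is modelled as a cascade of two first-order
Butterworth sections — a 0.64 Hz high-pass rejecting baseline wander and a
30 Hz low-pass attenuating muscle artifact — applied causally, the way
analog hardware would.  Rate conversion uses Fourier-method resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .records import ECGRecord


@dataclass
class FilterSpec:
    """Monitoring bandwidth filter: ``hp_cutoff``..``lp_cutoff`` Hz passband."""

    hp_cutoff: float = 0.64
    lp_cutoff: float = 30.0
    order: int = 1
    causal: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ValueError(
                f"need 0 < hp_cutoff < lp_cutoff, got "
                f"{self.hp_cutoff}/{self.lp_cutoff}")
        if self.lp_cutoff >= fs / 2:
            raise ValueError(
                f"lp_cutoff {self.lp_cutoff} Hz >= Nyquist {fs / 2} Hz")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def monitoring_filter(record: ECGRecord, spec: FilterSpec = None) -> ECGRecord:
    """Apply the high-pass/low-pass Butterworth cascade to every lead.

    Causal (single-pass) by default, simulating hardware filters; set
    ``spec.causal = False`` for zero-phase (forward-backward) filtering.
    """
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    b_hp, a_hp = sps.butter(spec.order, spec.hp_cutoff, "highpass",
                            fs=record.fs)
    b_lp, a_lp = sps.butter(spec.order, spec.lp_cutoff, "lowpass",
                            fs=record.fs)
    out = np.empty_like(record.samples)
    for i in range(record.n_leads):
        x = record.samples[i]
        if spec.causal:
            y = sps.lfilter(b_lp, a_lp, sps.lfilter(b_hp, a_hp, x))
        else:
            y = sps.filtfilt(b_lp, a_lp, sps.filtfilt(b_hp, a_hp, x))
        out[i] = y
    return replace(record, samples=out)


def clip_amplitude(record: ECGRecord, a_r: float = 2.5) -> ECGRecord:
    """Hard-limit every sample to the supported range [-a_r, +a_r] (mV)."""
    if a_r <= 0:
        raise ValueError(f"a_r must be > 0, got {a_r}")
    return replace(record, samples=np.clip(record.samples, -a_r, a_r))


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Fourier-method resampling of a 1-D signal from fs_in to fs_out.

    Output length is ``round(len(x) * fs_out / fs_in)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return x.copy()
    n_out = int(round(x.size * fs_out / fs_in))
    return sps.resample(x, n_out)


def butterworth_cascade_gain(f: float, spec: FilterSpec = None) -> float:
    """Analytic steady-state magnitude of the HP x LP first-order cascade."""
    spec = spec or FilterSpec()
    r_hp = f / spec.hp_cutoff
    r_lp = f / spec.lp_cutoff
    g_hp = (r_hp ** (2 * spec.order) /
            (1 + r_hp ** (2 * spec.order))) ** 0.5
    g_lp = (1 / (1 + r_lp ** (2 * spec.order))) ** 0.5
    return g_hp * g_lp
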