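"""FM sonification of an 8-lead ECG into one low-band audio stream.

Each lead L modulates its own carrier: the instantaneous frequency is

    f_L(t) = F_C^L + F_D * ecg_L(t) / A_R            [Hz]

with carriers F_C^L spaced 300 Hz apart from 450 Hz (lead I) to 2550 Hz
(lead V6), deviation F_D = 125 Hz and supported amplitude range
A_R = 2.5 mV — a modulation index of 50 Hz/mV.  Adjacent bands are
separated by a 50 Hz guard gap at full modulation.  The per-lead tones

    S_L[n] = A_C * cos(2*pi * sum_{k<=n} f_L[k] / F_S)

are summed into the mono audio stream at F_S = 11 kHz, which comfortably
carries the highest modulated frequency (2675 Hz).  All operating
frequencies sit inside the 300-3000 Hz passband of common GSM microphones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CANONICAL_8, AudioStream, ECGRecord
from .preprocess import resample

DEFAULT_CARRIERS_HZ = (450.0, 750.0, 1050.0, 1350.0, 1650.0, 1950.0,
                       2250.0, 2550.0)


@dataclass
class FMConfig:
    """Carrier table and modulation constants of the sonifier."""

    carriers_hz: tuple = DEFAULT_CARRIERS_HZ
    deviation_hz: float = 125.0
    amp_range_mv: float = 2.5
    carrier_amp: float = 1.0 / 8.0
    audio_fs: float = 11_000.0
    initial_phase_rad: tuple = field(default=None)

    def __post_init__(self):
        self.carriers_hz = tuple(float(c) for c in self.carriers_hz)
        if self.initial_phase_rad is None:
            self.initial_phase_rad = (0.0,) * len(self.carriers_hz)
        self.validate()

    @property
    def n_leads(self) -> int:
        return len(self.carriers_hz)

    @property
    def modulation_index_hz_per_mv(self) -> float:
        return self.deviation_hz / self.amp_range_mv

    def validate(self) -> None:
        c = np.asarray(self.carriers_hz)
        if c.size < 1 or np.any(np.diff(c) <= 0):
            raise ValueError("carriers must be strictly increasing")
        if self.deviation_hz <= 0:
            raise ValueError("deviation_hz must be > 0")
        if self.amp_range_mv <= 0:
            raise ValueError("amp_range_mv must be > 0")
        if c.size > 1 and np.min(np.diff(c)) - 2 * self.deviation_hz < 0:
            raise ValueError("adjacent FM bands overlap: spacing < 2*F_D")
        if c[-1] + self.deviation_hz >= self.audio_fs / 2:
            raise ValueError("highest modulated frequency exceeds Nyquist")
        if self.carrier_amp * c.size > 1.0 + 1e-12:
            raise ValueError("carrier_amp * n_leads must be <= 1 (WAV-safe)")
        if len(self.initial_phase_rad) != c.size:
            raise ValueError("initial_phase_rad length must match carriers")

    def guard_gap_hz(self) -> float:
        """Gap between adjacent bands at full modulation (50 Hz by default)."""
        spacing = np.min(np.diff(np.asarray(self.carriers_hz)))
        return float(spacing - 2 * self.deviation_hz)


def instantaneous_frequency(amplitude_mv, lead_index: int,
                            config: FMConfig = None):
    """Instantaneous frequency (Hz) of a lead at a given amplitude (mV).

    ``amplitude_mv`` may be a scalar or array; it is assumed already
    clipped to +/- ``config.amp_range_mv``.
    """
    config = config or FMConfig()
    if not 0 <= lead_index < config.n_leads:
        raise IndexError(f"lead_index {lead_index} out of range "
                         f"0..{config.n_leads - 1}")
    return (config.carriers_hz[lead_index]
            + config.deviation_hz * np.asarray(amplitude_mv, dtype=float)
            / config.amp_range_mv)


def modulate_lead(lead_samples_mv: np.ndarray, lead_index: int,
                  config: FMConfig = None) -> np.ndarray:
    """Frequency-modulate one lead (already at audio rate) onto its carrier.

    The phase is a running cumulative sum of the instantaneous frequency in
    double precision — never wrapped — so the tone is continuous across the
    whole record.
    """
    config = config or FMConfig()
    f_inst = instantaneous_frequency(lead_samples_mv, lead_index, config)
    phase = (config.initial_phase_rad[lead_index]
             + 2.0 * np.pi * np.cumsum(f_inst) / config.audio_fs)
    return config.carrier_amp * np.cos(phase)


def sonify(record: ECGRecord, config: FMConfig = None) -> AudioStream:
    """Sonify a canonical 8-lead ECG record into one mono audio stream.

    Pipeline per lead: clip to +/-A_R, Fourier-resample to the audio rate,
    frequency-modulate, then sum the eight band signals.
    """
    config = config or FMConfig()
    if record.lead_names != CANONICAL_8[:config.n_leads]:
        raise ValueError(
            f"sonify requires the canonical {config.n_leads}-lead record "
            f"{CANONICAL_8[:config.n_leads]}; got {record.lead_names}")
    rec = record.in_mv()
    n_audio = int(round(rec.duration_s * config.audio_fs))
    audio = np.zeros(n_audio)
    for li in range(rec.n_leads):
        x = np.clip(rec.samples[li], -config.amp_range_mv,
                    config.amp_range_mv)
        if rec.fs != config.audio_fs:
            x = resample(x, rec.fs, config.audio_fs)
        # resample length == round(n * audio_fs / fs); pad/trim guards the
        # off-by-one when duration*fs is not integral
        if x.size < n_audio:
            x = np.pad(x, (0, n_audio - x.size))
        audio += modulate_lead(x[:n_audio], li, config)
    return AudioStream(audio, config.audio_fs)
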