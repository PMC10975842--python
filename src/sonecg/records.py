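"""Core containers for multi-lead ECG and mono audio signals.

The canonical in-memory representation of an ECG is an :class:`ECGRecord`
holding a lead-major sample matrix in millivolts.  Twelve standard leads are
redundant: the minimum independent set is (I, II, V1..V6), from which the
remaining four limb leads follow by the Einthoven/Goldberger identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical ordering of the eight independent leads.
CANONICAL_8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Standard 12-lead ordering used when deriving the dependent limb leads.
STANDARD_12 = ("I", "II", "III", "aVR", "aVL", "aVF",
               "V1", "V2", "V3", "V4", "V5", "V6")

WAVE_LABELS = ("P-peak", "Q-point", "R-peak", "S-peak", "J-point", "T-peak")


@dataclass
class Fiducial:
    """A single fiducial point annotation: lead name, wave label, time in ms."""

    lead: str
    wave: str
    time_ms: float


@dataclass
class ECGRecord:
    """Multi-lead ECG: ``samples[lead, n]`` with sampling rate ``fs`` in Hz.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Lead-major amplitude matrix.
    fs : float
        Sampling frequency in Hz.
    lead_names : tuple of str
        Unique lead names, one per row of ``samples``.
    units : {"mV", "uV"}
        Physical unit of the samples.  Internally the package works in mV.
    fiducials : list of Fiducial, optional
        Ground-truth or detected fiducial point annotations.
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple
    units: str = "mV"
    fiducials: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.lead_names = tuple(self.lead_names)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.lead_names):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but "
                f"{len(self.lead_names)} lead names given")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if self.units not in ("mV", "uV"):
            raise ValueError(f"units must be 'mV' or 'uV', got {self.units!r}")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return the sample vector of lead ``name``."""
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"lead {name} absent") from None

    def in_mv(self) -> "ECGRecord":
        """Return a copy expressed in millivolts (exact factor 1000)."""
        if self.units == "mV":
            return replace(self, samples=self.samples.copy())
        return replace(self, samples=self.samples / 1000.0, units="mV")

    def in_uv(self) -> "ECGRecord":
        """Return a copy expressed in microvolts (exact factor 1000)."""
        if self.units == "uV":
            return replace(self, samples=self.samples.copy())
        return replace(self, samples=self.samples * 1000.0, units="uV")


@dataclass
class AudioStream:
    """Mono audio: samples nominally in [-1, 1] at rate ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def reduce_to_8(record: ECGRecord) -> ECGRecord:
    """Select the minimum independent lead set (I, II, V1..V6), in order.

    Any other leads (III, aVR, aVL, aVF, ...) are dropped; they are linear
    combinations of the retained ones and carry no extra information.
    """
    for name in CANONICAL_8:
        if name not in record.lead_names:
            raise ValueError(f"lead {name} absent")
    idx = [record.lead_names.index(name) for name in CANONICAL_8]
    fid = [f for f in record.fiducials if f.lead in CANONICAL_8]
    return ECGRecord(record.samples[idx].copy(), record.fs, CANONICAL_8,
                     units=record.units, fiducials=fid)


def derive_12(record: ECGRecord) -> ECGRecord:
    """Reconstruct the 12 standard leads from the canonical 8-lead set.

    Applies the sample-wise identities
    ``III = II - I``, ``aVR = -(I + II)/2``, ``aVL = I - II/2`` and
    ``aVF = II - I/2``.
    """
    if record.lead_names != CANONICAL_8:
        raise ValueError(
            "derive_12 requires the canonical 8-lead record "
            f"(I, II, V1..V6); got {record.lead_names}")
    i, ii = record.lead("I"), record.lead("II")
    derived = {
        "III": ii - i,
        "aVR": -(i + ii) / 2.0,
        "aVL": i - ii / 2.0,
        "aVF": ii - i / 2.0,
    }
    rows = [record.lead(n) if n in CANONICAL_8 else derived[n]
            for n in STANDARD_12]
    return ECGRecord(np.vstack(rows), record.fs, STANDARD_12,
                     units=record.units, fiducials=list(record.fiducials))
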