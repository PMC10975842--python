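"""Minimal WFDB record I/O (header + format-16 signal files).

Supports the subset of the WFDB specification used by clinical resting-ECG
archives such as PTB-XL: a single ``.dat`` file per record, format 16
(interleaved little-endian 16-bit two's complement), with per-signal gain,
baseline and units declared in the ``.hea`` header.  Read records are
returned in microvolts at the source sampling rate.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .records import ECGRecord

_GAIN_RE = re.compile(
    r"^(?P<gain>[-+0-9.eE]+)?(\((?P<baseline>[-+0-9]+)\))?(/(?P<units>\S+))?$")


def read_wfdb(path_or_id: str) -> ECGRecord:
    """Read a WFDB record given its path without extension (``rec`` for
    ``rec.hea`` + ``rec.dat``).  Returns an :class:`ECGRecord` in uV."""
    hea_path = path_or_id + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"{hea_path}: malformed record line {lines[0]!r}")
    n_sig = int(head[1])
    if n_sig < 1:
        raise ValueError(f"{hea_path}: header advertises {n_sig} signals")
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"{hea_path}: {n_sig} signals declared but only "
                         f"{len(sig_lines)} signal lines present")

    dat_files, gains, baselines, units, names = [], [], [], [], []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        if len(parts) < 2:
            raise ValueError(f"{hea_path}: malformed signal line {ln!r}")
        dat_files.append(parts[0])
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise ValueError(f"{hea_path}: unsupported WFDB format {fmt!r} "
                             "(only format 16 is supported)")
        gain, baseline, unit = 200.0, 0, "mV"
        if len(parts) >= 3:
            m = _GAIN_RE.match(parts[2])
            if m:
                if m.group("gain"):
                    gain = float(m.group("gain")) or 200.0
                if m.group("baseline"):
                    baseline = int(m.group("baseline"))
                if m.group("units"):
                    unit = m.group("units")
        gains.append(gain)
        baselines.append(baseline)
        units.append(unit)
        names.append(parts[-1] if len(parts) >= 9 else f"sig{i}")

    if len(set(dat_files)) != 1:
        raise ValueError(f"{hea_path}: multi-file records not supported")
    dat_path = os.path.join(os.path.dirname(hea_path) or ".", dat_files[0])
    if not os.path.exists(dat_path):
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_sig * n_samples:
        raise ValueError(f"{dat_path}: expected {n_sig * n_samples} samples, "
                         f"found {raw.size}")
    mat = raw[:n_sig * n_samples].reshape(n_samples, n_sig).T.astype(float)

    to_uv = {"uV": 1.0, "uv": 1.0, "mV": 1000.0, "mv": 1000.0}
    samples = np.empty_like(mat)
    for i in range(n_sig):
        factor = to_uv.get(units[i])
        if factor is None:
            raise ValueError(f"{hea_path}: unsupported units {units[i]!r}")
        samples[i] = (mat[i] - baselines[i]) / gains[i] * factor
    return ECGRecord(samples, fs, tuple(names), units="uV")


def write_wfdb(record: ECGRecord, path: str, gain_per_unit: float = 1000.0
               ) -> None:
    """Write a record as ``path.hea`` + ``path.dat`` (format 16).

    ``gain_per_unit`` is the ADC gain in adu per source unit; with the
    default 1000 adu/unit a uV record is stored at 1000 adu/uV.
    """
    rec_name = os.path.basename(path)
    n_sig, n_samples = record.samples.shape
    adc = np.round(record.samples * gain_per_unit)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("amplitudes overflow 16-bit storage at this gain; "
                         "lower gain_per_unit")
    adc = adc.astype(np.int16)
    with open(path + ".hea", "w") as fh:
        fh.write(f"{rec_name} {n_sig} {record.fs:g} {n_samples}\n")
        for i, name in enumerate(record.lead_names):
            fh.write(f"{rec_name}.dat 16 {gain_per_unit:g}(0)/{record.units} "
                     f"16 0 {adc[i, 0]} 0 0 {name}\n")
    adc.T.reshape(-1).astype("<i2").tofile(path + ".dat")
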