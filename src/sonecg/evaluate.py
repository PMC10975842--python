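"""Per-lead quality report for a transformed ECG against its original."""

from __future__ import annotations

import numpy as np

from .fiducials import detect_fiducials, match_fiducials
from .metrics import normalized_psd_error, prd, rmse
from .records import ECGRecord, WAVE_LABELS


def evaluate_records(original: ECGRecord, transformed: ECGRecord,
                     tol_ms: float = 50.0, include_psd: bool = True,
                     include_fiducials: bool = True,
                     trim_s: float = 0.0) -> dict:
    """Amplitude, diagnostic and spectral errors, per lead.

    Both records must be aligned: same sampling rate, length and lead
    ordering.  ``trim_s`` seconds are dropped from both ends of the
    amplitude/PSD comparisons (filter-transient exclusion).  Returns a
    JSON-ready dict: per-lead ``rmse_uv``, ``prd_pct``, QRS detector
    counts with Se/PPV, per-wave MAD, and a PSD-error summary.
    """
    if original.fs != transformed.fs:
        raise ValueError(
            f"sampling rates differ: {original.fs} vs {transformed.fs}")
    if original.lead_names != transformed.lead_names:
        raise ValueError("lead sets differ between original and transformed")
    if original.n_samples != transformed.n_samples:
        raise ValueError(
            f"lengths differ: {original.n_samples} vs "
            f"{transformed.n_samples}")
    orig = original.in_mv()
    trans = transformed.in_mv()
    # filter transients are excluded from every metric: amplitude, PSD and
    # fiducial detection all see the trimmed signals
    k = int(round(trim_s * orig.fs))
    if k:
        from dataclasses import replace
        orig = replace(orig, samples=orig.samples[:, k:-k])
        trans = replace(trans, samples=trans.samples[:, k:-k])

    report = {"fs": orig.fs, "n_samples": orig.n_samples,
              "trimmed_s": trim_s, "leads": {}}
    if include_fiducials:
        ref_fid = detect_fiducials(orig)
        test_fid = detect_fiducials(trans)
        match = match_fiducials(ref_fid, test_fid, tol_ms=tol_ms)

    for li, lead in enumerate(orig.lead_names):
        x = orig.samples[li]
        y = trans.samples[li]
        entry = {
            "rmse_uv": rmse(y, x) * 1000.0,
            "prd_pct": prd(y, x) if np.any(x) else float("nan"),
        }
        if include_fiducials:
            tp, fp, fn = match.counts(lead=lead, wave="R-peak")
            entry["qrs"] = {
                "TP": tp, "FP": fp, "FN": fn,
                "Se": match.sensitivity(lead=lead, wave="R-peak"),
                "PPV": match.ppv(lead=lead, wave="R-peak"),
            }
            entry["mad_ms"] = {}
            for wave in WAVE_LABELS:
                mean, sd = match.mad_ms(lead=lead, wave=wave)
                entry["mad_ms"][wave] = {"mean": mean, "sd": sd}
        if include_psd and orig.fs >= 200.0:
            psd = normalized_psd_error(y, x, orig.fs)
            entry["psd_error"] = {"median_pct": psd.median(),
                                  "peak_pct": psd.peak()}
        report["leads"][lead] = entry
    return report


def summarize(report: dict) -> dict:
    """Collapse a per-lead report into median figures across leads."""
    leads = report["leads"]
    out = {
        "median_rmse_uv": float(np.median(
            [v["rmse_uv"] for v in leads.values()])),
        "median_prd_pct": float(np.nanmedian(
            [v["prd_pct"] for v in leads.values()])),
    }
    if all("qrs" in v for v in leads.values()):
        tp = sum(v["qrs"]["TP"] for v in leads.values())
        fp = sum(v["qrs"]["FP"] for v in leads.values())
        fn = sum(v["qrs"]["FN"] for v in leads.values())
        out["qrs_se_pct"] = tp / (tp + fn) * 100.0 if tp + fn else float("nan")
        out["qrs_ppv_pct"] = tp / (tp + fp) * 100.0 if tp + fp else float("nan")
    return out
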