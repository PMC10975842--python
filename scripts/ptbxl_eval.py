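"""Optional full-scale evaluation against a local PTB-XL download.

Not part of the test suite: requires the PTB-XL WFDB files (500 Hz
records) on disk.  For each record the chain original -> conditioning ->
sonification -> demodulation (DSP reference or a trained CNN checkpoint)
is run and per-lead RMSE/PRD plus QRS Se/PPV are accumulated, mirroring
the package's synthetic evaluation on clinical data.

Usage:
    python scripts/ptbxl_eval.py --records-dir <dir-with-hea-dat> \
        [--method dsp | --method cnn --model model.hdf5] \
        [--limit 100] --out ptbxl_report.json
"""

import argparse
import glob
import json
import os

import numpy as np

from sonecg.cnn import load_model, predict
from sonecg.demod_dsp import EDGE_TRANSIENT_S, demodulate
from sonecg.evaluate import evaluate_records, summarize
from sonecg.fm import FMConfig, sonify
from sonecg.pipeline import prepare_target
from sonecg.preprocess import FilterSpec, clip_amplitude, monitoring_filter
from sonecg.records import reduce_to_8
from sonecg.wfdb_io import read_wfdb


def evaluate_one(base, method, model, fm, spec):
    record = reduce_to_8(read_wfdb(base).in_mv())
    conditioned = clip_amplitude(monitoring_filter(record, spec),
                                 fm.amp_range_mv)
    audio = sonify(conditioned, fm)
    if method == "dsp":
        transformed = demodulate(audio, fm)
    else:
        transformed = predict(model, audio)
    target = prepare_target(record, spec, fm)
    report = evaluate_records(target, transformed, trim_s=EDGE_TRANSIENT_S)
    return report


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--records-dir", required=True)
    parser.add_argument("--method", choices=["dsp", "cnn"], default="dsp")
    parser.add_argument("--model", default=None)
    parser.add_argument("--limit", type=int, default=100)
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    model = load_model(args.model) if args.method == "cnn" else None
    fm, spec = FMConfig(), FilterSpec()
    headers = sorted(glob.glob(os.path.join(args.records_dir, "**", "*.hea"),
                               recursive=True))[:args.limit]
    if not headers:
        raise SystemExit(f"no WFDB headers found under {args.records_dir}")

    per_lead = {}
    summaries = []
    for hea in headers:
        report = evaluate_one(hea[:-4], args.method, model, fm, spec)
        summaries.append(summarize(report))
        for lead, entry in report["leads"].items():
            per_lead.setdefault(lead, {"rmse_uv": [], "prd_pct": []})
            per_lead[lead]["rmse_uv"].append(entry["rmse_uv"])
            per_lead[lead]["prd_pct"].append(entry["prd_pct"])

    out = {"n_records": len(headers), "method": args.method, "leads": {}}
    for lead, vals in per_lead.items():
        out["leads"][lead] = {
            metric: {
                "median": float(np.nanmedian(v)),
                "q25": float(np.nanpercentile(v, 25)),
                "q75": float(np.nanpercentile(v, 75)),
            } for metric, v in vals.items()}
    out["median_prd_pct"] = float(np.nanmedian(
        [s["median_prd_pct"] for s in summaries]))
    with open(args.out, "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out["leads"], indent=2))


if __name__ == "__main__":
    main()
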