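"""End-to-end pipeline: synthesize -> condition -> sonify -> demodulate ->
evaluate, with every artifact written to disk and the run reproducible
from its logged configuration and seed."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

from . import audio_io, synth
from .cnn import load_model, predict
from .demod_dsp import EDGE_TRANSIENT_S, demodulate
from .evaluate import evaluate_records, summarize
from .fm import FMConfig, sonify
from .preprocess import FilterSpec, clip_amplitude, monitoring_filter, resample
from .records import ECGRecord


@dataclass
class PipelineConfig:
    """Joint configuration of all pipeline stages."""

    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    fm: FMConfig = field(default_factory=FMConfig)
    method: str = "dsp"            # "dsp" | "cnn"
    model_path: str = None         # required for method == "cnn"
    out_fs: float = 250.0

    def validate(self) -> None:
        self.synth.validate()
        self.filter.validate(self.synth.fs)
        self.fm.validate()
        if self.method not in ("dsp", "cnn"):
            raise ValueError(f"method must be 'dsp' or 'cnn': {self.method}")
        if self.method == "cnn":
            if not self.model_path or not os.path.exists(self.model_path):
                raise FileNotFoundError(
                    f"CNN model file not found: {self.model_path!r}")


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _config_dict(config: PipelineConfig) -> dict:
    d = {"synth": asdict(config.synth), "filter": asdict(config.filter),
         "fm": asdict(config.fm), "method": config.method,
         "model_path": config.model_path, "out_fs": config.out_fs}
    return d


def prepare_target(record: ECGRecord, spec: FilterSpec, fm: FMConfig,
                   out_fs: float = 250.0) -> ECGRecord:
    """Monitoring-filter, clip and resample a record to the output rate.

    This is the signal the demodulators are expected to reproduce: the
    FM stream carries the conditioned (band-limited, amplitude-limited)
    ECG, so errors are measured against it.
    """
    conditioned = clip_amplitude(monitoring_filter(record.in_mv(), spec),
                                 fm.amp_range_mv)
    n_out = int(round(conditioned.duration_s * out_fs))
    rows = [resample(conditioned.samples[i], conditioned.fs, out_fs)[:n_out]
            for i in range(conditioned.n_leads)]
    import numpy as np
    return ECGRecord(np.vstack(rows), out_fs, conditioned.lead_names,
                     units="mV")


def run_end_to_end(config: PipelineConfig, workdir: str) -> dict:
    """Execute the full chain and return the evaluation report dict.

    Writes into ``workdir``: the synthetic ECG (CSV + fiducials), the
    sonified stream (WAV), the demodulated ECG (CSV), the report (JSON)
    and a run manifest with the seed and configuration hash.
    """
    config.validate()
    os.makedirs(workdir, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                from exc

    record = stage("synth", synth.generate_record, config.synth)
    synth.write_csv(record, os.path.join(workdir, "original.csv"),
                    os.path.join(workdir, "original_fiducials.csv"))
    conditioned = stage("preprocess", monitoring_filter, record,
                        config.filter)
    conditioned = clip_amplitude(conditioned, config.fm.amp_range_mv)
    audio = stage("sonify", sonify, conditioned, config.fm)
    audio_io.write_wav(audio, os.path.join(workdir, "audio_ecg.wav"))

    if config.method == "dsp":
        transformed = stage("desonify", demodulate, audio, config.fm,
                            config.out_fs)
    else:
        model = stage("load_model", load_model, config.model_path)
        transformed = stage("desonify", predict, model, audio)
    synth.write_csv(transformed, os.path.join(workdir, "transformed.csv"))

    target = stage("target", prepare_target, record, config.filter,
                   config.fm, config.out_fs)
    report = stage("evaluate", evaluate_records, target, transformed,
                   trim_s=EDGE_TRANSIENT_S)
    report["summary"] = summarize(report)
    report["manifest"] = {
        "seed": config.synth.seed,
        "method": config.method,
        "config_hash": config_hash(config),
        "config": _config_dict(config),
    }
    with open(os.path.join(workdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report
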