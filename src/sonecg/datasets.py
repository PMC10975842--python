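"""Paired (audio, target ECG) datasets for training and evaluating the
CNN demodulator, built entirely from the synthetic generator.

Each pair is one 10 s record: the input is the sonified, conditioned
8-lead ECG (110,000 audio samples at 11 kHz); the target is the same
conditioned ECG at 250 Hz (2,500 x 8, mV).  Records vary in heart rate,
rhythm (sinus / irregular-RR / ectopic), wave amplitudes and noise so the
network sees the morphological diversity it must demodulate.
"""

from __future__ import annotations

import numpy as np

from .fm import FMConfig, sonify
from .pipeline import prepare_target
from .preprocess import FilterSpec, clip_amplitude, monitoring_filter
from .synth import DEFAULT_WAVE_PARAMS, SynthConfig, generate_record

RHYTHM_CYCLE = ("sinus", "sinus", "irregular_rr", "ectopic")


def random_synth_config(rng: np.random.Generator,
                        duration_s: float = 10.0,
                        fs: float = 500.0) -> SynthConfig:
    """Draw a randomized generator configuration for one training record."""
    scale = rng.uniform(0.6, 1.6)
    wave_params = {
        w: (a * scale * rng.uniform(0.85, 1.15), wd, off)
        for w, (a, wd, off) in DEFAULT_WAVE_PARAMS.items()}
    return SynthConfig(
        duration_s=duration_s,
        fs=fs,
        heart_rate_bpm=float(rng.uniform(50, 110)),
        rr_jitter_frac=float(rng.uniform(0.0, 0.1)),
        rhythm_mode=RHYTHM_CYCLE[int(rng.integers(len(RHYTHM_CYCLE)))],
        ectopic_prob=float(rng.uniform(0.05, 0.3)),
        wave_params=wave_params,
        noise_rms_mv=float(rng.uniform(0.0, 0.03)),
        baseline_wander_mv=float(rng.uniform(0.0, 0.15)),
        seed=int(rng.integers(2 ** 31)),
    )


def make_pair(config: SynthConfig, fm: FMConfig = None,
              filter_spec: FilterSpec = None, out_fs: float = 250.0):
    """One (audio, target) pair from a generator configuration."""
    fm = fm or FMConfig()
    spec = filter_spec or FilterSpec()
    record = generate_record(config)
    conditioned = clip_amplitude(monitoring_filter(record, spec),
                                 fm.amp_range_mv)
    audio = sonify(conditioned, fm)
    target = prepare_target(record, spec, fm, out_fs)
    return audio.samples.astype(np.float32), \
        target.samples.T.astype(np.float32)


def synthetic_training_set(n_records: int, seed: int = 0,
                           duration_s: float = 10.0, fs: float = 500.0,
                           fm: FMConfig = None, out_fs: float = 250.0):
    """Build ``n_records`` seeded pairs: audio (N, L) and targets
    (N, L/44, 8)."""
    rng = np.random.default_rng(seed)
    fm = fm or FMConfig()
    audio_rows, target_rows = [], []
    for _ in range(n_records):
        cfg = random_synth_config(rng, duration_s=duration_s, fs=fs)
        a, t = make_pair(cfg, fm, out_fs=out_fs)
        audio_rows.append(a)
        target_rows.append(t)
    return np.stack(audio_rows), np.stack(target_rows)
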