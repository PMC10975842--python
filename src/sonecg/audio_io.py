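"""WAV I/O for the sonified ECG stream: 16-bit PCM mono."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.io import wavfile

from .records import AudioStream


def write_wav(stream: AudioStream, path) -> None:
    """Write a mono stream as 16-bit PCM; samples are clipped to [-1, 1]."""
    x = stream.samples
    if np.any(np.abs(x) > 1.0):
        warnings.warn("audio samples outside [-1, 1] clipped on WAV write")
        x = np.clip(x, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, int(round(stream.fs)), pcm)


def read_wav(path) -> AudioStream:
    """Read a 16-bit PCM mono WAV back into an AudioStream in [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got "
                         f"{data.shape[1]} channels")
    if data.dtype != np.int16:
        raise ValueError(f"{path}: expected 16-bit PCM, got {data.dtype}")
    return AudioStream(data.astype(float) / 32767.0, float(fs))
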