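"""CNN audio-to-ECG demodulator: architecture, training loop, inference.

The demodulator is a fully convolutional stack of four 1D convolutions with
linear activations, interleaved with three max-pooling stages:

    conv(220@24) -> pool(11) -> conv(20@24) -> pool(2)
                 -> conv(10@24) -> pool(2) -> conv(5@8)

It maps a 10 s mono audio stream at 11 kHz (110,000 samples) to a 10 s
8-lead ECG at 250 Hz (2,500 x 8) — an exact 44x rate reduction — with
23,600 trainable parameters.  Linear activations suit the regression task
(the output swings symmetrically around zero); the only nonlinearity is
max pooling, which doubles as envelope rectification of the band-filtered
carriers.  Dropout (0.1) after each convolution regularizes training and
is disabled at inference.

Training minimizes the mean squared sample error between the network
output and the monitoring-filtered original ECG (the loss is reported as
RMSE); no annotation is involved, so the regression is unsupervised in the
labelling sense.  First-layer kernels are initialized as a Gabor filter
bank spanning the eight FM bands and the middle layers as identity
smoothers — structured audio front-end initializations that shorten the
optimization path without fixing the solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .fm import FMConfig
from .nn import Adam, Conv1D, Dropout, MaxPool1D, Sequential
from .records import CANONICAL_8, AudioStream, ECGRecord

DEFAULT_CONV_LAYERS = ((220, 24), (20, 24), (10, 24), (5, 8))
DEFAULT_POOL_WINDOWS = (11, 2, 2)


@dataclass
class CNNArchitecture:
    """Layer specification of the audio-to-ECG demodulator."""

    conv_layers: tuple = DEFAULT_CONV_LAYERS
    pool_windows: tuple = DEFAULT_POOL_WINDOWS
    dropout_rate: float = 0.1
    input_len: int = 110_000
    in_channels: int = 1

    def __post_init__(self):
        self.conv_layers = tuple((int(m), int(c)) for m, c in self.conv_layers)
        self.pool_windows = tuple(int(k) for k in self.pool_windows)
        if len(self.pool_windows) != len(self.conv_layers) - 1:
            raise ValueError("need one pool window between consecutive convs")
        length = self.input_len
        for k in self.pool_windows:
            if length % k:
                raise ValueError(
                    f"pool window {k} does not divide length {length}")
            length //= k

    @property
    def downsampling_factor(self) -> int:
        return int(np.prod(self.pool_windows))

    @property
    def output_len(self) -> int:
        return self.input_len // self.downsampling_factor

    @property
    def n_leads(self) -> int:
        return self.conv_layers[-1][1]

    def layer_param_counts(self) -> list:
        counts, c_in = [], self.in_channels
        for m, c_out in self.conv_layers:
            counts.append(m * c_in * c_out + c_out)
            c_in = c_out
        return counts

    @property
    def n_params(self) -> int:
        return sum(self.layer_param_counts())


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, RMSE loss, early stopping on val loss.

    ``crop_samples`` enables random-crop training: each epoch draws a
    random window of that many audio samples (a multiple of the 44x rate
    factor) from every training pair.  The network is fully convolutional,
    so weights learned on crops apply unchanged to full-length records.
    """

    learning_rate: float = 0.001
    batch_size: int = 256
    val_fraction: float = 0.30
    max_epochs: int = 1000
    early_stop_patience: int = 150
    shuffle: bool = True
    seed: int = 0
    crop_samples: int = None

    def validate(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError(
                f"val_fraction must be in (0,1), got {self.val_fraction}")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience exceeds max_epochs")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


class CNNModel:
    """Architecture plus weights; thin wrapper over the layer stack."""

    def __init__(self, arch: CNNArchitecture, net: Sequential,
                 audio_fs: float = 11_000.0):
        self.arch = arch
        self.net = net
        self.audio_fs = audio_fs

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def forward_array(self, audio: np.ndarray, training: bool = False,
                      rng: np.random.Generator = None) -> np.ndarray:
        """Run (B, L) or (L,) audio through the net -> (B, L/44, leads)."""
        x = np.asarray(audio, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        return self.net.forward(x[:, :, None], training=training, rng=rng)


def _gabor_bank(m: int, n_filters: int, fs: float,
                fm_config: FMConfig, rng: np.random.Generator) -> np.ndarray:
    """Windowed-sinusoid kernels covering the FM bands, unit L2 norm."""
    t = (np.arange(m) - (m - 1) / 2) / fs
    sigma = (m / 6.0) / fs
    envelope = np.exp(-0.5 * (t / sigma) ** 2)
    carriers = np.asarray(fm_config.carriers_hz)
    offsets = (-fm_config.deviation_hz, 0.0, fm_config.deviation_hz)
    freqs = [c + o for c in carriers for o in offsets]
    bank = np.empty((m, n_filters), dtype=np.float32)
    for i in range(n_filters):
        f = freqs[i % len(freqs)]
        phase = rng.uniform(0, 2 * np.pi)
        g = envelope * np.cos(2 * np.pi * f * t + phase)
        bank[:, i] = (g / np.linalg.norm(g)).astype(np.float32)
    return bank


def _diagonal_smoother(conv: Conv1D) -> None:
    """Identity moving-average init: output channel c averages input c."""
    w = np.zeros((conv.c_in, conv.m, conv.c_out), dtype=np.float32)
    for c in range(min(conv.c_in, conv.c_out)):
        w[c, :, c] = 1.0 / conv.m
    conv.w = np.ascontiguousarray(w.reshape(conv.c_in * conv.m, conv.c_out))


def build_model(arch: CNNArchitecture = None, seed: int = 0,
                audio_fs: float = 11_000.0, fm_config: FMConfig = None,
                structured_init: bool = True) -> CNNModel:
    """Instantiate the demodulator with seeded initial weights.

    With ``structured_init`` (default) the first convolution starts as a
    Gabor filter bank spanning the FM bands, the middle convolutions as
    identity moving-average smoothers, and the readout Glorot-uniform, so
    the untrained network already propagates band envelopes; with
    ``structured_init=False`` every layer is Glorot-uniform.  Biases are
    zero either way.
    """
    arch = arch or CNNArchitecture()
    rng = np.random.default_rng(seed)
    n_convs = len(arch.conv_layers)
    layers, c_in = [], arch.in_channels
    for i, (m, c_out) in enumerate(arch.conv_layers):
        conv = Conv1D(m, c_in, c_out)
        conv.init_glorot(rng)
        if structured_init and i == 0 and c_in == 1:
            bank = _gabor_bank(m, c_out, audio_fs,
                               fm_config or FMConfig(), rng)
            conv.w = np.ascontiguousarray(bank)  # (M, C_out) == (C_in*M, C_out)
        elif structured_init and 0 < i < n_convs - 1:
            _diagonal_smoother(conv)
        layers.append(conv)
        layers.append(Dropout(arch.dropout_rate))
        if i < len(arch.pool_windows):
            layers.append(MaxPool1D(arch.pool_windows[i]))
        c_in = c_out
    model = CNNModel(arch, Sequential(layers), audio_fs=audio_fs)
    if model.n_params != arch.n_params:
        raise AssertionError("parameter bookkeeping mismatch")
    return model


def _crop_indices(n_in: int, crop: int, factor: int,
                  rng: np.random.Generator = None):
    """Random (or centred, if rng is None) crop start aligned to ``factor``."""
    slots = (n_in - crop) // factor
    if rng is None:
        start = (slots // 2) * factor
    else:
        start = int(rng.integers(0, slots + 1)) * factor
    return start, start + crop


def train(model: CNNModel, audio: np.ndarray, targets: np.ndarray,
          config: TrainConfig = None) -> dict:
    """Fit the demodulator on paired (audio, target ECG) records.

    Parameters
    ----------
    audio : ndarray, shape (N, L_audio)
        Sonified streams, one row per record.
    targets : ndarray, shape (N, L_audio/44, n_leads)
        Monitoring-filtered original ECG at the output rate, in mV.
    config : TrainConfig

    Returns a history dict with per-epoch ``train_rmse`` and ``val_rmse``
    (mV).  The weights of the epoch with minimal validation loss are
    restored before returning.
    """
    config = config or TrainConfig()
    config.validate()
    audio = np.asarray(audio, dtype=np.float32)
    targets = np.asarray(targets, dtype=np.float32)
    if audio.ndim != 2 or targets.ndim != 3:
        raise ValueError("audio must be (N, L), targets (N, L_out, leads)")
    n = audio.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    factor = model.arch.downsampling_factor
    if targets.shape[1] * factor != audio.shape[1] \
            or targets.shape[2] != model.arch.n_leads:
        raise ValueError(
            f"shape mismatch: audio {audio.shape} vs targets "
            f"{targets.shape} (rate factor {factor})")

    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.val_fraction * n))
    n_val = min(max(n_val, 1), n - 1) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    crop = config.crop_samples or audio.shape[1]
    crop -= crop % factor
    if crop < factor or crop > audio.shape[1]:
        raise ValueError(f"crop_samples invalid: {config.crop_samples}")

    # fixed centred crops for the validation set
    v0, v1 = _crop_indices(audio.shape[1], crop, factor)
    val_x = audio[val_idx, v0:v1]
    val_y = targets[val_idx, v0 // factor:v1 // factor]

    opt = Adam(model.net.params(), lr=config.learning_rate)
    history = {"train_rmse": [], "val_rmse": []}
    best_val, best_weights, since_best = np.inf, model.net.get_weights(), 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(train_idx) if config.shuffle \
            else np.array(train_idx)
        sq_sum, n_sq = 0.0, 0
        for lo in range(0, order.size, config.batch_size):
            batch = order[lo:lo + config.batch_size]
            c0, c1 = _crop_indices(audio.shape[1], crop, factor, rng)
            x = audio[batch, c0:c1]
            y = targets[batch, c0 // factor:c1 // factor]
            pred = model.forward_array(x, training=True, rng=rng)
            err = pred - y
            model.net.backward(2.0 * err / err.size)
            opt.step(model.net.grads())
            sq_sum += float(np.sum(err.astype(np.float64) ** 2))
            n_sq += err.size
        history["train_rmse"].append(float(np.sqrt(sq_sum / max(n_sq, 1))))

        if val_idx.size:
            val_rmse = _eval_rmse(model, val_x, val_y,
                                  config.batch_size)
        else:
            val_rmse = history["train_rmse"][-1]
        history["val_rmse"].append(val_rmse)

        if val_rmse < best_val:
            best_val = val_rmse
            best_weights = model.net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    model.net.set_weights(best_weights)
    return history


def _eval_rmse(model: CNNModel, x: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    sq, cnt = 0.0, 0
    for lo in range(0, x.shape[0], batch_size):
        pred = model.forward_array(x[lo:lo + batch_size], training=False)
        err = (pred - y[lo:lo + batch_size]).astype(np.float64)
        sq += float(np.sum(err ** 2))
        cnt += err.size
    return float(np.sqrt(sq / max(cnt, 1)))


def predict(model: CNNModel, audio: AudioStream) -> ECGRecord:
    """Demodulate one audio stream into a canonical 8-lead ECG record."""
    if abs(audio.fs - model.audio_fs) > 0.01 * model.audio_fs:
        raise ValueError(
            f"audio sampled at {audio.fs} Hz; model expects "
            f"{model.audio_fs} Hz")
    x = np.asarray(audio.samples, dtype=np.float32)
    factor = model.arch.downsampling_factor
    if x.size < model.arch.input_len:
        warnings.warn(
            f"audio shorter than {model.arch.input_len} samples; zero-padded")
        x = np.pad(x, (0, model.arch.input_len - x.size))
    elif x.size % factor:
        x = np.pad(x, (0, factor - x.size % factor))
    out = model.forward_array(x, training=False)[0]
    fs_out = model.audio_fs / factor
    return ECGRecord(out.T.astype(float), fs_out,
                     CANONICAL_8[:model.arch.n_leads], units="mV")


def save_model(model: CNNModel, path) -> None:
    """Store weights and architecture in one self-describing HDF5 file."""
    arch = model.arch
    meta = {
        "conv_layers": list(list(p) for p in arch.conv_layers),
        "pool_windows": list(arch.pool_windows),
        "dropout_rate": arch.dropout_rate,
        "input_len": arch.input_len,
        "in_channels": arch.in_channels,
        "audio_fs": model.audio_fs,
    }
    with h5py.File(path, "w") as fh:
        fh.attrs["sonecg_arch"] = json.dumps(meta)
        for i, w in enumerate(model.net.get_weights()):
            fh.create_dataset(f"param_{i:02d}", data=w)


def load_model(path) -> CNNModel:
    """Rebuild a model from :func:`save_model` output (bit-identical)."""
    with h5py.File(path, "r") as fh:
        if "sonecg_arch" not in fh.attrs:
            raise ValueError(f"{path}: not a sonecg model checkpoint")
        meta = json.loads(fh.attrs["sonecg_arch"])
        weights = [fh[f"param_{i:02d}"][...]
                   for i in range(len(meta["conv_layers"]) * 2)]
    arch = CNNArchitecture(
        conv_layers=tuple(tuple(p) for p in meta["conv_layers"]),
        pool_windows=tuple(meta["pool_windows"]),
        dropout_rate=meta["dropout_rate"],
        input_len=meta["input_len"],
        in_channels=meta["in_channels"])
    model = build_model(arch, audio_fs=meta["audio_fs"])
    model.net.set_weights([np.asarray(w, dtype=np.float32) for w in weights])
    return model
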