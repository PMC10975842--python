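# Methods

## Overview

`sonecg` implements a two-transformer signal chain for remote multi-lead
ECG monitoring over an audio channel:

1. **ECG-to-Audio (sonification).** Eight independent ECG leads
   (I, II, V1..V6) are frequency-modulated onto carriers spaced 300 Hz
   apart (450 Hz for lead I up to 2550 Hz for V6) and summed into one
   mono stream at 11 kHz. The instantaneous frequency of lead *L* is

       f_L(t) = F_C^L + F_D · x_L(t) / A_R,

   with deviation F_D = 125 Hz and supported amplitude range
   A_R = 2.5 mV, i.e. a modulation index of 50 Hz/mV. At full-scale
   modulation adjacent bands remain separated by a 50 Hz guard gap, and
   the highest modulated frequency (2675 Hz) stays well inside both the
   11 kHz Nyquist limit and the 300–3000 Hz passband of common GSM
   microphones.

2. **Audio-to-ECG (demodulation).** Two independent inverses are
   provided: a classical DSP discriminator used as a training-free
   reference, and a small fully convolutional network trained by
   regression against the conditioned original ECG.

The evaluation layer quantifies how faithfully the round trip preserves
the ECG: amplitude errors (RMSE, PRD), diagnostic errors (fiducial-point
MAD, QRS Se/PPV under a ±50 ms matching tolerance), spectral errors
(normalized Welch-PSD difference on a 0.2 Hz grid over 0–100 Hz), and an
STFT monitor of the audio stream (1 s window, half-window overlap).

## Signal conditioning

The patient-module front end is modelled by causal first-order
Butterworth filters: a 0.64 Hz high-pass (baseline-wander rejection) and
a 30 Hz low-pass (muscle-artifact attenuation), applied lead-wise in a
single forward pass, the way analog monitoring hardware behaves. A
zero-phase option exists for offline analysis. Amplitudes are
hard-limited to ±2.5 mV before modulation; rate conversion uses
Fourier-method resampling throughout, so a 10 s record at any source
rate becomes exactly 110,000 audio samples. Filtering is applied at the
source rate and decimation to the 250 Hz target rate afterwards.

## The classical demodulator (reference path)

Each band is isolated by a zero-phase 5th-order Butterworth band-pass
(±150 Hz around the carrier: deviation plus half the guard gap), giving
better than 40 dB suppression of neighbouring carriers after
forward–backward filtering. The analytic signal is formed via the
Hilbert transform; the instantaneous frequency is the smoothed discrete
derivative of its unwrapped phase (moving average of ~2 ms); inverting
the modulation law maps it back to mV. A polyphase anti-alias decimator
brings the signal to 250 Hz. The first and last 100 ms are dominated by
filter transients and are excluded from round-trip error metrics. On
clean synthetic records the round trip achieves per-lead PRD well below
1 %, and cross-talk from a single active lead into the other seven
outputs is far below 1 % RMS — this is the oracle against which both the
modulator and the CNN are checked.

## The CNN demodulator

Architecture (23,600 trainable parameters):

    conv 220@24 → pool 11 → conv 20@24 → pool 2 → conv 10@24 → pool 2 → conv 5@8

All activations are linear: the regression target swings symmetrically
around zero, and rectifying nonlinearities would bias it. The only
nonlinearity is max pooling, which besides reducing the rate 44× acts as
an envelope rectifier for the band-filtered carriers — exactly the
nonlinearity a slope-detection FM discriminator needs. Dropout (rate
0.1) after each convolution is active only in training. The network is
fully convolutional, so any input length divisible by 44 is accepted;
the nominal contract is 110,000 samples in, (2,500 × 8) out.

Stated pooling stages reduce 110,000 → 10,000 → 5,000 → 2,500; the
windows (11, 2, 2) are fixed by the input/output lengths.

Numerical engine: the network runs on a small numpy engine (im2col +
BLAS matmul convolutions, argmax-routed pooling gradients, inverted
dropout, Adam). Given a seed and a single thread it is bit-for-bit
reproducible. Checkpoints are self-describing HDF5 files (architecture
JSON + weight arrays); loading reproduces predictions exactly.

### Initialization

First-layer kernels are initialized as a Gabor filter bank: three
windowed sinusoids per FM band, tuned to the band edges (F_C ± F_D) and
centre, with random phases and unit L2 norm. The two middle
convolutions are initialized as identity moving-average smoothers
(each output channel averages its corresponding input channel), so the
untrained network already propagates per-band envelopes to the readout
layer; the final readout is Glorot-uniform, hence the untrained output
is an uninformative mixture. These are standard structured
initializations for audio front ends; they shorten the optimization
path without fixing the solution — all 23,600 parameters remain
trainable and move during fitting.

### Training protocol

The reference protocol is Adam, learning rate 0.001, batch size 256,
record-level 70/30 train/validation split, up to 1000 epochs with early
stopping after 150 epochs without validation improvement, minimum-
validation-loss weights restored. The loss is optimized as MSE and
reported as RMSE (mV internally; μV in reports).

Desk-scale protocol (used by the test suite and the bundled `train`
command): hundreds of synthetic pairs rather than thousands of clinical
records, smaller batches (4–8), learning rate 0.003, a few tens of
epochs, and random-crop training — each step draws a random 2.5 s
window (27,500 audio samples, aligned to the 44× factor) from every
10 s pair. Crops are valid because the network is fully convolutional;
they multiply the number of optimization steps per CPU-second by 4 and
act as data augmentation. Validation uses fixed centred crops; held-out
evaluation always runs on full 10 s records. At this scale the 0.1
dropout regularizer is counterproductive (the binding constraint is
optimization, not overfitting), so desk-scale configurations may
disable it; the full-scale default keeps it.

## Synthetic data

The generator replaces a clinical 12-lead archive for all desk-scale
work. Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with
configurable amplitude/width/offset; a per-lead projection vector gives
eight channels with realistic polarity (V1 dominantly negative). Rhythm
modes: quasi-periodic sinus with fractional RR jitter; `irregular_rr`
(wide uniform RR variation with suppressed P waves, the pattern of
atrial fibrillation); `ectopic` (premature wide-QRS beats without P, 3×
QRS width, at a configurable rate). White Gaussian noise and a 0.2–0.4
Hz sinusoidal baseline wander model the dominant acquisition artifacts;
all outputs are clipped to ±2.5 mV. Ground-truth fiducial times are
emitted with every record, which is what makes the fiducial detector
testable against an absolute reference.

Default conditions: 10 s records, 500 Hz source rate, 70 bpm, 5 % RR
jitter, 0.01 mV RMS noise, 0.05 mV wander. Training sets randomize
heart rate (50–110 bpm), rhythm mode (sinus : irregular : ectopic =
2:1:1), global amplitude scale (0.6–1.6×), noise (0–0.03 mV RMS) and
wander (0–0.15 mV).

What the generator does **not** emulate: genuine clinical morphology
variation (infarct patterns, bundle-branch blocks, ST shifts), electrode
motion artifacts, powerline interference, and inter-lead timing
differences of a real torso. Passing tests therefore demonstrate that
the signal chain is a faithful FM codec for band-limited multi-lead
signals in the supported amplitude range — not clinical-grade validation
on pathological ECGs.

## Fiducial detection and matching

The built-in detector uses the squared derivative of each lead,
integrated over a 100 ms moving window, with an adaptive threshold
(25 % of the 90th-percentile candidate height) and a 250 ms refractory
period; R positions are refined to the local extremum of the raw lead.
P, Q, S and T are constrained extremum searches in polarity-aware
physiological windows around each R; the J point is the recovery of the
S wave to 15 % of its depth. The detector is deliberately simple and
pluggable: MAD/Se/PPV only require that the *same* detector runs on the
original and the transformed signal. Matching is greedy one-to-one by
ascending |Δt| within ±50 ms (ties toward the earlier reference point);
Se and PPV are undefined (NaN) when their denominators are zero.

## Numerical choices and degenerate inputs

- Phase accumulation in the modulator is an unwrapped running sum in
  double precision; initial phases default to zero.
- The carrier amplitude A_C defaults to 1/8 so the 8-band sum is
  bounded by 1.0 and survives 16-bit WAV quantization; quantization
  happens only at WAV write.
- Audio rate defaults to 11,000 Hz (configurable, e.g. 11,025 Hz).
- Welch segments are 5 s with 50 % overlap and a Hann window, realizing
  0.2 Hz bins; the PSD-error normalizer is the scalar global maximum
  over both spectra, so the error is bounded by 100 %.
- PRD is rejected for an all-zero reference; empty fiducial sets are
  allowed and produce NaN rates rather than exceptions.
- All-zero ECG input produces a pure 8-carrier chord; demodulating it
  returns all leads ≈ 0 mV.

## Known limitations

- The acoustic over-the-air channel (speaker/microphone nonlinearities,
  ambient noise, codec effects) is out of scope; the audio stream is
  passed digitally between the two transformers.
- The classical demodulator is zero-phase and non-causal by design — it
  is a verification instrument, not a real-time receiver.
- Desk-scale CNN training on synthetic data demonstrates that the
  architecture learns FM demodulation; it does not reproduce the error
  statistics of full-scale training on a clinical database.
- The WFDB reader supports single-file format-16 records (the layout
  used by resting 12-lead archives), not the full WFDB specification.
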