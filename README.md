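# sonecg

Multi-lead ECG sonification by frequency-modulation multiplexing, and its
inverse transformation back to diagnostic-quality ECG.

`sonecg` is for engineers and researchers working on remote ECG
monitoring over plain audio channels (e.g. a patient module playing a
sound into a phone microphone during an ordinary call). It implements
the full signal chain in both directions, plus the evaluation machinery
needed to argue that the round trip preserves diagnostic content.

## The method

**Forward (ECG-to-Audio).** The eight independent leads (I, II, V1–V6 —
sufficient to reconstruct all 12 standard leads) each modulate a private
carrier. The instantaneous frequency of lead *L* is

```
f_L(t) = F_C^L + F_D · x_L(t) / A_R        [Hz]
```

with carriers `F_C = 450, 750, …, 2550 Hz` (300 Hz steps), deviation
`F_D = 125 Hz` and amplitude range `A_R = 2.5 mV` — a 50 Hz/mV modulation
index with a 50 Hz guard gap between adjacent bands at full modulation.
The per-lead tones `S_L[n] = A_C cos(2π Σ_k f_L[k]/F_S)` are summed into
one mono stream at `F_S = 11 kHz` and can be written as 16-bit WAV.

**Inverse (Audio-to-ECG).** Two demodulators return a 250 Hz, 8-lead
record in mV:

- `dsp`: a classical discriminator (band-pass → analytic signal →
  instantaneous frequency → invert the modulation law) used as a
  training-free reference;
- `cnn`: a fully convolutional network,
  `conv 220@24 → pool 11 → conv 20@24 → pool 2 → conv 10@24 → pool 2 → conv 5@8`
  (23,600 parameters, linear activations, 44× rate reduction), trained by
  regression against the conditioned original ECG.

**Evaluation.** RMSE and PRD per lead; fiducial-point matching (P-peak,
Q-point, R-peak, S-peak, J-point, T-peak) with a ±50 ms tolerance giving
MAD, sensitivity and positive predictive value; normalized Welch-PSD
error in 0.2 Hz bins over 0–100 Hz; STFT monitoring of the audio stream.

A seeded synthetic multi-lead ECG generator (Gaussian PQRST phantom with
sinus / irregular-RR / ectopic rhythm modes and analytic ground-truth
fiducials) makes the whole package self-contained — no database download
is needed. See `docs/methods.md` for the model details and limitations.

## Worked example

```
$ sonecg run-all --workdir /tmp/demo --seed 2
median RMSE 0.5 uV, median PRD 0.32 %, QRS Se 100.00 % / PPV 100.00 %
```

This generates a seeded 10 s synthetic 8-lead record, applies the
monitoring-band filters (0.64–30 Hz), sonifies it into a 110,000-sample
audio stream (written as `audio_ecg.wav`), demodulates it with the DSP
reference, and compares the reconstruction with the conditioned
original: a median amplitude error of ~0.5 μV (~0.3 % of the signal
RMS), with every QRS complex recovered at its correct position. The per-lead
breakdown, fiducial MAD and PSD errors are in `/tmp/demo/report.json`.

The same stages are available individually:

```
sonecg synth   --seed 3 --out ecg.csv
sonecg sonify  --in ecg.csv --out audio.wav
sonecg desonify --method dsp --in audio.wav --out transformed.csv
sonecg evaluate --original ecg.csv --transformed transformed.csv --report report.json
sonecg train   --n-records 500 --epochs 15 --out model.hdf5
sonecg desonify --method cnn --model model.hdf5 --in audio.wav --out cnn.csv
```

Library use mirrors the CLI: `generate_record`, `monitoring_filter`,
`sonify`, `demodulate` / `predict`, `evaluate_records` — see the module
docstrings.

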