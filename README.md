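# spikespeech

Reconstructing heard audio from intracortical multiunit spiking.

In a passive-listening experiment, a multielectrode array records
broadband (30 kS/s) voltage traces from auditory cortex while word-like
sounds play in pseudorandom order, and a microphone records the audio
synchronously. `spikespeech` implements the full offline decoding
analysis for this setting:

* **Features** — bandpass-filtered traces (2nd-order elliptic,
  grid-searchable cutoffs), per-channel MAD noise levels estimated on
  training data, negative threshold crossings at
  −(threshold factor)·σ, counts binned on the audio target hop,
  channels ranked by training activity, centered feature windows of
  span + 1 bins per channel.
* **Targets** — mel-scaled power spectrograms
  (STFT → triangular mel filterbank), per-band zero-mean standardized
  with training means; reconstruction by filterbank pseudo-inversion and
  Griffin–Lim phase recovery.
* **Decoders** — seven scikit-learn-style regressors: Kalman filter,
  Wiener filter, Wiener cascade, and dense / simple-recurrent / GRU /
  LSTM networks (single hidden layer, MSE, Adam or RMSprop, early
  stopping with max 2048 epochs and patience 5), all implemented in
  NumPy.
* **Metrics** — Fisher-mean mel-band correlation
  `tanh(mean(atanh(r_band)))`, envelope correlation, gross pitch error
  (share of frames with |F0 − F̂0| > 0.2·F0), mean loudness factor
  `mean(2^(|l − l̂|/10))` over BS.1770-4 momentary loudness, ESTOI, and
  STMI `1 − ‖T − N‖²/‖T‖²` over spectro-temporal modulation content.
* **Statistics** — the multisample correlation chi-square
  `χ² = Σ nᵢ(rᵢ − r_w)²/(1 − rᵢ r_w)²` with Tukey-type post-hoc, and
  block-based (2 s) Friedman + Conover comparisons for the other
  metrics.
* **Synthetic sessions** — word-like tokens and audio-driven spiking
  from a known spectrotemporal-receptive-field encoding with half-wave
  rectification, so every stage is testable end to end with ground
  truth. See `docs/methods.md` for the model and its limitations.

## Worked example

```python
import spikespeech.synth as synth
import spikespeech.pipeline as pipeline
from spikespeech.decoders import DecoderSpec

# one synthetic session: 16 channels, 3 word-like tokens x 40 reps, ~172 s
bundle, trials, model = synth.make_session(synth.SessionSpec(seed=1))
dataset = pipeline.assemble_dataset(bundle, trials)

for algorithm, hp in [("wiener", {}), ("lstm_rnn", {"units": 64})]:
    res = pipeline.run_experiment(
        pipeline.ExperimentConfig(decoder=DecoderSpec(algorithm, hp, seed=1)),
        bundle, trials, dataset=dataset,
    )
    print(algorithm, {k: round(res[k], 3) for k in ("train_r", "val_r", "test_r")})
```

prints

```
wiener {'train_r': 0.865, 'val_r': 0.825, 'test_r': 0.819}
lstm_rnn {'train_r': 0.989, 'val_r': 0.975, 'test_r': 0.97}
```

Each number is the Fisher-mean Pearson correlation between target and
predicted mel-spectrogram bands on the sequential 80/10/10
train/validation/test split, predicted bin by bin. The LSTM's margin
over the Wiener filter reflects the half-wave rectification in the
synthetic encoding: a linear read-out cannot represent the folded part
of the drive, a recurrent network can.

`pipeline.reconstruct_audio` turns predicted mel frames back into a
waveform, and `spikespeech.metrics.evaluate_all` scores it against the
target with all six metrics. A thin CLI is available as
`spikespeech synth|train|evaluate|stats`.

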