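# Methods

## Problem and scope

`spikespeech` implements an offline neural-decoding analysis for
reconstructing heard audio from intracortical multiunit spiking. The
target setting is a passive-listening experiment: word-like sounds play
in pseudorandom order while a multielectrode array records broadband
(30 kS/s) voltage traces synchronized with a microphone track. The
package covers the complete path — multiunit feature extraction,
mel-spectrogram targets, seven regression decoders, audio
reconstruction, six quality metrics, and the statistics for comparing
decoders — together with a synthetic-session generator that provides a
known ground-truth encoding, since no public recordings of this kind
are available at desk scale.

## Audio representation

Targets are mel-scaled power spectrograms: an STFT (Hann window,
centered frames, reflect padding, FFT window 2048) followed by a
triangular mel filterbank spanning 0 Hz to Nyquist. The searched
representation grid is 32/64/128/256 mel bands and 10–50 ms hops; the
default operating point is 128 bands at a 40 ms hop. Targets are
per-band zero-mean standardized with means estimated on training frames
only. Targets are *linear* mel power by default; a dB option
(`log_power`) exists but is off, as the regression literature this
follows regresses linear band power.

Reconstruction inverts the filterbank with a Moore–Penrose
pseudo-inverse (power clipped at zero; decoder outputs are clipped
before inversion because mel power cannot be negative) and recovers
phase with Griffin–Lim (default 64 iterations, seeded random phase
initialization). On the synthetic tokens the full round trip
audio → mel(128, 40 ms) → invert → Griffin–Lim → mel retains a
Fisher-mean band correlation above 0.99, comfortably above the 0.85
bound the acceptance suite enforces; this is the "perfect decoder"
ceiling of the reconstruction path.

Framing convention: frame `t` is centered on sample `t·hop`; a signal of
`n` samples yields `⌊n/hop⌋ + 1` frames. When aligning with spike-count
bins (non-overlapping `[t·hop, (t+1)·hop)` windows) each trial
contributes `⌊len/hop⌋` frames and the trailing STFT frame is dropped.

## Multiunit features

Broadband traces are bandpass filtered with a 2nd-order elliptic filter
(0.1 dB passband ripple, 40 dB stopband attenuation — unstated in the
source conventions, chosen as standard values; zero-phase
forward-backward application avoids latency shifts). The standard
cutoff grid is 100–1000 Hz lows by 1000–10000 Hz highs, giving 99 valid
pairs. Per-channel noise is the median absolute deviation over
*training-set samples* divided by 0.6745 (Gaussian consistency), robust
to the spikes themselves. Crossings are negative threshold crossings at
`−threshold_factor·σ` (grid 2–5), detected on the filtered full-rate
signal, with a 1 ms dead time (common multiunit practice; the exact
rule of the classical extraction toolchain is not published). Counts are
binned on the target hop grid. Channels are ranked by total
training-set crossing count (ties toward lower index, so top-k selection
is a stable prefix) with the channel-count grid 2–96. Each feature row
concatenates, per channel, a centered window of `span + 1` bins
(span grid 4/8/16; the span excludes the current bin).

## Decoders

Seven algorithms, all consuming feature rows and emitting one value per
mel band:

* **Wiener filter** — per-band OLS with intercept.
* **Wiener cascade** — the linear stage followed by a per-band static
  polynomial (degree grid 2–5) fitted to map linear output onto the
  target; degree 1 reduces exactly to the Wiener filter.
* **Kalman filter** — state = target vector; transition `A`/noise `W`
  fitted by least squares on consecutive target pairs, observation
  `H`/noise `Q` by regressing features on targets; the `C`
  hyperparameter (grid 0.1/1/10) scales `W`, the convention of the
  reference decoding library this follows (where `C` sits in that
  library is not documented; transition noise is the implemented
  reading, and it is a constructor argument). The filter consumes
  single-bin features and is initialized at the training-mean state.
* **Dense NN / simple RNN / GRU / LSTM** — single hidden layer (unit
  grid 256–2048; smaller sizes used at desk scale), linear output, no
  dropout; ReLU hidden units for dense and simple RNN, tanh for the
  gated cells; Adam for the dense network, RMSprop for all recurrent
  ones (learning rate 1e-3, the common library default, fixed and
  logged); MSE loss; batch size 128; early stopping on validation loss
  with a maximum of 2048 epochs and patience 5, restoring the
  best-epoch parameters. Recurrent decoders consume each windowed row
  as a `span + 1`-step sequence of per-channel counts (windowed per
  prediction, not stateful across bins — matching a window centered on
  the current prediction); the dense network consumes the row
  flattened.

The networks are implemented directly in NumPy (forward and backward
passes verified against central finite differences in the test suite).
Inputs and targets are z-scored inside the network decoders with
training-set statistics and predictions mapped back to target units;
this is purely gradient conditioning and does not change the decoder
interface or the target definition.

## Metrics

1. **Fisher-mean mel correlation** — per-band Pearson r, z-transformed
   (`atanh`, clipped at 1−1e−7), averaged, back-transformed. Zero
   variance bands are excluded.
2. **Envelope correlation** — |Hilbert| low-passed at 50 Hz (4th-order
   zero-phase Butterworth; filter type unstated in the conventions this
   follows) then Pearson r.
3. **Gross pitch error** — percent of target-voiced frames with
   relative F0 error strictly above 20%. F0 by the normalized
   correlation function over 50–400 Hz with 40 ms frames aligned to the
   decoding hop and voicing at NCF peak ≥ 0.6 (the frame/threshold
   choices are this package's defaults; only the method is prescribed).
   Reconstruction frames with no detected pitch count as errors.
4. **Mean loudness factor** — momentary loudness per
   ITU-R BS.1770-4 / EBU R 128 (K-weighting biquads re-derived for the
   session rate, 400 ms windows, 75% overlap, −120 LUFS silence
   floor), then the time mean of `2^(|l−l̂|/10)`; a constant 10 dB error
   scores exactly 2.
5. **ESTOI** — 10 kHz internal rate, 256-sample frames (50% overlap,
   512-point FFT), 15 third-octave bands from 150 Hz, 40 dB
   silent-frame removal keyed to the clean signal, sliding 30-frame
   (384 ms) segments with row/column normalization and projection.
6. **STMI** — `1 − ‖T−N‖²/‖T‖²` over time-averaged modulation content:
   a 128-channel log-frequency (constant-Q-style, amplitude-linear)
   spectrogram at 5 ms hop filtered by Gaussian spectro-temporal
   modulation filters at rates {2,4,8,16,32} Hz and scales
   {0.25,0.5,1,2,4,8} cyc/oct. This is a documented simplification of
   the full auditory-model implementation; because every stage is
   1-homogeneous in the waveform, the index satisfies the exact
   identities N=T→1, N=0→0, N=2T→0.

## Statistics

Mel-correlation comparisons use the multisample chi-square of Paul
(1988): `χ² = Σ nᵢ(rᵢ−r_w)²/(1−rᵢr_w)²`, df = k−1, with the common
correlation `r_w` estimated as the n-weighted mean in z-space,
back-transformed (the estimator is not fully specified in the secondary
sources; this reading is pluggable). `nᵢ` is the validation frame count
entering each correlation. The post-hoc is a Tukey-type studentized
range test on z values with standard errors `1/√(nᵢ−3)` (k = 2 falls
back to a two-sample z test, flagged). All other metrics are computed
on non-overlapping 2 s blocks of validation audio and compared with a
Friedman test (midrank ties; statistic cross-checked against
`scipy.stats.friedmanchisquare` and exhaustive permutation enumeration)
plus Conover pairwise post-hocs with Holm adjustment (the adjustment
method is this package's choice). Type-I error of the Friedman path is
verified ≤ α + 2 Monte-Carlo SE at α = 0.05 over 2000 null simulations.

## Synthetic sessions

The generator emulates the study conditions rather than any particular
animal: 30 kS/s shared sample rate; a vocabulary of word-like tokens
(harmonic source, swept Gaussian formant envelopes, attack/decay
envelope, RMS-normalized) of different durations and spectral content;
each token repeated 40–60 times (default 40) in seeded pseudorandom
order at 1 s intervals; all trials marked keep.

Neural traces come from a known encoding model: each informative
channel (default 75% of channels) has a smooth, localized
spectrotemporal receptive field — an excitatory Gaussian bump with a
weaker inhibitory flank over (mel band, lag), unit L2 norm, centers
confined to the stimulus band — and fires at
`rate = rectify(baseline + gain · (STRF ⊛ mel power))` on a 10 ms grid
(mel power normalized by its mean active value so the gain is in
spikes/s). Defaults: baseline 2 spikes/s, gain 30 (peak multiunit rates
of a few hundred spikes/s), 16 channels, noise SD 5 µV with a 50/50
white/pink mix (pink via 1/√f spectral shaping), biphasic ~1.4 ms
spike template with negative peak, additive superposition of
overlapping spikes. Spikes are inhomogeneous Poisson at full sample
resolution. Everything is deterministic given the seeds.

The half-wave rectification is the deliberate nonlinearity: a linear
read-out cannot represent the folded part of the drive, so recurrent
networks should (and do) beat the Wiener filter on these sessions,
mirroring the qualitative linear-vs-nonlinear ordering reported for
real parabelt recordings. What the generator does *not* emulate:
adaptation and refractoriness, correlated noise across channels,
movement artifacts, non-Poisson firing statistics, or any
quantitatively calibrated receptive-field structure — there is no
public quantitative encoding model for these neurons, so all generator
parameters are free knobs of the stand-in, not estimates. Passing
tests therefore demonstrate pipeline correctness and recoverability of
a known generative link, not performance on real cortex.

## Problem sizes and numerical choices

Desk-scale defaults: one default session is 16 channels × ~172 s at
30 kS/s (3 tokens × 40 reps); decoder comparisons in the acceptance
suite use 64-unit networks and 5 session seeds. Degenerate inputs are
handled explicitly: constant feature columns fall back to least-squares
pseudo-solutions; the Kalman gain uses a pseudo-inverse so noiseless
steady states do not crash; silence is floored at −120 LUFS;
zero-variance mel bands are excluded from correlation averaging; the
Griffin–Lim spectral-convergence error is recorded per iteration and is
non-increasing.

## Known limitations

Grid execution is a sequential loop (optionally resumable by rerunning
configurations); there is no distributed backend. The Kalman decoder's
`C` placement follows one reading of an underdocumented convention.
The STMI and ESTOI implementations follow the published algorithm
descriptions, not the authors' binaries, so absolute scores on real
speech corpora may differ slightly from reference implementations while
preserving orderings and identities.
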