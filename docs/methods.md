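# Methods

`hypnoseeg` implements a complete EEG analysis chain for identifying *road
hypnosis* — an unconscious driving state induced by monotonous, highly
predictable driving — from frontal EEG. Because real driving-EEG corpora of
this kind are private, the package pairs the analysis chain with a
first-class synthetic-data generator that emulates the statistical
structure the chain assumes, giving every stage a ground truth to be tested
against.

## Synthetic data model

A recording is a linear instantaneous mixture `X = A·S + ε` sampled at
500 Hz on the eight frontal 10–20 channels Fp2, Fpz, Fp1, F4, Fz, F3, FC2,
FC1 plus two mastoid reference channels (M1, M2). The eight latent sources
are:

* **Five narrowband oscillatory sources**, one per canonical band
  — δ (0.5–4 Hz), θ (4–8), α (8–13), β (13–30), γ (30–42). Each source is a
  frequency-wandering sinusoidal carrier (an Ornstein-Uhlenbeck-style walk
  of the instantaneous frequency inside the band interior) plus
  band-filtered Gaussian noise, under a slow (≈0.2 Hz bandwidth) amplitude
  modulation. Defaults: `carrier_fraction = 0.92` of source power in the
  carrier, `am_depth = 0.10`. Two considerations fix these values. First,
  ICA identifiability: narrowband-*filtered* noise alone is essentially
  Gaussian, and no independent-component method can separate Gaussian
  sources; the constant-amplitude carrier makes each source strongly
  sub-Gaussian (excess kurtosis ≈ −1.2), which is also the textbook model
  of a sustained EEG rhythm. Second, epoch-level statistics: a 0.8 s epoch
  resolves a band with only ~6–8 periodogram degrees of freedom, so for a
  purely stochastic source the within-class band-power spread would swamp
  a 1.5× amplitude contrast (a Bayes error around 14%, i.e. an accuracy
  ceiling below 0.9 for *any* classifier); the stable carrier keeps the
  class contrast recoverable at the configured size.
* **A blink artifact source**: biphasic ~300 ms derivative-of-Gaussian
  pulses at Poisson times (default 12/min, 0.5 s refractory period), with a
  steep frontal-pole scalp gradient and ~250 µV peak amplitude at Fp —
  typical EOG scale, an order of magnitude above the EEG rhythms.
* **A cardiac artifact source**: a ~1.2 Hz train of sharp Ricker (QRS-like)
  wavelets with 2% beat-interval jitter, projecting near-uniformly on the
  scalp and strongly onto the mastoids.
* **A broadband heavy-tailed noise source** (filtered Laplace noise,
  diffuse mixed-polarity projection).

Scalp projections are fixed dipolar-style patterns with seeded ±8% jitter.
The signed, spatially diverse topographies matter: with smooth all-positive
patterns the mixing columns are nearly collinear, the mixture's signal
covariance collapses onto ~3 principal axes, and weak sources fall below
the sensor-noise floor before any separation is attempted. Channel-level
sensor noise is white Gaussian, `noise_sd = 2 µV` by default.

Two latent states — RH (road hypnosis) and ND (normal driving) — alternate
in 20 s blocks. They differ *only* by per-band amplitude multipliers on the
oscillatory sources; the default raises θ and α amplitude by 1.5×
(2.25× power) in RH, a configurable stand-in pointing in the direction the
drowsiness/monotony literature reports for frontal slow rhythms, not a
quantitative claim about road hypnosis. Event annotations are emitted every
2 s and labeled with the active state; an event whose 1 s post-onset window
would straddle a block boundary is skipped, so epochs are label-pure.

What the generator does **not** emulate: volume-conducted source
correlations, non-stationary artifact morphology, electrode drift/popping,
1/f background structure, or inter-subject variability. Passing tests
therefore demonstrate the *computational* correctness of the chain under
its stated assumptions, not field performance on real driving EEG.

## Preprocessing

Re-referencing subtracts the bilateral mastoid average from every EEG
channel and drops the mastoids. Filtering uses linear-phase windowed-sinc
FIR kernels (Hamming window): low-pass 30 Hz and notch 40 Hz at order 500
(1 s at 500 Hz), high-pass 0.1 Hz at order 3300 (a narrow transition needs
a long kernel; 6.6 s keeps edge effects manageable). High-pass and notch
kernels are built by spectral inversion (unit impulse minus low-pass /
band-pass), so the DC contracts are exact by construction: low-pass taps
sum to 1, high-pass and notch taps to 0. Gain at the cutoff itself is 0.5
(half-amplitude), the windowed-sinc convention. Application is zero-phase:
symmetric taps, reflect-padding by one kernel length, centred (`same`)
convolution — the effective magnitude response is |H(f)|, not |H(f)|².
The 40 Hz notch default is kept as configured even though mains
interference is usually 50/60 Hz; the centre frequency is a config knob.
A PyWavelets-backed continuous wavelet transform is included as a
comparison path for time-frequency inspection; it is not part of the main
chain.

## FastICA

Whitening is PCA-based (`Z = K(X − μ)`, identity covariance, top
`n_components = 8` eigenvectors). The fixed-point update

    W_new = E{g(WZ) Zᵀ} − diag(E{g′(WZ)}) W,  g = tanh (pow3 optional)

is followed by symmetric decorrelation `W ← (WWᵀ)^{-1/2} W` every sweep;
iteration stops when every row is colinear with its previous iterate
(`tol = 1e-4`, `max_iter = 200`). Non-convergence returns the best iterate
with a warning rather than failing — on near-Gaussian inputs the fixed
point is genuinely shallow. Recovery quality is always assessed
permutation- and sign-invariantly (Hungarian matching on |correlation|).

Artifact components are scored automatically, because a headless pipeline
cannot reproduce visual topography inspection: a blink score combines
frontal-pole projection concentration, positive excess kurtosis, and peak
normalized cross-correlation with a canonical blink pulse; a cardiac score
combines kurtosis with autocorrelation periodicity at physiological beat
lags (0.5–1.2 s). A component is flagged above `threshold = 0.55`, chosen
to sit between the scores oscillatory components reach (≲0.35) and those
of injected artifacts (≳0.65); manual override is always available.
Correction subtracts the back-projection of the flagged components,
`X_corrected = X − A_excluded S_excluded`.

## Epoching and spectral features

Epochs cover the half-open window `[onset + 0.2 s, onset + 1.0 s)` — 400
samples at 500 Hz starting exactly 100 samples after the onset; events that
do not fit are dropped and counted. The PSD of an epoch is the raw
periodogram `|DFT(x)|²/N` on the one-sided grid with non-DC/non-Nyquist
bins doubled, no detrending or tapering by default (Hann and Welch are
options). Under this normalization the one-sided PSD sums to the epoch's
energy `Σ x[n]²` — the Parseval identity asserted in the tests. Band powers
sum bins with `lo ≤ f < hi`; the half-open, lower-edge-inclusive convention
makes the five bands tile 0.5–42 Hz without double-counting the shared
edges at 4, 8, 13 and 30 Hz.

## Classifiers

All networks are implemented in NumPy with hand-written backprop
(im2col/batched-matmul convolutions), trained with Adam (lr 1e-3, batch
32), class-weighted softmax cross-entropy, global gradient-norm clipping at
5 (this matters only for the vanilla RNN), and early stopping on validation
accuracy with best-epoch weight restoration. Data are split 60/20/20
(train/validation/test) by stratified hold-out with largest-remainder
rounding, and standardized per channel with training-set statistics.

* **EEGNet**: temporal conv 1→16, kernel (1, 51), padding (0, 25) (time
  length preserved) → batch norm → depthwise conv 16→32, kernel (1, 10),
  groups 16, valid mode → batch norm → ELU → average pool (1, 4) →
  pointwise 1×1 conv 32→32 → batch norm → ELU → flatten → dropout 0.25 →
  dense 2. For 8×400 input the time axis evolves 400 → 400 → 391 → 97. The
  published parameter table for this family stops at the pooling layer;
  the pointwise block and head here are the minimal completion consistent
  with the three-convolution description, with ELU as the canonical
  activation. Batch norm uses biased batch statistics, ε = 1e-5,
  momentum 0.1.
* **RNN / LSTM baselines**: two layers, input size 1000, hidden size 128,
  final hidden state → dense 2. An 8×400 epoch does not factor into
  1000-wide steps; each step consumes a channel-concatenated 100-sample
  window (800 features) zero-padded to 1000, giving 4 steps per epoch. The
  padding rule is a documented choice — the stated input size is not
  derivable from the epoch geometry.

Class index 0 is RH (the positive class); exact score ties predict ND so a
degenerate model cannot claim detections.

## Benchmark protocol and problem sizes

The standard comparison fixture is 600 label-pure epochs produced by the
full chain (simulate → mastoid re-reference → 30 Hz/0.1 Hz/40 Hz FIR →
automatic ICA cleaning → epoching) from a single base seed. Twenty protocol
seeds then drive the hold-out split, weight initialization, batch order and
dropout; the comparison statistic is the per-model median test accuracy.
Benchmark training uses at most 15 epochs with patience 4 — on this
fixture EEGNet's validation accuracy plateaus within ~5–8 epochs, and the
cap keeps a full 20-seed sweep of all three models around ten minutes on a
single CPU. Observed behaviour: EEGNet median test accuracy ≈ 0.92, LSTM
≈ 0.76, vanilla RNN ≈ 0.5 (chance) — the recurrent baselines receive raw
waveform windows and largely fail to extract the spectral contrast, which
is precisely the representational advantage the convolutional model is
supposed to demonstrate.

## Evaluation

With RH positive: `ACC = (TP+TN)/n`, `SEN = TP/(TP+FN)`,
`SPE = TN/(TN+FP)`, `GM = √(SEN·SPE)`. A zero denominator yields an
explicit *undefined* (`None`), never 0. `GM` as the literal product
`SEN·SPE` (no radical) is available behind a flag for auditability, since
that form occasionally appears in print. Invariants asserted on randomized
matrices: AM–GM (`GM ≤ (SEN+SPE)/2`) and the prevalence decomposition
`ACC = prev·SEN + (1−prev)·SPE`.

## Pipeline and reproducibility

The `hypnoseeg run` pipeline executes simulate → re-reference → filter →
ICA → epoch → features → train → evaluate, hashing every artifact's
*content* (HDF5 embeds timestamps, so byte hashes would not reproduce) into
a JSON manifest; `--resume` recomputes only stages whose outputs are
missing or whose configuration changed. One global seed fans out to
per-stage seeds by fixed offsets. All randomness flows through
`numpy.random.Generator`, so identical config + seed reproduces arrays
bit-for-bit and the final metric report exactly (single-threaded BLAS).
Continuous recordings travel as an HDF5 container (channels × samples with
`fs`/names/reference attributes) and events as TSV (`onset_s`, `label`);
these are the package's boundary formats.

## Known limitations

* The generator's class contrast is a configurable stand-in; no claim is
  made about the true EEG signature of road hypnosis.
* The artifact scorer is tuned to the generator's stereotyped blink and
  cardiac morphologies; real artifacts are more varied.
* The vanilla RNN baseline at chance level reflects a hard input
  representation, not a bug: with four 800-feature raw-waveform steps and
  no spectral prior, the 2-layer tanh RNN overfits its training set while
  generalizing at chance on this task size.
* Welch PSD is provided for completeness but the band-power path is
  tested primarily against the raw periodogram.
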