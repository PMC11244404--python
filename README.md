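# hypnoseeg

An EEG pipeline for identifying **road hypnosis** — the unconscious driving
state induced by monotonous, highly predictable driving environments — from
frontal EEG, built for researchers who want a fully testable, reproducible
version of the standard driver-state analysis chain:

```
simulate/load → mastoid re-reference → FIR filtering (30 Hz LP, 0.1 Hz HP,
40 Hz notch) → FastICA artifact removal → event-locked epoching (0.2–1.0 s)
→ periodogram band-power features → EEGNet / RNN / LSTM classification
→ ACC / SEN / SPE / GM evaluation
```

Real driving-EEG corpora of this kind are private, so the package ships a
first-class synthetic-data generator: a linear mixture `X = A·S + ε` of
five narrowband oscillatory sources (δ, θ, α, β, γ), a frontal blink
source, a cardiac source and broadband noise, projected onto the eight
frontal 10–20 channels (Fp2, Fpz, Fp1, F4, Fz, F3, FC2, FC1) plus two
mastoids at 500 Hz. Two driving states — `RH` (road hypnosis) and `ND`
(normal driving) — differ by per-band amplitude multipliers (default:
θ and α raised 1.5× in RH). Every downstream stage is tested against this
ground truth; see `docs/methods.md` for the model and its limits.

The core quantities, with RH the positive class:

* periodogram PSD per epoch/channel: `PSD(f) = |DFT(x)|² / N`, one-sided;
  band power = Σ PSD bins with `lo ≤ f < hi` over the canonical bands
  δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–42 Hz;
* FastICA: whitening, fixed-point update
  `W ← E{g(WZ)Zᵀ} − diag(E{g′(WZ)}) W` with symmetric decorrelation
  `(WWᵀ)^{-1/2}W`, artifact back-projection subtraction
  `X_corr = X − A_exc S_exc`;
* metrics: `ACC = (TP+TN)/n`, `SEN = TP/(TP+FN)`, `SPE = TN/(TN+FP)`,
  `GM = √(SEN·SPE)`.

All classifiers (EEGNet with temporal → depthwise → pointwise convolution
blocks; 2-layer RNN/LSTM, input 1000, hidden 128) are implemented from
scratch in NumPy with hand-written backprop.

## Worked example

```python
import numpy as np
import hypnoseeg as hs

# 60 s labeled recording under default study conditions
cfg = hs.SyntheticConfig(duration=60.0, seed=42)
rec, events, sources, mixing = hs.simulate(cfg)

# preprocess: mastoid re-reference + FIR chain
rec = hs.rereference(rec)
for spec in (hs.FilterSpec("low-pass", 30.0),
             hs.FilterSpec("high-pass", 0.1),
             hs.FilterSpec("notch", 40.0)):
    rec = hs.apply_filter(rec, hs.design_fir(spec, rec.fs))

# ICA artifact removal (automatic blink/cardiac scoring)
clean, model, scores = hs.clean_recording(rec, seed=0)
print("excluded components:", model.excluded)

# event-locked epochs and band powers
epochs = hs.extract_epochs(clean, events)
psd = hs.compute_psd(epochs)
theta = hs.band_power(psd, "theta")
ratio = theta[psd.labels == "RH"].mean() / theta[psd.labels == "ND"].mean()
print(f"{epochs.n_epochs} epochs of {epochs.epoch_len} samples; "
      f"theta power RH/ND = {ratio:.2f}")
```

prints

```
excluded components: (6, 7)
27 epochs of 400 samples; theta power RH/ND = 2.43
```

— two components flagged (the blink and cardiac sources) and the θ-band
power contrast close to the configured 1.5² = 2.25 (the residual gap is
sampling error at 60 s). The same chain from a shell:

```sh
hypnoseeg run --seed 7 --out runs/        # full pipeline, JSON manifest
hypnoseeg simulate --duration 60 --seed 42 --out fixture/
hypnoseeg preprocess --in fixture/recording.h5 --out pre.h5
```

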