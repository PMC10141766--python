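# mi-compen

Nonlinear-feature analysis of four-class motor-imagery EEG.

Motor imagery (MI) — the mental rehearsal of a movement without executing
it — produces decodable changes in sensorimotor EEG, most prominently
event-related desynchronization (ERD) of the mu/beta rhythms. Brain–computer
interfaces built on MI are used in post-stroke rehabilitation, where a
patient's imagined left-hand / right-hand / foot / tongue movements must be
told apart from 22-channel scalp EEG. This package implements a complete
analysis chain for that problem, aimed at BCI researchers who want every
stage to be individually testable:

1. **I/O** — GDF/EDF recordings in the standard 22 EEG + 3 EOG, 250 Hz
   layout; epoching into 6-s (1500-sample) trials keyed by annotation
   events.
2. **Denoising** — 50 Hz notch and 8–30 Hz band-pass (zero-phase
   Butterworth/IIR), and ICA artifact rejection: sources are estimated by
   SOBI (joint diagonalization of time-lagged covariances) under the linear
   mixing model x(t) = A s(t); a component *i* is flagged ocular when

       XCorr(y_i, eog) = Σ(y−ȳ)(e−ē) / √(Σ(y−ȳ)² Σ(e−ē)²)

   exceeds 0.5 in magnitude against any EOG channel, flagged rows of s(t)
   are zeroed, and the cleaned signal is rebuilt as x̂(t) = A ŝ(t).
3. **CompEn features** — per trial and channel: Higuchi fractal dimension
   (slope of ln L(k) vs ln 1/k, kmax = 20), rescaled-range Hurst exponent
   (slope of log(R/S)ₙ vs log n), Tsallis entropy via Sneddon's
   critical-point approximation (1 − (1/N)Σ sᵢ²/σ²), and dispersion
   entropy (Shannon entropy of NCDF-mapped dispersion patterns).
4. **Screening** — per-feature two-way ANOVA (class × channel) computed
   from the classical sums-of-squares decomposition.
5. **Reduction + classification** — Laplacian Eigenmaps (the generalized
   eigenproblem Ly = λDy on a k-NN graph, constraint YᵀDY = I) feeding
   10-fold stratified cross-validated KNN (k = 5), RBF-SVM (C = 10,
   σ = 0.5) and random-forest (100 trees) classifiers.

A synthetic-data generator with exact ground truth (fractional Gaussian
noise by circulant embedding, known mixing matrices, planted blink
artifacts and class-specific Hurst exponents) exercises every stage, so
the whole pipeline runs and is verified without any external dataset.

## Worked example

```python
import micompen as mc

# four classes with Hurst exponents 0.35/0.50/0.65/0.80 on disjoint
# channel groups, blinks at 12/min, 50 Hz line noise, random mixing
rec, truth = mc.generate_recording(n_trials=40, seed=0)

cleaned, dec = mc.denoise(rec)            # notch -> SOBI zeroing -> band-pass
print(f"flagged {int(dec.artifact_flags.sum())} of {dec.n_components} components,"
      f" max |XCorr| = {dec.xcorr_scores.max():.2f}")

epochs = mc.epoch(cleaned)                # 6-s windows, 1500 samples
ft = mc.extract_features(epochs)          # 40 trials x (22 ch x 4 features)
report = mc.classify_features(ft.values, ft.labels, seed=0)
print(report.summary_frame().round(2))
```

Output:

```
flagged 1 of 22 components, max |XCorr| = 0.70
     accuracy_%  macro_precision_%  macro_recall_%
KNN        80.0               84.0            80.0
SVM       100.0              100.0           100.0
RF        100.0              100.0           100.0
```

One component was identified as the blink source (its time course
correlates 0.70 with the EOG references) and removed; on the reduced
Laplacian-Eigenmap coordinates all three classifiers recover the four
planted classes far above the 25 % chance level.

The same run from a shell:

```bash
mi-compen simulate rec.edf --n-trials 40 --seed 0 --truth-json truth.json
mi-compen run --outdir results --seed 0
```

## Layout

```
src/micompen/
  synthgen.py     synthetic recordings + exact fGn/fBm ground truth
  eeg_io.py       RawRecording/EpochSet, GDF/EDF reading, epoching
  edfwrite.py     minimal EDF+C writer (events as TAL annotations)
  preprocess.py   notch/band-pass, SOBI, XCorr flagging and zeroing
  complexity.py   Higuchi fractal dimension, R/S Hurst exponent
  entropy.py      Tsallis (Sneddon/histogram), dispersion entropy
  features.py     CompEn feature table + sklearn-style extractor
  screening.py    two-way ANOVA screening report
  embedding.py    k-NN graph, Laplacian Eigenmap transformer
  pipeline.py     orchestration, CV harness, metrics
  cli.py          `mi-compen` entry point
docs/methods.md   model, parameter and design notes
```
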