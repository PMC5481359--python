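# Methods

This note records the modeling conventions, defaults, and design choices
behind `zsdecode`, and what the synthetic-data tests do and do not
establish about real recordings.

## Model and protocol

Encoding and decoding are independent ridge regressions per target
(feature or attribute) with shared closed-form solutions. Conventions:

- Attribute rows (one per class) are rescaled ordinal ratings in [−1, 1],
  unit-normalized per row. The trial-level design matrix repeats each
  class's attribute row once per trial of that class — with T training
  trials the normal equations are over T rows, which is the only reading
  consistent with the ridge solution's dimensions.
- Neural feature columns are z-scored with the **sample** standard
  deviation (n−1). Any consistent denominator rescales features uniformly
  and leaves every ranking unchanged; we use the common convention.
  Zero-variance columns are mapped to all-zero (never dropped) with a
  logged warning so feature indices stay stable across folds.
- Decoder target columns (trial-level attribute values) are scaled to unit
  length **within each training fold**. Whether this normalization should
  be per fold or global is underdetermined by the model description; we
  normalize per fold to keep every training-side statistic free of
  held-out information.
- When selected features outnumber training trials the decoder solves the
  equivalent dual system (YYᵀ + λI instead of YᵀY + λI); the two routes
  agree to numerical precision and the tests assert it.
- Regularization grids: λ⁽ᵉⁿ⁾ ∈ logspace(100, 1000, 5) and
  λ⁽ᵈᵉ⁾ ∈ logspace(1, 10, 5). Where a single λ is needed (the wrapper
  selector's inner encoder, single-λ desk runs) we use the geometric
  midpoint of the corresponding grid (≈316.2 and ≈3.162).

Zero-shot identification uses cosine *distance* 1 − cos(u, v) with argmin
— equivalent to maximizing cosine similarity; magnitudes are deliberately
ignored. Ties in the candidate ranking receive the mid-rank, which keeps
the chance level of rank accuracy exactly at 50. In encoding mode the
held-out class's gallery template is the mean of its own trials
(transformed with training statistics); it is part of the identification
gallery, not the training set. In decoding mode the decoder input is the
mean of the held-out class's trials — one prediction per fold, mirroring
the class-average template used on the encoding side; per-trial decoding
is available as an option.

Cumulative MRA-vs-M curves add features in each selector's rank order. The
reported budget grid is trimmed at the smallest candidate pool over folds,
so for the attribute/feature correlation selector the curve genuinely ends
at M′ ≤ P and "smallest M at the peak" is always a realized budget.

## Feature selectors

- **Stability (correlation and Gaussian MI).** A feature's block profile is
  its vector of per-class responses within one block (the within-block
  class mean when blocks contain replicates). For every pair of blocks the
  profile correlation (or the Gaussian mutual information
  −½ log(1 − ρ²), in nats) is computed and averaged over all B(B−1)/2
  pairs. The per-block-pair correlation *over classes* is the convention
  of the stability-selection literature; the alternative per-class
  correlation over blocks degenerates to single points at one trial per
  class per block and is therefore not offered. Degenerate pairs contribute 0
  (correlation) or are capped at ρ² = 1 − 1e−12 (MI), with warnings.
- **Attribute/feature correlation.** Stage 1 matches each attribute to the
  feature with the largest |Pearson r| over all training trials — absolute
  value, since a negatively correlated feature is exactly as useful to a
  linear model. Duplicate winners collapse, so the pool size M′ is at most
  P and often much smaller. Stage 2 ranks the pool by correlation
  stability.
- **Fisher score.** Between-class over pooled within-class spread with
  sample variances; zero-denominator features score +inf (nonzero
  numerator, ranked first) or 0 (constant feature).
- **Ridge wrapper.** An inner LOCO sweep over the training classes (59
  inner folds of 58-class encoders in the full design); each feature is
  scored by the Pearson correlation between its predicted and true
  class-average responses, computed jointly over inner folds (the
  per-fold-then-average variant is statistically noisier at one point per
  fold and is not used).

All selectors see only the fold's training trials. Score ties break by
ascending feature index, making rankings deterministic.

## ECoG front-end

CAR is applied per grid/strip; anti-aliasing uses an 8th-order Butterworth
at 128 Hz applied forward-backward, followed by polyphase resampling to
256 Hz. The 0–750 ms analysis gate (192 samples) yields exactly two
128-sample STFT frames at 50% overlap, centered at 250 and 500 ms; the
1,000 ms pre-onset baseline yields three frames whose mean magnitude per
frequency normalizes the trial spectrogram (this cancels any per-channel
gain). The window function is Hann and configurable; the subregion
averages are insensitive to the choice.

The 12 frequency bands are geometrically spaced in center frequency from
2 to 128 Hz, each spanning one center-to-center step on either side, so
adjacent bands overlap by 50% in log frequency and the lowest edge falls
at ≈1.37 Hz; the top edge is clipped at the 128 Hz Nyquist. The exact band
edges of the original analysis are not recoverable, and a 128-sample FFT
at 256 Hz has 2 Hz native resolution — coarser than the lowest band — so
the FFT is zero-padded (default ×4, configurable) to give the low bands
their own bins. Noisy-channel rejection by visual inspection is replaced
by an optional automated amplitude/variance screen
(`screen_channels`), since by-eye screening is not reproducible.

## Synthetic data

The tabular generator reproduces the study conditions: 60 classes × 6
blocks (one presentation per class per block, order permuted within
block), 218 ordinal attributes mapped (a − 3)/2 into [−1, 1] and
row-normalized, a 2,000-feature pool with 50 informative features. An
informative feature is x·w* (scaled to unit sd over classes) plus white
trial noise of sd 1/snr plus an additive per-(feature, block) drift offset
(sd 0.3 by default — large enough to matter, small relative to signal, as
block effects in repeated-presentation designs typically are); noise
features are white noise with matched marginal variance plus the same
drift process. Planted weights are sparse by default (3 attributes per
informative feature), creating the few-features-highly-correlated-with-
single-attributes regime the attribute/feature selector is designed for; a
dense-weights hard case is available. Drift is additive and constant
within block — the regime correlation stability assumes — and the snr
knob, not drift, controls detectability, because an additive block offset
leaves a profile's across-class correlation unchanged.

The ECoG simulator uses the real schedule (1,000 Hz, 1 s stimulus,
3.5–4.5 s jittered fixation, every class once per block), 1/f background
noise per channel, a shared per-grid common-mode component (removed
exactly by CAR), and class information planted as amplitude-modulated
70–110 Hz band-limited noise on responsive electrodes during the first
750 ms. The default 16 electrodes in two grids is a desk-scale layout;
real implant counts vary per patient (36–114) and carry no single default.
All randomness flows through numpy's PCG64 generator seeded from the
config, so outputs are bit-reproducible.

What the generator does **not** emulate: spatial autocorrelation and
hemodynamics of fMRI voxels, speech artifacts, electrode drift or
impedance changes, and any non-linear attribute→response coding. Passing
tests therefore demonstrate correctness of the algorithms and protocol
under the linear generative model, not performance on real recordings.

## Problem sizes and numerical choices

The test suite runs the full 60 × 6 design for structural and calibration
checks (feature pools of 200–2,000 as each check requires) and smaller
12–20-class designs for unit tests; cumulative curves use a 25-feature
grid step up to the 500-feature cap. Ridge systems are solved with
symmetric positive-definite solvers; λ = 0 on singular designs raises an
error directing the caller to a positive penalty. Chance-level
calibrations permute class labels within blocks, which preserves the
balanced design while destroying the attribute-feature link.

## Known limitations

- The decoder's ranking compares decoded attributes (fit to
  column-normalized targets) against row-normalized candidate attribute
  vectors; cosine distance absorbs the global scale but not per-attribute
  rescaling. This mirrors the model as specified; an exactly self-
  consistent variant would rank against column-rescaled candidates.
- The wrapper selector's cost grows with classes × features; at the full
  design it is the slowest selector by an order of magnitude.
- Mid-ranking assumes exact distance ties; floating-point near-ties are
  ranked strictly.
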