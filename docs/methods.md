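# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `forcetrace`.

## The problem

A sensorized bipolar forceps records tip force on each prong at 20 Hz while
a surgeon operates. A recording is a long, mostly-idle trace punctuated by
force-ON segments — contiguous periods of active tool–tissue interaction.
Each segment belongs to one of five surgical tasks (Coagulation,
Manipulating, Pulling, Retracting, Dissecting) and to a surgeon of known
experience level (Expert or Novice). The pipeline segments the trace
point-wise into ON/OFF, summarizes segments with engineered features, and
classifies segments by task (Coagulation vs non-Coagulation) and by skill.

## Synthetic data generator (`synth`)

Real operating-room recordings are not publicly deposited, so all training,
testing and benchmarking here run on a generator calibrated to the
published summary statistics of such data. What it emulates:

- **Task mix.** Segment tasks are drawn i.i.d. with probabilities equal to
  the observed class frequencies (1170 : 323 : 316 : 149 : 127 over 2085
  segments, i.e. 56.1% Coagulation).
- **Durations.** Per-task lognormal laws, moment-matched analytically to a
  target arithmetic mean/SD (solve `sigma^2 = ln(1 + (s/m)^2)`,
  `mu = ln m − sigma^2/2`). Coagulation: 12.1 s mean, 7.2 s SD. The other
  four tasks share mean 12.1/1.58 ≈ 7.66 s — Coagulation segments run ~58%
  longer — with SD 4.6 s (the source reports no per-task SD for these; 4.6 s
  keeps a coefficient of variation similar to Coagulation's). Durations are
  clipped to ≥ 1 s. A lognormal was chosen because segment durations have
  positive support and the observed duration distribution is positively
  skewed.
- **Waveforms.** Each task has a two-prong waveform family: Coagulation is
  a smooth raised-cosine rise/plateau/fall with slow plateau modulation and
  an 8–9.5 Hz low-amplitude tremor (kept below the 10 Hz Nyquist limit of
  20 Hz sampling); Pulling is a ramp-and-hold; Retracting a long
  low-variance hold; Dissecting short Gaussian force bursts over a low
  baseline; Manipulating irregular low-force wandering (mildly smoothed
  noise, hence broadband). Both prongs share the common waveform plus
  independent noise scaled so the channel Pearson correlation approximates
  `prong_correlation` (default 0.8). All forces are non-negative. Plateau
  amplitudes are uniform per task within sub-2 N ranges typical of
  microsurgical grasping; no amplitude statistics are published, so these
  are unconstrained design values.
- **Idle structure.** OFF gaps are exponential with mean 8 s (no idle
  statistics are published; configurable), with near-zero force plus
  half-normal sensor noise (SD 0.02 N).
- **Skill effects.** Novice segments receive a variance multiplier (1.15),
  broadband noise (SD 0.03 N) and occasional force transients
  (0.05 events/s); Expert segments pass through unchanged. Effect sizes are
  deliberately small: in the real data the two skill classes are nearly
  indistinguishable on engineered features, and the generator reproduces
  that overlap. Skill effects never alter segment duration, matching the
  observed ~0.8% Novice-vs-Expert difference in mean Coagulation duration.

What it does **not** emulate: electro-cautery artifacts, tissue mechanics,
hand kinematics, inter-case drift, or surgeon-specific signatures beyond
the skill effects. Consequently, passing benchmarks here demonstrates that
the pipeline's machinery works end-to-end at realistic signal statistics —
not that the same scores would be reached on operating-room data, where
class boundaries are far less clean.

Generator determinism is bit-exact per `(config, seed)`; every stochastic
element draws from one `numpy` Generator stream.

## Point-wise segmentation (`segmodel`)

**T-U-Net** is a 1-D U-Net over standardized 224-point two-channel
windows: 3 encoder levels (two conv(3)+batch-norm+ReLU blocks each, filters
16/32/64, max-pool ×2 between levels), a 128-filter bottleneck at length
28, and a mirrored decoder (nearest-neighbour upsample ×2 followed by a
learned convolution, skip concatenation, two conv blocks), ending in a
1-wide convolution to per-time-point 2-class logits. Depth 3 was chosen so
the bottleneck keeps a meaningful temporal extent (224 → 28); the filter
schedule doubles from the configured base (default 16).

Training: point-wise softmax cross-entropy, Adam at learning rate 0.001,
early stopping on validation loss with best-epoch weight restore (patience
5–10). Inference tiles a recording into non-overlapping windows
(edge-padding the final partial window and discarding the padded
predictions), yielding one ON probability per sample.

Post-processing (`extract_segments`) binarizes at 0.5, merges ON runs
separated by OFF gaps ≤ `gap_tol` (default 10 samples = 0.5 s — the
reconciliation of noise-driven discontinuities), then discards blocks
shorter than `min_len` (default 40 samples = 2 s). The implementation is
verified against an independent fill-then-scan oracle on all 4,096 binary
masks of length 12 for nine parameter combinations.

## Feature engineering (`features`)

Exactly 29 named scalar features per segment, frozen in canonical order.
Single-channel features are computed on the mean of the two prongs; the
two prong channels additionally contribute Prong Correlation and Prong
Asymmetry (mean |L−R|). Definitions follow the standard time-series
feature canon where the original per-feature table is not available:

- moments/extrema: mean, median, max, min, range, SD (population), IQR,
  RMS, skewness, excess kurtosis, coefficient of variation;
- **Entropy**: Shannon entropy of the DC-free normalized periodogram,
  divided by log of the bin count (∈ [0, 1]; 0 for a pure tone);
- **Stability / Lumpiness**: variance of tiled-window means / variances
  (20-sample tiles = 1 s);
- **Heterogeneity**: ARCH-effect statistic — R² of regressing squared
  demeaned values on 12 lags of themselves;
- **Spikiness**: variance of leave-one-out variances of the residuals of a
  quadratic trend fit;
- Trend Strength, Linearity, Curvature: from orthonormal quadratic
  polynomial regression on time (fraction of variance explained, and the
  two orthonormal-basis coefficients);
- ACF1, First Autocorrelation Zero, Flat Spots (longest run within one of
  10 equal-width amplitude bins), Crossing Points (mean crossings), Peak
  Count, Dominant Frequency, Spectral Centroid.

Degenerate inputs are defined explicitly: constant segments report zero
for variance-derived, spectral and crossing features rather than NaN.
Moment/extremum/counting features match independent brute-force
recomputation to 1e-9; scale invariances (CV, Entropy, Skewness, Prong
Correlation) and linear scalings (Range, SD) are property-tested.

Outlier screening drops rows with any |z| ≥ 3, scores computed once on the
input table. Feature ranking reports KNN (k=5) permutation importance
(10 seeded permutations, accuracy drop) and XGBoost gain importance plus
their rank-sum consensus.

## Recognition models (`recog`)

**FTFIT** stacks inception modules: a 1-wide bottleneck convolution
(32 filters) feeds three parallel convolutions with kernels {10, 20, 40},
joined by a max-pool(3)/1-wide-conv branch; the four 32-filter branches are
concatenated (128 channels), batch-normalized and passed through ReLU. A
residual shortcut (1-wide conv + batch norm on the shortcut path) is added
every third module. Global average pooling produces a 128-dim embedding for
a 2-class softmax head; the embedding is also exposed for the hybrid
logistic head. Defaults follow the InceptionTime lineage (width 32,
kernels {10, 20, 40}); depth 6 is the skill-model default and depth 12 the
full-scale task-model setting. A single network is trained per run; the
original InceptionTime 5-model ensemble is exposed only as a config knob
defaulting to 1.

The engineered-feature channel: the selected features (default the
4-feature dashboard subset) are standardized with training-set statistics,
placed at equally spaced abscissae across the 200-point window,
interpolated with a cubic spline (order configurable; 0 = step), and
appended as the third input channel. One combined channel is the default
reading of "added as the third signal"; per-feature channels are supported.

**LSTM baseline**: 2 stacked layers of 64 units over the same windows,
softmax on the final hidden state (the original topology is unspecified;
these defaults are declared, not inferred). **XGBoost baseline**: boosted
trees on the 29 engineered features only. **Hybrid head**: logistic
regression on the concatenation of the pooled FTFIT embedding and the
standardized engineered features.

## Evaluation (`evalreport`)

Binary decisions threshold the positive-class probability at 0.5.
Sensitivity is recall of the positive class, specificity recall of the
negative. Weighted F1 is the support-weighted mean of per-class F1 and is
re-verified from the confusion matrix. AUC uses the trapezoidal ROC
integral with ties counting one half, so it equals the exhaustive
Mann-Whitney pairwise concordance (tested exactly for n ≤ 200). Macro-AUC
averages one-vs-rest AUCs. Cross-validation is stratified 5-fold, seeded,
every sample tested once. The two-way ANOVA of a feature on task and skill
is additive (no interaction term), matching its use as a marginal-effect
screen. The gauge report maps the dashboard names to features as
Average Force Duration → Duration Force, Range of Forces → Range Force,
Force Variability → SD Force, Force Uncertainty → Entropy; the
variability/uncertainty mappings are declared conventions (configurable),
since the dashboard names are not formally defined as formulas.

## Desk-scale benchmark protocol

All learning benchmarks run on one CPU in minutes, preserving the
pipeline's structure at reduced size:

- **Segmentation**: 400 labeled 224-point windows cut from idle-balanced
  synthetic recordings, nested 64/16/20 split, T-U-Net with filter size 16
  and learning rate 0.001, ≤ 30 epochs with early stopping (patience 5).
  Mini-batches of 16 rather than the full-scale 128: with only 256
  training windows, batch 128 would allow just two optimizer steps per
  epoch, an order of magnitude fewer Adam updates than a full-scale run;
  batch 16 restores a comparable step count while leaving the prescribed
  learning rate, filter size, window length and epoch budget untouched.
  Held-out point-wise weighted F1 ≥ 0.95 is the pass bar (typical runs
  reach ≈ 0.985).
- **Task recognition**: 1,000 generated segments, Coagulation subsampled
  at fraction 0.5 *before* splitting (matching the published balancing
  order), 200-point center-crop/edge-pad windows, subset-1 feature channel,
  FTFIT depth 6 at learning rate 0.001 and batch 128, ≤ 30 epochs.
  Held-out macro-AUC ≥ 0.89 is the pass bar (typical runs exceed 0.99 —
  the synthetic task classes are cleaner than real ones). The LSTM
  baseline trains on identical inputs; the convolutional model's AUC must
  exceed the recurrent baseline's, mirroring the published ordering.
- **Skill-duration invariance** is measured with a paired
  (common-random-numbers) design: each Coagulation duration draw is
  rendered once under each skill condition through the full segment
  pipeline, so the reported Novice-vs-Expert gap isolates the skill-effect
  pathway from duration sampling noise.

## Numerical and implementation notes

- The neural models run on a purpose-built reverse-mode autodiff engine
  over float32 numpy arrays (`forcetrace._nn`). Convolutions use a
  channels-last shift-and-GEMM formulation (one batched matrix product per
  kernel tap) chosen for bandwidth-limited CPUs; batch normalization is a
  fused op with the standard closed-form backward pass. All operators are
  verified against central-difference gradients.
- Determinism: initialization, shuffling and all data generation derive
  from explicit integer seeds; repeated runs are bit-identical on the same
  platform in single-threaded mode.
- Standardization uses population SD and is always fitted on the training
  partition only; zero-variance channels are an error, not a silent skip.
- The nested split draws 20% for test, then 20% of the remainder for
  validation (64/16/20 overall, exact to ±1 item).
- Index conventions are 0-based, half-open `[start, end)` everywhere.
- File formats are plain text: CSV for recordings/segments/features, JSON
  for manifests/metrics, YAML for run configs. Readers reject NaN forces,
  non-uniform time, overlapping segments and unknown labels with errors
  naming the offending row.

## Known limitations

- The 29 feature definitions beyond the explicitly named ones follow the
  public time-series-features canon; the original study's exact formula
  table is not available, so absolute feature values are comparable only
  within this package.
- Synthetic benchmark scores overstate what the same models achieve on
  operating-room data; the benchmarks validate machinery and calibration,
  not clinical performance.
- The skill-classification problem is intentionally near-degenerate under
  the default generator (heavy class overlap); no acceptance bar is set
  for it.
- Training determinism is bit-exact only in single-threaded BLAS mode;
  multi-threaded runs agree to ~1e-6.
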