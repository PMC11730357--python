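# Methods

This note documents the models, procedures and numerical choices behind
`nanotherm`, in the spirit of a methods appendix: what is computed, under
which assumptions, which knobs matter, and what the synthetic benchmarks do
and do not demonstrate.

## Two-state melting-curve analysis

A label-free DSF trace records intrinsic fluorescence at 330 nm and 350 nm
while temperature ramps through the unfolding transition. Each channel is
modeled as a two-state equilibrium between native (N) and denatured (D)
ensembles, each with a linear fluorescence baseline:

    y(T) = [α_N + β_N·T + (α_D + β_D·T)·E(T)] / [1 + E(T)]
    E(T) = exp((ΔH_{D−N}/R)·(1/T_M − 1/T))

Six parameters are fit by trust-region least squares: two baseline
intercept/slope pairs, the midpoint T_M, and the effective van 't Hoff
enthalpy over the gas constant ΔH/R. **Units:** the model is evaluated
directly on Celsius temperatures (initial guesses T_M = 65 °C,
ΔH/R = 3000 °C), matching the labeling protocol this package reproduces.
Because 1/T changes ~20× faster per degree on the Celsius scale than on the
Kelvin scale around physiological temperatures, the Celsius-fit ΔH/R is an
*effective* parameter, roughly Kelvin-ΔH/R divided by 20; it should not be
interpreted thermodynamically. `FitConfig.kelvin=True` switches to a Kelvin
evaluation for users who want thermodynamically meaningful enthalpies.

Per-sample protocol (`analyze_nanodsf_curve`):

1. smooth each trace with a Savitzky–Golay filter (window 21 points,
   order 2; polynomial edge interpolation, since the filter's edge behavior
   is otherwise undefined);
2. fit the 350/330 ratio over the full span → first-pass T_M₀ (the ratio of
   two two-state signals is not itself exactly two-state, so T_M₀ can carry
   a few-tenths-of-a-degree bias; it is only used to place the window);
3. subtract from each channel its own full-trace linear regression (this
   removes most of the temperature dependence of intrinsic fluorescence and
   leaves the model form invariant — a linear offset is absorbed by the
   baselines), then refit the two-state model using only data within
   `refit_halfwidth` of T_M₀;
4. a channel fit is *conclusive* iff the optimizer converged, T_M lies
   strictly inside the window, the transition amplitude (baseline
   separation at T_M) is ≥ 3× the residual standard deviation, and the
   residual sum of squares improves ≥ 50% on a baselines-only linear fit.
   These thresholds replace subjective visual inspection and are tunable;
5. the sample T_m is the mean of the conclusive channel fits
   (`individual_channels`), else T_M₀ (`ratio_fallback`); if even the ratio
   fit fails the sample is flagged unfittable. Replicates aggregate as mean
   ± sample SD.

**Window width.** The per-channel refit is windowed around T_M₀ so the
baseline-corrected transition dominates the fit. With effective ΔH/R ≈ 3000
the 10–90% transition spans 7–10 °C, and a ±5 °C window clips it, making
the six-parameter fit ill-conditioned (recovery MAE degrades ~5× at 1%
noise). The default `refit_halfwidth` is therefore 10 °C — the window keeps
data within 10 °C of the midpoint. Sharper transitions tolerate (and can
benefit from) a tighter window; the parameter exists for that reason.

Initial baseline guesses come from straight-line fits to the first and last
10% of points (`baseline_fraction`); T_M and ΔH/R start at 65 °C and 3000.
Non-convergence never raises: the best-effort parameters return with
`converged=False`.

## Sequence representation

Sequences are aligned to the fixed 149-position antibody variable-domain
numbering scheme; the alignment alphabet is the 20 amino acids plus the gap
symbol. Encodings:

* **one-hot** — 21 indicator channels per column (amino acids in
  alphabetical one-letter order, gap last — the order is arbitrary for
  modeling but frozen for reproducibility), d = 3129;
* **VHSE** — the eight principal-component descriptors of each residue
  (hydrophobic, steric, electronic; the published 20×8 table ships as a
  constant), gap columns contribute eight zeros, d = 1192;
* **external** — per-sequence vectors computed elsewhere (typically
  mean-pooled per-residue language-model states) read from a delimited
  `id, f0..f{d-1}` table, validated and reordered by id.

Numbering uses an adapter interface so any external numbering tool can be
plugged in; the bundled fallback threads a query onto stored germline-like
templates by residue-count match and identity (≥ 0.5), which is sufficient
for template-derived sequences (all fixtures and simulations) but **not** a
substitute for a real numbering tool on diverse repertoire data.

Pairwise identity between aligned sequences counts matching columns over
columns where at least one sequence has a residue; doubly-gapped columns
are excluded from the denominator and residue-vs-gap counts as a mismatch.

## Stratified repeated nested cross-validation

Labels aggregated from the literature mix measurement techniques with
systematic offsets of a few °C, and sequence space is clumped. Both
structures leak into naive random splits. Splits are therefore stratified
on the cross of experimental method × sequence cluster; cells smaller than
`min_class_size` (default 3, the fold count) merge into their method's
pooled class and, if still undersized, into a global `rare` class. The
public `stratified_kfold` enforces every class ≥ k and otherwise raises;
inside the pipeline engines an undersized `rare` class is tolerated and
spread over as many folds as it has members.

Clusters come from PAM-style k-medoids (greedy BUILD initialization, then
alternating assignment/medoid updates; deterministic, ties to the lower
index) on Euclidean distances between one-hot vectors, with k chosen by
knee detection on the inertia-vs-k curve (Kneedle for decreasing convex
curves, sensitivity 1.0, default range 2–30, documented fallback k = 8
when no knee exists).

The evaluation loop, per pipeline seed: outer stratified 3-fold; within
each outer-train subset, features are standardized (train statistics only;
zero-variance columns are centered, not scaled) and ranked by the absolute
coefficients of a ridge fit (penalty fixed at 1.0 on standardized features
— only the ranking is consumed); an inner stratified 3-fold grid search
over hyperparameters × feature-selection sizes, repeated `inner_repeats`
times with scores averaged, selects by mean Spearman ρ; the winner is refit
on the outer-train subset and predicts the outer-test fold (collected into
the out-of-fold table) and the outer-train subset (to report overfitting).
Headline metrics are across-fold/repeat means ± SD; a pooled variant over
all out-of-fold predictions is reported separately since the two
conventions differ slightly.

Metrics: Pearson r, Spearman ρ (average ranks on ties), MAE in °C, and
**SDR = sd(ŷ)/sd(y)** computed per test fold. SDR is the package's
regression-to-the-mean diagnostic: 0 for constant predictions, 1 when
predictions cover the full measured dynamic range. Zero variance in y
leaves r/ρ/SDR undefined; they return NaN with a flag rather than raising.

Default hyperparameter grids (all overridable): ridge/elastic-net/Huber
penalties log-spaced; SVR C ∈ {1, 10, 100}, ε ∈ {0.1, 1}; random forest
200 trees, depth ∈ {None, 10}; gradient-boosted trees 200 trees, 15/31
leaves, learning rate 0.05; Gaussian process with constant×RBF + white
kernel, noise ∈ {0.1, 1}, normalized targets, exact solve guarded to
n ≤ 5000 (the method targets small data; the kernel solve is cubic).
Stochastic regressors receive fold-derived sub-seeds, so identical
configurations reproduce bit-identical out-of-fold tables for the
deterministic families.

## Ensembles

Base models are combined strictly through out-of-fold predictions: each
prediction of sequence i was made by a model whose training fold excluded
i, so the combiner learns in an inference-like regime. Two combiners:

* **ridge stacking** — a ridge meta-model trained on the out-of-fold
  columns with the same stratified nested CV, per seed with that seed's
  fold scheme (penalty grid 0.01–100);
* **averaging** — the unweighted per-sequence mean.

Averaging a set of variance-calibrated predictors keeps their shrinkage
(each fitted model already compresses toward the training mean), while the
stacker's coefficients can rescale the combination back toward the full
dynamic range; averaged SDR therefore sits at or below stacked SDR even
when the two have similar ρ. The stacking-vs-averaging benchmark simulates
base predictors accordingly — as shrinkage-calibrated conditional-mean
estimates ŷᵢ = ȳ + β(y + εᵢ − ȳ), β = σ_y²/(σ_y²+σ_n²), which is what
regression outputs look like; raw unbiased y + ε columns would instead
*inflate* the averaged spread (SDR > 1) and invert the comparison, a
regime fitted models do not produce.

Model selection for ensembling ranks (regressor, encoding) pairs by mean
test Spearman ρ and supports three strategies: best m pairs overall, best
regressor per encoding, best encoding per regressor. A
`bootstrap_metric_distribution` utility quantifies how much r/ρ fluctuate
when evaluated on sub-sampled test sets (without replacement) — small
fractions (a dozen sequences) give dramatically broader distributions than
third-of-the-data folds, a caution against judging predictors on tiny
external sets.

For deployment, each selected base model is re-tuned by stratified CV and
refit on all data; the stacker is tuned and fit on the merged out-of-fold
table. At inference the refit base models feed the stacker. The in-sample
base predictions at inference are distributionally slightly tighter than
the out-of-fold columns the stacker was trained on; this mild mismatch is
inherent to the refit-everything deployment recipe and is accepted. The
bundle serializes scalers, kept feature indices, hyperparameters and fitted
estimators (joblib payload + JSON manifest, versioned).

## Synthetic data: what it emulates, and what it does not

The generator provides the study conditions for every benchmark:

* **sequences** — eight bundled 149-position germline-like templates with
  distinct loop lengths; each sequence is a template with i.i.d.
  substitutions at non-gap positions (substitutions drawn uniformly over
  the other 19 residues, so expected identity to the parent is exactly
  1 − rate). The default rate 0.12 was calibrated once so a generated
  640-sequence set shows ~64% average pairwise identity, the diversity
  level of the curated nanobody T_m compilations it stands in for.
  Template labels are a planted clustering (k-medoids recovers them with
  adjusted Rand ≥ 0.9 at rate ≤ 0.05).
* **labels** — a frozen deterministic surrogate functional: the sum over
  all 7-column sliding windows of tanh(mean hydropathy) plus 0.5 × the sum
  of charge products at column pairs (i, i+3), using published hydropathy
  and side-chain charge scales; gaps contribute zero. The functional is
  deliberately non-additive in one-hot features (saturating windows,
  pairwise terms) so that it exercises nonlinear regressors, yet is exactly
  reproducible and license-free. Scores map affinely onto 50–90 °C; the
  observed label adds a method offset (0, +1.5, −1.0, +0.5 °C for nanoDSF,
  CD, DSF, other — emulating the ~2.4 °C cross-technique discrepancy seen
  when the same molecule is measured twice) and Gaussian noise (default
  2 °C). Methods are drawn with the empirical mixture 251:205:165:19.
* **traces** — forward evaluations of the two-state model on a 0.1 °C grid
  (the sampling cadence of a 2 °C/min instrument ramp from 22 to 95 °C),
  with the 350 nm channel rising and the 330 nm channel falling across the
  transition and additive Gaussian noise as a fraction of each channel's
  amplitude.

What passing these benchmarks shows: the pipelines are internally
consistent, leak-free, correctly calibrated under a known nonlinear
sequence→label map with realistic diversity, noise and heterogeneity
structure. What they do not show: performance on real nanobody
measurements, which carry buffer/concentration/scan-rate variability,
aggregation-coupled irreversibility, and sequence features (unusual loops,
rare frameworks) outside the template family. Synthetic labels are also
noiseless at source; real labels are not.

## Problem sizes and runtime choices

The bundled benchmarks use: 50 simulated traces (plus a 10-curve
brute-force grid oracle cross-check of the optimizer, agreement within
0.1 °C); a 300-sequence dataset for the label-permutation null (all seven
families, two pipeline seeds, VHSE with 256 selected features); 20
replicates of the 4-predictor stacking comparison at n = 300; 100 random
stratification configurations; and a 1000-sequence dataset (300 held out)
for the one-hot learning curve over training sizes 20–640. These sizes
give stable statistics while keeping a full run in the minutes range on a
single CPU; all are parameters, not limits.

## Known limitations

* The bundled template aligner only places sequences derived from its
  template family; real repertoire data needs an external numbering tool
  behind the adapter interface.
* Language-model embeddings are consumed, never computed; the package
  contains no neural networks.
* The two-state model ignores aggregation-coupled and multi-state
  unfolding; scan-rate effects are out of scope.
* The Celsius-mode ΔH/R is effective, not thermodynamic (see above).
* An uncertainty model for deployed predictions (e.g. an error-predicting
  regressor trained on out-of-fold residuals) is a natural extension hook
  but is not implemented.
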