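# nanotherm

Learning nanobody thermostability from small, heterogeneous labeled
datasets.

Nanobodies (VHH single-domain antibodies) are routinely triaged by their
apparent melting temperature T<sub>m</sub>, but public measurements are
scarce (hundreds, not tens of thousands), collected with mutually offset
techniques (nanoDSF, dye-based DSF, DSC, CD), and redundant. `nanotherm` is
a toolkit for building and honestly evaluating sequence-based
T<sub>m</sub> regressors under exactly these conditions. It is aimed at
antibody-engineering and protein-ML practitioners who need to (a) extract
T<sub>m</sub> values from raw fluorescence melting traces, (b) curate and
encode small labeled sequence sets, and (c) train and assess predictors
without fooling themselves about generalization.

## What's inside

**Melting-curve fitting.** Label-free DSF traces (fluorescence at 330 and
350 nm during a temperature ramp) are fit to a two-state denaturation model
with linear native/denatured baselines:

    y(T) = [α_N + β_N·T + (α_D + β_D·T)·E(T)] / [1 + E(T)],
    E(T) = exp((ΔH/R)(1/T_M − 1/T))

The per-sample protocol smooths each trace (Savitzky–Golay, window 21,
order 2), fits the 350/330 ratio for a first-pass T<sub>M</sub>,
baseline-corrects each channel by its own linear regression, refits each
channel in a window around the first-pass midpoint, and averages the
conclusive channel fits (falling back to the ratio fit otherwise).

**Sequence representations.** Sequences are aligned to the fixed
149-position antibody numbering scheme and encoded as one-hot vectors
(149 × 21 = 3129 features; 20 amino acids + gap per column) or VHSE
physicochemical descriptors (149 × 8 = 1192 features); precomputed
language-model embeddings are consumed from delimited tables through an
adapter.

**Evaluation engine.** Repeated stratified nested cross-validation:
splits are stratified on experimental method × k-medoids sequence cluster,
an inner loop tunes hyperparameters and feature-selection sizes (ridge
importance ranking, Spearman scoring), an outer loop measures
generalization, and the whole procedure repeats over seeds. Metrics are
Pearson r, Spearman ρ, MAE (°C), and the standard deviation ratio
SDR = sd(ŷ)/sd(y), which exposes regression toward the dataset mean
(SDR 0 = constant predictions, 1 = full dynamic range). Seven regressor
families are supported (ridge, Huber, elastic net, random forest,
gradient-boosted trees, SVR, Gaussian process).

**Ensembling.** Base models are combined through their out-of-fold
predictions only, either by a ridge stacking meta-model or by plain
averaging. Averaging compresses predictions toward the mean more than
stacking does; the SDR makes this visible when ρ alone would not.

**Synthetic data.** A fully self-contained generator produces
nanobody-like aligned sequences with planted cluster structure (calibrated
to ~64% average pairwise identity), a frozen nonlinear surrogate label
function, method-dependent label offsets and noise, and forward-simulated
two-channel melting traces — so every pipeline is testable end-to-end with
no downloads.

## Worked example

```python
import nanotherm as nt
from nanotherm.modeling import CVConfig, ModelSpec, run_nested_cv, merge_oof
from nanotherm.ensemble import stack_ensemble, average_ensemble

# 1. extract a melting temperature from a (here: simulated) trace
curve = nt.generate_melt_curve(tm=71.3, noise_sd=0.01, seed=5)
res = nt.analyze_nanodsf_curve(curve)
print(res.tm, res.provenance)        # 71.30 individual_channels

# 2. cross-validate four model/encoding combinations on a synthetic dataset
syn = nt.generate_labeled_dataset(nt.SyntheticSpec(n=300, seed=7))
ds = syn.dataset
strata = nt.make_strata(ds.methods, syn.template_labels, min_class_size=6)
cfg = CVConfig(seeds=(101,), inner_repeats=1)
results = []
for enc in ("onehot", "vhse"):
    X = nt.encode_sequences(ds.aligned, enc, ids=ds.ids)
    for reg, grid in (("ridge", {"alpha": [100.0, 1000.0]}),
                      ("support_vector", {"C": [1.0, 10.0], "epsilon": [0.5]})):
        results.append(run_nested_cv(X, ds.tms, strata.labels,
                                     ModelSpec(reg, enc, grid=grid), cfg))

# 3. stack them on their out-of-fold predictions
oof = merge_oof(results)
stacked = stack_ensemble(oof, strata.labels, cfg)
averaged = average_ensemble(oof)
```

Output of the session above:

```
ridge+onehot:          test rho = 0.500 +- 0.034, MAE = 5.39, SDR = 0.41
support_vector+onehot: test rho = 0.487 +- 0.028, MAE = 5.58, SDR = 0.24
ridge+vhse:            test rho = 0.662 +- 0.014, MAE = 4.77, SDR = 0.55
support_vector+vhse:   test rho = 0.591 +- 0.036, MAE = 5.24, SDR = 0.33
stacked:  rho = 0.640, MAE = 5.35, SDR = 0.77
averaged: rho = 0.607,             SDR = 0.36
```

Read: individual models rank sequences reasonably (ρ 0.49–0.66) but
compress the predicted range (SDR 0.24–0.55) on this small noisy dataset.
Averaging their predictions keeps the ranking but compresses further
(SDR 0.36), while ridge stacking restores much of the dynamic range
(SDR 0.77) at comparable ρ — the reason stacking is the preferred
combiner.

A command-line interface mirrors the library
(`nanotherm simulate dataset`, `nanotherm ingest`, `nanotherm encode`,
`nanotherm cluster`, `nanotherm meltfit`, `nanotherm cv`, ...); run
`nanotherm --help`.

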