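"""Model selection, ensemble stacking/averaging, and bootstrap diagnostics.

Base models are combined through their out-of-fold predictions only: a ridge
meta-model is trained on predictions that were each produced by a base model
whose training fold excluded the sequence, so the stacker learns to weigh
the base models in an inference-like regime. Plain unweighted averaging is
provided as the alternative; it tends to regress predictions toward the
dataset mean more than ridge stacking does (lower SDR), which is why
stacking is the preferred combiner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, ContractError
from .features import EmbeddingMatrix
from .modeling import (CVConfig, Metrics, MetricsReport, ModelSpec,
                       NestedCVResult, OOFTable, compute_metrics,
                       run_nested_cv)

SELECTION_STRATEGIES = ("top_combos", "best_per_embedding",
                        "best_per_regressor")

#: meta-model ridge penalty grid
STACKER_GRID = {"alpha": [0.01, 0.1, 1.0, 10.0, 100.0]}


def rank_and_select(
    reports: dict[tuple[str, str], MetricsReport],
    strategy: str = "best_per_embedding",
    m: int = 4,
) -> list[tuple[str, str]]:
    """Order (regressor, encoding) pairs by mean test Spearman rho and pick.

    ``top_combos`` takes the m best pairs overall; ``best_per_embedding``
    the best regressor per encoding (at most m encodings);
    ``best_per_regressor`` the best encoding per regressor (at most m
    regressors).
    """
    if strategy not in SELECTION_STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}")
    scored = sorted(reports.items(),
                    key=lambda kv: -kv[1].test_mean("spearman_rho"))
    if strategy == "top_combos":
        picks = [key for key, _ in scored]
    else:
        group_idx = 1 if strategy == "best_per_embedding" else 0
        best: dict[str, tuple[str, str]] = {}
        for key, _ in scored:                       # already sorted desc
            group = key[group_idx]
            best.setdefault(group, key)
        picks = list(best.values())
    if m > len(picks):
        warnings.warn(f"requested m={m} but only {len(picks)} models "
                      "available", stacklevel=2)
    return picks[:m]


@dataclass
class EnsembleResult:
    """Combined predictions (per seed) and their metrics."""

    predictions: dict[int, np.ndarray]
    report: MetricsReport
    kind: str
    meta: list[NestedCVResult] = field(default_factory=list)

    def mean_prediction(self) -> np.ndarray:
        return np.mean(np.column_stack(list(self.predictions.values())),
                       axis=1)


def stack_ensemble(
    oof_tables: dict[int, OOFTable],
    strata_labels: list[str] | np.ndarray,
    cfg: CVConfig | None = None,
    grid: dict[str, list] | None = None,
) -> EnsembleResult:
    """Ridge-stack base models from their out-of-fold prediction columns.

    Each seed's table is stacked with that same seed's fold scheme (the
    meta-model is itself evaluated by the nested cross-validation pipeline);
    metrics are aggregated across all folds and seeds.
    """
    cfg = cfg or CVConfig()
    if not oof_tables:
        raise ContractError("no out-of-fold tables given")
    report = MetricsReport()
    predictions: dict[int, np.ndarray] = {}
    meta_results: list[NestedCVResult] = []
    pooled_y, pooled_pred = [], []
    for seed, table in oof_tables.items():
        if len(table.columns) < 2:
            raise ContractError("stacking requires >= 2 base-model columns")
        X = EmbeddingMatrix(ids=table.ids, values=table.matrix(),
                            encoding="oof")
        spec = ModelSpec(regressor="ridge", encoding="oof",
                         grid=grid or STACKER_GRID)
        res = run_nested_cv(X, table.y, strata_labels, spec,
                            CVConfig(outer_folds=cfg.outer_folds,
                                     inner_folds=cfg.inner_folds,
                                     inner_repeats=cfg.inner_repeats,
                                     seeds=(seed,)))
        meta_results.append(res)
        preds = res.oof[seed].columns[spec.name]
        predictions[seed] = preds
        report.train_folds.extend(res.report.train_folds)
        report.test_folds.extend(res.report.test_folds)
        pooled_y.append(table.y)
        pooled_pred.append(preds)
    report.pooled_test = compute_metrics(np.concatenate(pooled_y),
                                         np.concatenate(pooled_pred))
    return EnsembleResult(predictions=predictions, report=report,
                          kind="stacked", meta=meta_results)


def average_ensemble(oof_tables: dict[int, OOFTable]) -> EnsembleResult:
    """Unweighted per-sequence mean of the base-model columns."""
    if not oof_tables:
        raise ContractError("no out-of-fold tables given")
    report = MetricsReport()
    predictions: dict[int, np.ndarray] = {}
    pooled_y, pooled_pred = [], []
    for seed, table in oof_tables.items():
        if len(table.columns) < 2:
            raise ContractError("averaging requires >= 2 base-model columns")
        preds = table.matrix().mean(axis=1)
        predictions[seed] = preds
        for fold in np.unique(table.fold_of):
            mask = table.fold_of == fold
            report.test_folds.append(compute_metrics(table.y[mask],
                                                     preds[mask]))
        pooled_y.append(table.y)
        pooled_pred.append(preds)
    report.pooled_test = compute_metrics(np.concatenate(pooled_y),
                                         np.concatenate(pooled_pred))
    return EnsembleResult(predictions=predictions, report=report,
                          kind="averaged")


@dataclass
class BootstrapSummary:
    """Distribution of a correlation metric over random subsamples."""

    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(self.values, [25, 50, 75])
        return float(q1), float(q2), float(q3)

    @property
    def iqr(self) -> float:
        q1, _, q3 = self.quartiles
        return q3 - q1

    @property
    def whiskers(self) -> tuple[float, float]:
        q1, _, q3 = self.quartiles
        lo, hi = q1 - 1.5 * self.iqr, q3 + 1.5 * self.iqr
        inside = self.values[(self.values >= lo) & (self.values <= hi)]
        return float(inside.min()), float(inside.max())


def bootstrap_metric_distribution(
    y: np.ndarray,
    yhat: np.ndarray,
    fraction: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapSummary]:
    """Correlation distributions over subsamples without replacement.

    Quantifies how much an observed r/rho can fluctuate when a model is
    evaluated on a small external set: small fractions give much broader
    distributions than the full test folds do.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if not 0.0 < fraction <= 1.0:
        raise ContractError("fraction must be in (0, 1]")
    size = int(round(fraction * y.size))
    if size < 3:
        raise ContractError(f"subsample size {size} < 3")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(y.size, size=size, replace=False) \
            if size < y.size else np.arange(y.size)
        rs[b] = stats.pearsonr(y[idx], yhat[idx]).statistic
        rhos[b] = stats.spearmanr(y[idx], yhat[idx]).statistic
    return {"pearson_r": BootstrapSummary(rs),
            "spearman_rho": BootstrapSummary(rhos)}
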