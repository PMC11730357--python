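"""Stratified repeated nested cross-validation over regressor families.

The evaluation engine at the heart of the package. For every candidate
(regressor family, encoding) the procedure is, per pipeline seed:

* outer stratified k-fold (default 3 folds) for generalization assessment;
* inside each outer-train subset: standardize (train statistics only),
  rank features by ridge-coefficient magnitude, and run an inner stratified
  k-fold grid search over hyperparameters and feature-selection sizes,
  repeated several times with the scores averaged (selection criterion:
  Spearman rho);
* refit the winning configuration on the whole outer-train subset, predict
  the outer-test fold (collected into an out-of-fold table, the legitimate
  training input for ensemble stacking) and the outer-train subset (to
  report overfitting).

Metrics are Pearson r, Spearman rho, MAE (degC) and the standard deviation
ratio SDR = sd(predicted)/sd(measured), which quantifies regression toward
the dataset mean (0 = constant predictions, 1 = full dynamic range). The
headline aggregation is the across-folds/repeats mean +- sd; a pooled
variant over all out-of-fold predictions is reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import ElasticNet, HuberRegressor, Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVR

from .exceptions import ConfigError, ContractError, ModelError, SplitError
from .features import EmbeddingMatrix, Scaler, select_features

REGRESSOR_FAMILIES: tuple[str, ...] = (
    "ridge", "huber", "elastic_net", "random_forest",
    "gradient_boosted_trees", "support_vector", "gaussian_process",
)

#: default hyperparameter grids per family (overridable via ModelSpec.grid)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ridge": {"alpha": [0.1, 1.0, 10.0, 100.0, 1000.0]},
    "huber": {"alpha": [1e-4, 1e-2, 1.0]},
    "elastic_net": {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.5]},
    "random_forest": {"n_estimators": [200], "max_depth": [None, 10]},
    "gradient_boosted_trees": {"n_estimators": [200],
                               "learning_rate": [0.05],
                               "num_leaves": [15, 31]},
    "support_vector": {"C": [1.0, 10.0, 100.0], "epsilon": [0.1, 1.0]},
    "gaussian_process": {"noise_level": [0.1, 1.0]},
}

#: hard scalability guard for the kernel regressor (the method targets
#: small datasets; the exact kernel solve is cubic in n)
GPR_MAX_N = 5000


def make_regressor(name: str, params: dict, seed: int = 0):
    """Instantiate a regressor family member with the given hyperparameters."""
    if name == "ridge":
        return Ridge(**params)
    if name == "huber":
        return HuberRegressor(max_iter=2000, **params)
    if name == "elastic_net":
        return ElasticNet(max_iter=10000, **params)
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "gradient_boosted_trees":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)
    if name == "support_vector":
        return SVR(**params)
    if name == "gaussian_process":
        p = dict(params)
        noise = p.pop("noise_level", 1.0)
        kernel = ConstantKernel(1.0) * RBF(length_scale=10.0) \
            + WhiteKernel(noise_level=noise)
        return GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                        random_state=seed, **p)
    raise ConfigError(f"unknown regressor family {name!r}; "
                      f"choose from {REGRESSOR_FAMILIES}")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class Metrics:
    pearson_r: float
    spearman_rho: float
    mae: float
    sdr: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"pearson_r": self.pearson_r, "spearman_rho": self.spearman_rho,
                "mae": self.mae, "sdr": self.sdr}


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """r, rho, MAE and SDR for one set of predictions.

    Zero variance in the measured values leaves r/rho/SDR undefined: they are
    returned as NaN with ``degenerate=True`` rather than raising.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size or y.size == 0:
        raise ContractError("y and yhat must have equal nonzero length")
    mae = float(np.mean(np.abs(y - yhat)))
    sd_y = float(np.std(y))
    if sd_y == 0.0:
        return Metrics(np.nan, np.nan, mae, np.nan, degenerate=True)
    sdr = float(np.std(yhat) / sd_y)
    if np.std(yhat) == 0.0:
        return Metrics(0.0, 0.0, mae, 0.0)
    r = float(stats.pearsonr(y, yhat).statistic)
    rho = float(stats.spearmanr(y, yhat).statistic)
    return Metrics(r, rho, mae, sdr)


@dataclass
class MetricsReport:
    """Across-fold metric aggregation for one model, train and test splits."""

    train_folds: list[Metrics] = field(default_factory=list)
    test_folds: list[Metrics] = field(default_factory=list)
    pooled_test: Metrics | None = None

    def _agg(self, folds: list[Metrics], metric: str) -> tuple[float, float]:
        vals = np.array([getattr(m, metric) for m in folds], dtype=float)
        return float(np.nanmean(vals)), float(np.nanstd(vals))

    def test_mean(self, metric: str) -> float:
        return self._agg(self.test_folds, metric)[0]

    def test_sd(self, metric: str) -> float:
        return self._agg(self.test_folds, metric)[1]

    def train_mean(self, metric: str) -> float:
        return self._agg(self.train_folds, metric)[0]

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in ("pearson_r", "spearman_rho", "mae", "sdr"):
            tr_m, tr_s = self._agg(self.train_folds, metric)
            te_m, te_s = self._agg(self.test_folds, metric)
            rows.append({"metric": metric,
                         "train_mean": tr_m, "train_sd": tr_s,
                         "test_mean": te_m, "test_sd": te_s,
                         "pooled_test": getattr(self.pooled_test, metric)
                         if self.pooled_test else np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified folds

def stratified_kfold(
    strata_labels: list[str] | np.ndarray,
    k: int,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold partition over precomputed strata.

    Per-class counts across folds differ by at most one. Classes smaller
    than ``k`` make the split infeasible and raise :class:`SplitError`
    naming the class.
    """
    labels = np.asarray(strata_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    for lab, cnt in zip(uniq, counts):
        if cnt < k:
            raise SplitError(f"stratum {lab!r} has {cnt} members, fewer than "
                             f"k={k} folds")
    return _lenient_stratified_kfold(labels, k, seed)


def _lenient_stratified_kfold(labels: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [(tr, te) for tr, te in
                skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class CVConfig:
    outer_folds: int = 3
    inner_folds: int = 3
    inner_repeats: int = 3
    seeds: tuple[int, ...] = (101, 211, 307)

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigError("fold counts must be >= 2")
        if not self.seeds:
            raise ConfigError("seeds must be nonempty")


@dataclass
class ModelSpec:
    regressor: str
    encoding: str = "onehot"
    grid: dict[str, list] | None = None
    feature_k: tuple = ("all",)

    def __post_init__(self) -> None:
        if self.regressor not in REGRESSOR_FAMILIES:
            raise ConfigError(f"unknown regressor {self.regressor!r}")

    @property
    def name(self) -> str:
        return f"{self.regressor}+{self.encoding}"

    def grid_combos(self) -> list[dict]:
        grid = self.grid if self.grid is not None \
            else DEFAULT_GRIDS[self.regressor]
        keys = list(grid)
        return [dict(zip(keys, combo))
                for combo in product(*(grid[k] for k in keys))]


@dataclass
class OOFTable:
    """Out-of-fold predictions for every sequence, one pipeline seed."""

    ids: list[str]
    y: np.ndarray
    columns: dict[str, np.ndarray]
    seed: int
    fold_of: np.ndarray                    # outer-fold index per sequence
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.columns)
        return np.column_stack([self.columns[n] for n in names])

    def restrict(self, names: list[str]) -> "OOFTable":
        return OOFTable(ids=self.ids, y=self.y,
                        columns={n: self.columns[n] for n in names},
                        seed=self.seed, fold_of=self.fold_of, folds=self.folds)


@dataclass
class NestedCVResult:
    spec: ModelSpec
    report: MetricsReport
    oof: dict[int, OOFTable]
    best_params: list[dict] = field(default_factory=list)


def _spearman(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(yhat) == 0 or np.std(y) == 0:
        return 0.0
    return float(stats.spearmanr(y, yhat).statistic)


def _resolve_k(k, d: int) -> int:
    if k in ("all", None):
        return d
    k = int(k)
    if k > d:
        warnings.warn(f"feature k={k} > d={d}; keeping all features",
                      stacklevel=3)
        return d
    return k


def _fit_predict(spec: ModelSpec, params: dict, k, Xtr, ytr, Xte,
                 importance: np.ndarray, seed: int):
    """Fit one configuration on (already standardized) data; return
    (test predictions, train predictions)."""
    d = Xtr.shape[1]
    kk = _resolve_k(k, d)
    if kk < d:
        order = np.argsort(-importance, kind="stable")
        kept = np.sort(order[:kk])
        Xtr, Xte = Xtr[:, kept], Xte[:, kept]
    if spec.regressor == "gaussian_process" and Xtr.shape[0] > GPR_MAX_N:
        raise ModelError(f"gaussian_process limited to n <= {GPR_MAX_N} "
                         f"(got {Xtr.shape[0]})")
    model = make_regressor(spec.regressor, params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xtr, ytr)
        return model.predict(Xte), model.predict(Xtr)


def _ridge_importance(Xtr: np.ndarray, ytr: np.ndarray) -> np.ndarray:
    sel = select_features(Xtr, ytr, k=Xtr.shape[1], ridge_penalty=1.0)
    return sel.importance


def run_nested_cv(
    X: EmbeddingMatrix,
    y: np.ndarray,
    strata_labels: list[str] | np.ndarray,
    spec: ModelSpec,
    cfg: CVConfig | None = None,
) -> NestedCVResult:
    """Repeated stratified nested cross-validation for one model spec.

    Returns the across-fold metrics report and one out-of-fold table per
    pipeline seed. Every out-of-fold prediction for a sequence comes from a
    model whose outer-training fold excluded that sequence.
    """
    cfg = cfg or CVConfig()
    y = np.asarray(y, dtype=float)
    labels = np.asarray(strata_labels)
    if X.n != y.size or X.n != labels.size:
        raise ContractError("X, y and strata must be aligned")

    candidates = [(params, k) for params in spec.grid_combos()
                  for k in spec.feature_k]
    report = MetricsReport()
    oof: dict[int, OOFTable] = {}
    best_params: list[dict] = []
    pooled_y: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []

    for seed in cfg.seeds:
        # lenient split: a merged "rare" stratum may be smaller than the fold
        # count; it is then spread over as many folds as it has members
        outer = _lenient_stratified_kfold(labels, cfg.outer_folds, seed=seed)
        preds = np.full(X.n, np.nan)
        fold_of = np.full(X.n, -1, dtype=int)
        for fold_idx, (tr, te) in enumerate(outer):
            sub_seed = (seed * 97 + fold_idx) % (2**31 - 1)
            # --- inner grid search -------------------------------------
            if len(candidates) > 1:
                scores = np.zeros(len(candidates))
                n_evals = 0
                for rep in range(cfg.inner_repeats):
                    inner = _lenient_stratified_kfold(
                        labels[tr], cfg.inner_folds,
                        seed=(sub_seed + 7919 * rep) % (2**31 - 1))
                    for itr, ival in inner:
                        gtr, gval = tr[itr], tr[ival]
                        scaler = Scaler.fit(X.values[gtr])
                        Xtr = scaler.transform(X.values[gtr])
                        Xval = scaler.transform(X.values[gval])
                        imp = _ridge_importance(Xtr, y[gtr])
                        for ci, (params, k) in enumerate(candidates):
                            phat, _ = _fit_predict(spec, params, k, Xtr,
                                                   y[gtr], Xval, imp,
                                                   seed=sub_seed)
                            scores[ci] += _spearman(y[gval], phat)
                        n_evals += 1
                scores /= max(n_evals, 1)
                params, k = candidates[int(np.argmax(scores))]
            else:
                params, k = candidates[0]
            best_params.append({"seed": seed, "fold": fold_idx,
                                **params, "feature_k": k})
            # --- refit on the full outer-train subset ------------------
            scaler = Scaler.fit(X.values[tr])
            Xtr = scaler.transform(X.values[tr])
            Xte = scaler.transform(X.values[te])
            imp = _ridge_importance(Xtr, y[tr])
            test_pred, train_pred = _fit_predict(spec, params, k, Xtr, y[tr],
                                                 Xte, imp, seed=sub_seed)
            if not (np.all(np.isfinite(test_pred))
                    and np.all(np.isfinite(train_pred))):
                raise ModelError(f"{spec.name}: non-finite predictions in "
                                 f"fold {fold_idx} (seed {seed})")
            preds[te] = test_pred
            fold_of[te] = fold_idx
            report.test_folds.append(compute_metrics(y[te], test_pred))
            report.train_folds.append(compute_metrics(y[tr], train_pred))
        oof[seed] = OOFTable(ids=list(X.ids), y=y,
                             columns={spec.name: preds}, seed=seed,
                             fold_of=fold_of, folds=outer)
        pooled_y.append(y)
        pooled_pred.append(preds)
    report.pooled_test = compute_metrics(np.concatenate(pooled_y),
                                         np.concatenate(pooled_pred))
    return NestedCVResult(spec=spec, report=report, oof=oof,
                          best_params=best_params)


def merge_oof(results: list[NestedCVResult]) -> dict[int, OOFTable]:
    """Join the per-seed out-of-fold tables of several models column-wise."""
    if not results:
        raise ContractError("no results to merge")
    seeds = list(results[0].oof)
    merged: dict[int, OOFTable] = {}
    for seed in seeds:
        base = results[0].oof[seed]
        columns: dict[str, np.ndarray] = {}
        for res in results:
            tab = res.oof[seed]
            if tab.ids != base.ids:
                raise ContractError("out-of-fold tables have mismatched ids")
            columns.update(tab.columns)
        merged[seed] = OOFTable(ids=base.ids, y=base.y, columns=columns,
                                seed=seed, fold_of=base.fold_of,
                                folds=base.folds)
    return merged


# ---------------------------------------------------------------------------
# learning curves

def learning_curve(
    X: EmbeddingMatrix | np.ndarray,
    y: np.ndarray,
    sizes: list[int],
    holdout: int = 300,
    n_seeds: int = 3,
    alphas: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0),
    cv: int = 5,
) -> pd.DataFrame:
    """Held-out test performance of a ridge model vs training-set size.

    Per seed: reserve a fixed random holdout, then for each size subsample
    the remaining pool, standardize, tune the ridge penalty by k-fold grid
    search (Spearman scoring) and evaluate rho on the holdout. Returns a
    tidy frame with mean +- sd of train and test rho per size.
    """
    values = X.values if isinstance(X, EmbeddingMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    n = values.shape[0]
    if max(sizes) + holdout > n:
        raise ContractError("max(sizes) + holdout exceeds the dataset size")
    rows = []
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        test_idx, pool = perm[:holdout], perm[holdout:]
        for size in sizes:
            if size > pool.size:
                warnings.warn(f"size {size} exceeds the training pool; "
                              "skipped", stacklevel=2)
                continue
            sub = pool[:size]
            scaler = Scaler.fit(values[sub])
            Xtr = scaler.transform(values[sub])
            Xte = scaler.transform(values[test_idx])
            folds = min(cv, size)
            best_alpha, best_score = alphas[0], -np.inf
            for alpha in alphas:
                scores = []
                kf_rng = np.random.default_rng(seed + 1)
                order = kf_rng.permutation(size)
                for f in range(folds):
                    val = order[f::folds]
                    trn = np.setdiff1d(order, val)
                    m = Ridge(alpha=alpha).fit(Xtr[trn], y[sub][trn])
                    scores.append(_spearman(y[sub][val], m.predict(Xtr[val])))
                score = float(np.mean(scores))
                if score > best_score:
                    best_alpha, best_score = alpha, score
            model = Ridge(alpha=best_alpha).fit(Xtr, y[sub])
            rows.append({
                "seed": seed, "size": size, "alpha": best_alpha,
                "train_rho": _spearman(y[sub], model.predict(Xtr)),
                "test_rho": _spearman(y[test_idx], model.predict(Xte)),
            })
    df = pd.DataFrame(rows)
    out = df.groupby("size").agg(
        train_rho_mean=("train_rho", "mean"), train_rho_sd=("train_rho", "std"),
        test_rho_mean=("test_rho", "mean"), test_rho_sd=("test_rho", "std"),
    ).reset_index()
    return out
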