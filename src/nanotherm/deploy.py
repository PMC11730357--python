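"""Final-model training, serialization and batch prediction.

For deployment every selected base model is tuned by stratified
cross-validation and then refit on the whole dataset; the ridge stacker is
tuned and fit on the merged out-of-fold prediction table (never on in-sample
predictions) and at inference combines the refit base models' outputs.
The bundle is a versioned directory: a JSON manifest plus a joblib payload
holding scalers, kept feature indices, hyperparameters and fitted
estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .data_io import Dataset, NumberingBackend, number_sequence, read_fasta
from .exceptions import AlignmentError, ConfigError, ContractError
from .features import (EmbeddingMatrix, Scaler, encode_sequences,
                       one_hot_encode, select_features, vhse_encode)
from .modeling import (CVConfig, ModelSpec, merge_oof, run_nested_cv,
                       _fit_predict, _lenient_stratified_kfold,
                       _ridge_importance, _spearman)
from .strata import Strata, dissimilarity_to_set

BUNDLE_VERSION = "1"


@dataclass
class FittedBase:
    spec: ModelSpec
    params: dict
    feature_k: object
    scaler: Scaler
    kept_indices: np.ndarray
    model: object

    def predict(self, values: np.ndarray) -> np.ndarray:
        X = self.scaler.transform(values)[:, self.kept_indices]
        return np.asarray(self.model.predict(X), dtype=float)


@dataclass
class FinalModel:
    """Deployed ensemble: refit base models plus the ridge stacker."""

    bases: list[FittedBase]
    stacker: Ridge
    train_aligned: list[str]
    train_ids: list[str]
    version: str = BUNDLE_VERSION

    @property
    def encodings(self) -> list[str]:
        return [b.spec.encoding for b in self.bases]

    def predict_from_matrices(
        self, matrices: dict[str, np.ndarray]
    ) -> np.ndarray:
        """Predict from per-encoding matrices (rows aligned across
        encodings)."""
        cols = []
        for base in self.bases:
            enc = base.spec.encoding
            if enc not in matrices:
                raise ConfigError(f"missing embedding matrix for {enc!r}")
            cols.append(base.predict(matrices[enc]))
        return self.stacker.predict(np.column_stack(cols))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": self.version,
            "bases": [{"regressor": b.spec.regressor,
                       "encoding": b.spec.encoding,
                       "params": b.params,
                       "feature_k": b.feature_k}
                      for b in self.bases],
            "n_train": len(self.train_ids),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest,
                                                            indent=2))
        joblib.dump(self, directory / "model.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "FinalModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest["version"] != BUNDLE_VERSION:
            raise ConfigError(f"bundle version {manifest['version']} not "
                              f"supported (expected {BUNDLE_VERSION})")
        return joblib.load(directory / "model.joblib")


def _tune_spec(X: EmbeddingMatrix, y: np.ndarray, labels: np.ndarray,
               spec: ModelSpec, cfg: CVConfig) -> tuple[dict, object]:
    """Stratified CV grid search over a spec's candidates on all data."""
    candidates = [(params, k) for params in spec.grid_combos()
                  for k in spec.feature_k]
    if len(candidates) == 1:
        return candidates[0]
    folds = _lenient_stratified_kfold(labels, cfg.inner_folds,
                                      seed=cfg.seeds[0])
    scores = np.zeros(len(candidates))
    for tr, te in folds:
        scaler = Scaler.fit(X.values[tr])
        Xtr = scaler.transform(X.values[tr])
        Xte = scaler.transform(X.values[te])
        imp = _ridge_importance(Xtr, y[tr])
        for ci, (params, k) in enumerate(candidates):
            phat, _ = _fit_predict(spec, params, k, Xtr, y[tr], Xte, imp,
                                   seed=cfg.seeds[0])
            scores[ci] += _spearman(y[te], phat)
    return candidates[int(np.argmax(scores))]


def train_final(
    ds: Dataset,
    encodings: dict[str, EmbeddingMatrix],
    specs: list[ModelSpec],
    strata: Strata | list[str],
    cfg: CVConfig | None = None,
) -> FinalModel:
    """Tune, refit and bundle the deployed ensemble.

    ``specs`` is the selected base-model list (default selection upstream:
    the best model per encoding). Each base is tuned by stratified CV and
    refit on all data; the ridge stacker is tuned and fit on the merged
    out-of-fold prediction table from the full nested-CV runs.
    """
    cfg = cfg or CVConfig()
    labels = np.asarray(strata.labels if isinstance(strata, Strata)
                        else strata)
    y = ds.tms
    for spec in specs:
        if spec.encoding not in encodings:
            raise ConfigError(f"no embedding matrix provided for "
                              f"{spec.encoding!r}")

    # out-of-fold predictions for stacker training
    results = [run_nested_cv(encodings[s.encoding], y, labels, s, cfg)
               for s in specs]
    oof = merge_oof(results)
    first_seed = cfg.seeds[0]
    oof_matrix = oof[first_seed].matrix([s.name for s in specs])

    # tune + refit each base on all data
    bases: list[FittedBase] = []
    for spec in specs:
        X = encodings[spec.encoding]
        params, k = _tune_spec(X, y, labels, spec, cfg)
        scaler = Scaler.fit(X.values)
        Xs = scaler.transform(X.values)
        sel = select_features(Xs, y, k=X.d if k in ("all", None) else int(k))
        from .modeling import make_regressor
        model = make_regressor(spec.regressor, params, seed=first_seed)
        model.fit(Xs[:, sel.kept_indices], y)
        bases.append(FittedBase(spec=spec, params=params, feature_k=k,
                                scaler=scaler,
                                kept_indices=sel.kept_indices, model=model))

    # tune + fit the stacker on out-of-fold predictions
    best_alpha, best_score = 1.0, -np.inf
    for alpha in (0.01, 0.1, 1.0, 10.0, 100.0):
        scores = []
        for tr, te in _lenient_stratified_kfold(labels, cfg.inner_folds,
                                                seed=first_seed):
            m = Ridge(alpha=alpha).fit(oof_matrix[tr], y[tr])
            scores.append(_spearman(y[te], m.predict(oof_matrix[te])))
        score = float(np.mean(scores))
        if score > best_score:
            best_alpha, best_score = alpha, score
    stacker = Ridge(alpha=best_alpha).fit(oof_matrix, y)

    return FinalModel(bases=bases, stacker=stacker,
                      train_aligned=ds.aligned, train_ids=ds.ids)


def predict_tm(
    model: FinalModel,
    sequences: list[tuple[str, str]] | str | Path,
    backend: NumberingBackend | None = None,
    external_embeddings: dict[str, EmbeddingMatrix] | None = None,
) -> pd.DataFrame:
    """Predict apparent melting temperatures for a batch of sequences.

    ``sequences`` is a FASTA path or a list of ``(id, sequence)`` pairs.
    Unalignable sequences produce per-row failure entries; the batch
    continues. Each successful row reports the predicted Tm and the
    dissimilarity to the most similar training sequence.
    """
    if isinstance(sequences, (str, Path)):
        sequences = read_fasta(sequences)
    rows = []
    aligned_ok: list[tuple[str, str]] = []
    for sid, seq in sequences:
        try:
            aligned_ok.append((sid, number_sequence(seq, backend)))
        except AlignmentError as exc:
            rows.append({"id": sid, "tm_pred": np.nan, "status": "failed",
                         "error": str(exc), "dissimilarity": np.nan,
                         "nearest_id": ""})
    if aligned_ok:
        ids = [sid for sid, _ in aligned_ok]
        aligned = [a for _, a in aligned_ok]
        matrices: dict[str, np.ndarray] = {}
        for enc in set(model.encodings):
            if enc == "onehot":
                matrices[enc] = np.vstack([one_hot_encode(a) for a in aligned])
            elif enc == "vhse":
                matrices[enc] = np.vstack([vhse_encode(a) for a in aligned])
            elif external_embeddings and enc in external_embeddings:
                ext = external_embeddings[enc]
                order = [ext.ids.index(i) for i in ids]
                matrices[enc] = ext.values[order]
            else:
                raise ConfigError(f"no source for encoding {enc!r}")
        preds = model.predict_from_matrices(matrices)
        for (sid, a), tm in zip(aligned_ok, preds):
            dis, nearest = dissimilarity_to_set(a, model.train_aligned,
                                                model.train_ids)
            rows.append({"id": sid, "tm_pred": float(tm), "status": "ok",
                         "error": "", "dissimilarity": dis,
                         "nearest_id": nearest})
    order = {sid: i for i, (sid, _) in enumerate(sequences)}
    df = pd.DataFrame(rows)
    return df.sort_values("id", key=lambda s: s.map(order)) \
             .reset_index(drop=True)
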