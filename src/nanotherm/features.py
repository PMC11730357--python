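"""Fixed-length numeric sequence representations and in-fold preprocessing.

Three families of representations feed the regressors:

* **one-hot** -- each of the 149 alignment columns becomes a 21-channel
  indicator block (20 amino acids alphabetically, gap last), d = 149 x 21
  = 3129;
* **VHSE** -- each column becomes the 8 physicochemical principal-component
  descriptors of its residue (gaps contribute 8 zeros), d = 149 x 8 = 1192;
* **external** -- per-sequence vectors precomputed by an outside model
  (e.g. mean-pooled language-model residue representations), consumed from a
  delimited table ``id, f0..f{d-1}``.

Standardization and ridge-importance feature selection are deliberately
fit-on-train-only operations so cross-validation folds never leak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .data_io import validate_aligned
from .exceptions import ContractError, FormatError
from .scales import AHO_LENGTH, ALPHABET, ALPHABET_INDEX, GAP, VHSE_DIM, vhse_matrix

ONEHOT_DIM = AHO_LENGTH * len(ALPHABET)   # 3129
VHSE_TOTAL_DIM = AHO_LENGTH * VHSE_DIM    # 1192


@dataclass
class EmbeddingMatrix:
    """n sequences x d features with encoding provenance."""

    ids: list[str]
    values: np.ndarray
    encoding: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ContractError("values must be (n_ids, d)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "EmbeddingMatrix":
        idx = list(indices)
        return EmbeddingMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[idx],
            encoding=self.encoding,
        )


def one_hot_encode(aligned: str) -> np.ndarray:
    """One-hot vector of a 149-column alignment (length 3129, 149 ones)."""
    validate_aligned(aligned)
    vec = np.zeros(ONEHOT_DIM)
    width = len(ALPHABET)
    for pos, ch in enumerate(aligned):
        vec[pos * width + ALPHABET_INDEX[ch]] = 1.0
    return vec


def vhse_encode(aligned: str) -> np.ndarray:
    """VHSE vector of a 149-column alignment (length 1192, gaps -> zeros)."""
    validate_aligned(aligned)
    table = vhse_matrix()
    vec = np.zeros(VHSE_TOTAL_DIM)
    for pos, ch in enumerate(aligned):
        if ch != GAP:
            vec[pos * VHSE_DIM:(pos + 1) * VHSE_DIM] = table[ALPHABET_INDEX[ch]]
    return vec


_ENCODERS = {"onehot": one_hot_encode, "vhse": vhse_encode}


def encode_sequences(aligned: Iterable[str], encoding: str,
                     ids: Sequence[str] | None = None) -> EmbeddingMatrix:
    """Encode aligned sequences into an :class:`EmbeddingMatrix`."""
    if encoding not in _ENCODERS:
        raise ContractError(f"unknown encoding {encoding!r}; "
                            f"choose from {sorted(_ENCODERS)}")
    aligned = list(aligned)
    fn = _ENCODERS[encoding]
    values = np.vstack([fn(a) for a in aligned]) if aligned else \
        np.empty((0, ONEHOT_DIM if encoding == "onehot" else VHSE_TOTAL_DIM))
    if ids is None:
        ids = [f"seq{i}" for i in range(len(aligned))]
    return EmbeddingMatrix(ids=list(ids), values=values, encoding=encoding)


def write_embeddings(mat: EmbeddingMatrix, path: str | Path) -> None:
    """Write an embedding matrix as the delimited ``id, f0..f{d-1}`` dialect."""
    df = pd.DataFrame(mat.values, columns=[f"f{i}" for i in range(mat.d)])
    df.insert(0, "id", mat.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_external_embeddings(
    path: str | Path,
    expected_d: int | None = None,
    ids: Sequence[str] | None = None,
    name: str = "external",
) -> EmbeddingMatrix:
    """Load precomputed per-sequence vectors from a delimited table.

    The table must have an ``id`` column plus ``d`` numeric columns. When
    ``ids`` is given, rows are reordered to that id list and any missing ids
    raise a :class:`FormatError` listing them.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    if "id" not in df.columns:
        raise FormatError(f"{path.name}: missing 'id' column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{path.name}: duplicate ids {dupes[:5]}")
    feature_cols = [c for c in df.columns if c != "id"]
    d = len(feature_cols)
    if expected_d is not None and d != expected_d:
        raise FormatError(f"{path.name}: {d} feature columns, expected {expected_d}")
    df = df.set_index("id")
    if ids is not None:
        missing = [i for i in ids if i not in df.index]
        if missing:
            raise FormatError(f"{path.name}: missing ids {missing}")
        df = df.loc[list(ids)]
    values = df[feature_cols].to_numpy(dtype=float)
    return EmbeddingMatrix(ids=list(df.index), values=values,
                           encoding=f"external:{name}")


@dataclass
class Scaler:
    """Column-wise standardizer fitted on a training subset only.

    Zero-variance (constant) columns are centered but not scaled.
    """

    means: np.ndarray
    sds: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance columns

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ContractError("cannot fit a scaler on an empty matrix")
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        constant = sds == 0.0
        sds = np.where(constant, 1.0, sds)
        return cls(means=means, sds=sds, constant=constant)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sds + self.means


def standardize_features(
    train: EmbeddingMatrix, others: Sequence[EmbeddingMatrix] = (),
) -> tuple[Scaler, EmbeddingMatrix, list[EmbeddingMatrix]]:
    """Fit a scaler on ``train`` only; transform train and all ``others``."""
    for other in others:
        if other.d != train.d:
            raise ContractError(
                f"dimension mismatch: train d={train.d}, other d={other.d}")
    scaler = Scaler.fit(train.values)
    train_t = EmbeddingMatrix(train.ids, scaler.transform(train.values),
                              train.encoding)
    others_t = [EmbeddingMatrix(o.ids, scaler.transform(o.values), o.encoding)
                for o in others]
    return scaler, train_t, others_t


@dataclass
class FeatureSelection:
    """Top-k feature indices ranked by ridge-coefficient magnitude."""

    kept_indices: np.ndarray
    importance: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.kept_indices]


def select_features(
    X: np.ndarray | EmbeddingMatrix,
    y: np.ndarray,
    k: int,
    ridge_penalty: float = 1.0,
) -> FeatureSelection:
    """Rank features by |coefficient| of a ridge fit; keep the top ``k``.

    The ridge penalty is fixed (default 1.0 on standardized features): only
    the ranking is consumed, not the fit. Ties are broken by lower index;
    ``k >= d`` keeps everything.
    """
    if isinstance(X, EmbeddingMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ContractError("k must be >= 1")
    d = X.shape[1]
    if k > d:
        warnings.warn(f"k={k} exceeds d={d}; keeping all features",
                      stacklevel=2)
    model = Ridge(alpha=ridge_penalty)
    model.fit(X, y)
    importance = np.abs(model.coef_)
    if k >= d:
        kept = np.arange(d)
    else:
        order = np.argsort(-importance, kind="stable")  # ties -> lower index
        kept = np.sort(order[:k])
    return FeatureSelection(kept_indices=kept, importance=importance)
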