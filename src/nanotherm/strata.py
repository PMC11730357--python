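"""Sequence similarity, k-medoids clustering and stratification labels.

Cross-validation splits are stratified on the cross of experimental method
and sequence-similarity cluster, so every fold sees the same mixture of
measurement techniques and sequence neighborhoods. Clusters come from
k-medoids on the one-hot representation, with the cluster count picked by
knee detection on the inertia-vs-k curve.

Pairwise identity between two 149-column alignments is the fraction of
matching columns among columns where at least one sequence has a residue
(doubly-gapped columns are excluded from the denominator; a residue against
a gap counts as a mismatch).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import validate_aligned
from .exceptions import ConfigError, ContractError
from .features import EmbeddingMatrix
from .scales import GAP


def _char_matrix(aligned: list[str]) -> np.ndarray:
    for a in aligned:
        validate_aligned(a)
    return np.array([list(a) for a in aligned])


def pairwise_identity_matrix(aligned: list[str]) -> np.ndarray:
    """Symmetric n x n matrix of pairwise identity fractions."""
    chars = _char_matrix(aligned)
    n = chars.shape[0]
    gap = chars == GAP
    ident = np.ones((n, n))
    for i in range(n):
        eq = chars[i + 1:] == chars[i]
        both_gap = gap[i + 1:] & gap[i]
        compared = (~both_gap).sum(axis=1)
        matches = (eq & ~both_gap).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(compared > 0, matches / np.maximum(compared, 1), 1.0)
        ident[i, i + 1:] = frac
        ident[i + 1:, i] = frac
    return ident


def identity_to_set(query: str, reference: list[str]) -> np.ndarray:
    """Identity fraction of ``query`` against each reference alignment."""
    if not reference:
        raise ContractError("empty reference set")
    validate_aligned(query)
    chars = _char_matrix(reference)
    q = np.array(list(query))
    both_gap = (chars == GAP) & (q == GAP)
    compared = (~both_gap).sum(axis=1)
    matches = ((chars == q) & ~both_gap).sum(axis=1)
    return np.where(compared > 0, matches / np.maximum(compared, 1), 1.0)


def dissimilarity_to_set(
    query: str, reference: list[str],
    reference_ids: list[str] | None = None,
) -> tuple[float, str | int]:
    """Minimum dissimilarity (1 - max identity) of a query to a set.

    Returns ``(dissimilarity, nearest)`` where ``nearest`` is the id (or
    index) of the most similar reference sequence.
    """
    ident = identity_to_set(query, reference)
    best = int(np.argmax(ident))
    nearest = reference_ids[best] if reference_ids is not None else best
    return float(1.0 - ident[best]), nearest


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    medoid_ids: list[str]
    inertia: float


def _build_init(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD initialization: repeatedly add the medoid that most
    reduces the total distance to the nearest chosen medoid."""
    n = dist.shape[0]
    first = int(np.argmin(dist.sum(axis=0)))
    medoids = [first]
    nearest = dist[first].copy()
    while len(medoids) < k:
        gains = np.minimum(dist, nearest[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        nxt = int(np.argmin(gains))
        medoids.append(nxt)
        nearest = np.minimum(nearest, dist[nxt])
    return medoids


def kmedoids_cluster(
    X: EmbeddingMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """PAM-style k-medoids on Euclidean distances.

    Deterministic: greedy BUILD initialization followed by alternating
    assignment / within-cluster medoid update until stable. ``seed`` is kept
    in the signature for interface stability (the bundled scheme is
    deterministic and seed-free); ties break toward the lower index.
    """
    ids = X.ids if isinstance(X, EmbeddingMatrix) else None
    values = X.values if isinstance(X, EmbeddingMatrix) else np.asarray(X, float)
    n = values.shape[0]
    if not 1 <= k <= n:
        raise ContractError(f"k={k} outside [1, n={n}]")
    dist = squareform(pdist(values, metric="euclidean"))
    medoids = _build_init(dist, k)
    for _ in range(max_iter):
        labels = np.argmin(dist[np.ix_(range(n), medoids)], axis=1)
        new_medoids = list(medoids)
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[int(np.argmin(within))])
        if new_medoids == medoids:
            break
        medoids = new_medoids
    labels = np.argmin(dist[np.ix_(range(n), medoids)], axis=1)
    inertia = float(dist[np.arange(n), [medoids[c] for c in labels]].sum())
    medoid_idx = np.array(medoids)
    return ClusterAssignment(
        k=k,
        labels=labels.astype(int),
        medoid_indices=medoid_idx,
        medoid_ids=[ids[i] for i in medoid_idx] if ids else
                   [str(i) for i in medoid_idx],
        inertia=inertia,
    )


def kneedle_knee(
    x: np.ndarray, y: np.ndarray, sensitivity: float = 1.0,
) -> int | None:
    """Knee of a decreasing convex curve (Kneedle, global-maximum variant).

    Both axes are min-max normalized; the decreasing convex curve is flipped
    to concave increasing and the knee is the x value maximizing the
    difference to the diagonal, provided the maximum clears the sensitivity
    threshold. Returns ``None`` when no knee exists (e.g. a linear decay).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.ptp(y) == 0:
        return None
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y.min()) / np.ptp(y)
    diff = (1.0 - yn) - xn          # flipped curve minus the diagonal
    threshold = sensitivity * np.mean(np.diff(xn))
    best = int(np.argmax(diff))
    if diff[best] <= threshold:
        return None
    return int(round(x[best]))


def choose_k_elbow(
    X: EmbeddingMatrix | np.ndarray,
    k_range: tuple[int, int] = (2, 30),
    seed: int = 0,
    sensitivity: float = 1.0,
    fallback_k: int = 8,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Sweep k, run k-medoids per k, and knee-detect the inertia curve.

    Returns ``(selected_k, ks, inertias)``. When no knee is found the
    documented ``fallback_k`` (clipped to the range) is used with a warning.
    """
    n = X.n if isinstance(X, EmbeddingMatrix) else np.asarray(X).shape[0]
    lo, hi = k_range
    hi = min(hi, n - 1)
    if lo < 2 or lo > hi:
        raise ContractError(f"invalid k range [{lo}, {hi}] for n={n}")
    ks = np.arange(lo, hi + 1)
    inertias = np.array([kmedoids_cluster(X, int(k), seed=seed).inertia
                         for k in ks])
    knee = kneedle_knee(ks, inertias, sensitivity=sensitivity)
    if knee is None:
        knee = int(np.clip(fallback_k, lo, hi))
        warnings.warn(f"no knee found on the inertia curve; falling back to "
                      f"k={knee}", stacklevel=2)
    return knee, ks, inertias


#: merged class labels
POOLED_SUFFIX = "pooled"
RARE_CLASS = "rare"


@dataclass
class Strata:
    """Per-sequence stratification labels (method x cluster, post-merging)."""

    labels: list[str]
    class_counts: dict[str, int]
    min_class_size: int

    def __len__(self) -> int:
        return len(self.labels)


def make_strata(
    methods: list[str],
    clusters: list[int] | np.ndarray,
    min_class_size: int = 3,
) -> Strata:
    """Cross method x cluster into stratification classes, merging small ones.

    Classes below ``min_class_size`` are first pooled within their method
    (label ``"<method>|pooled"``); a pooled class still undersized joins the
    global ``"rare"`` class. The total count is conserved.
    """
    if len(methods) != len(clusters):
        raise ContractError("methods and clusters must have equal length")
    if min_class_size < 2:
        warnings.warn("min_class_size < 2: stratified splits may be "
                      "infeasible", stacklevel=2)
    labels = [f"{m}|{int(c)}" for m, c in zip(methods, clusters)]
    counts = Counter(labels)

    # stage 1: pool undersized cells within their method
    relabel: dict[str, str] = {}
    for lab, cnt in counts.items():
        if cnt < min_class_size:
            method = lab.split("|")[0]
            relabel[lab] = f"{method}|{POOLED_SUFFIX}"
    labels = [relabel.get(lab, lab) for lab in labels]
    counts = Counter(labels)

    # stage 2: pooled classes still undersized join the global rare class
    relabel = {lab: RARE_CLASS for lab, cnt in counts.items()
               if cnt < min_class_size}
    labels = [relabel.get(lab, lab) for lab in labels]
    counts = Counter(labels)
    return Strata(labels=labels, class_counts=dict(counts),
                  min_class_size=min_class_size)
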