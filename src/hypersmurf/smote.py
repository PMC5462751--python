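"""Synthetic minority oversampling (SMOTE) by k-NN linear interpolation.

New minority-class points are generated by picking, for each positive
example ``x``, one of its ``k`` nearest positive neighbours ``x'`` (Euclidean
distance) and interpolating

    x_s = x + lambda * (x' - x),        lambda ~ Uniform[0, 1]

with the neighbour and the interpolation weight redrawn independently for
each of the ``f`` repetitions.  The output therefore contains exactly
``f * |P|`` synthetic points, each lying on the closed segment between its
source positive and the chosen neighbour.

Only the classic Euclidean-interpolation variant is provided; the point of
the module is the exact, auditable geometry (every synthetic point records
the indices of its source and neighbour), not a family of SMOTE flavours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SmoteConfig", "SyntheticSet", "knn_positive_neighbors", "smote_oversample"]


@dataclass(frozen=True)
class SmoteConfig:
    """Parameters of the oversampler.

    Parameters
    ----------
    f
        Oversampling factor: number of synthetic points generated per
        original positive.  Must be >= 1.
    k
        Number of nearest positive neighbours to interpolate towards.
        Clamped to ``|P| - 1`` when the positive set is small.
    seed
        Seed for the neighbour-choice and interpolation-weight draws.
    """

    f: int = 2
    k: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ValueError(f"oversampling factor f must be >= 1, got {self.f}")
        if self.k < 1:
            raise ValueError(f"neighbor count k must be >= 1, got {self.k}")


@dataclass
class SyntheticSet:
    """Synthetic positives plus full interpolation provenance.

    ``vectors[i]`` was generated from source positive ``source_idx[i]`` and
    neighbour ``neighbor_idx[i]`` (both row indices into the positive set
    passed to :func:`smote_oversample`) with interpolation weight
    ``lambdas[i]``.
    """

    vectors: np.ndarray
    source_idx: np.ndarray
    neighbor_idx: np.ndarray
    lambdas: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.vectors)


def _as_positive_matrix(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P.reshape(-1, 1)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("positive set must be a non-empty 2-d array of feature vectors")
    if not np.isfinite(P).all():
        raise ValueError("positive set contains non-finite values")
    return P


def _knn_index_table(P: np.ndarray, k: int) -> np.ndarray:
    """For every positive, the indices of its k nearest other positives.

    Ties at equal distance are broken by ascending row index (stable sort),
    so the table is fully deterministic.
    """
    n = P.shape[0]
    k_eff = min(k, n - 1)
    d = cdist(P, P)
    np.fill_diagonal(d, np.inf)  # never select self
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k_eff]


def knn_positive_neighbors(P, x, k: int) -> np.ndarray:
    """The ``min(k, |P|-1)`` positives nearest to ``x``, excluding ``x`` itself.

    ``x`` must be a member of ``P``; the row matched (first occurrence for
    duplicated points) is excluded from its own neighbour set.  Distances are
    Euclidean; ties are broken by ascending row index.
    """
    P = _as_positive_matrix(P)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 positives to define neighbors")
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != P.shape[1]:
        raise ValueError(f"dimensionality mismatch: x has {x.shape[0]} features, P has {P.shape[1]}")
    matches = np.flatnonzero((P == x).all(axis=1))
    if matches.size == 0:
        raise ValueError("x is not a member of the positive set")
    self_idx = int(matches[0])
    d = np.linalg.norm(P - x, axis=1)
    d[self_idx] = np.inf
    order = np.argsort(d, kind="stable")
    k_eff = min(k, P.shape[0] - 1)
    return P[order[:k_eff]]


def smote_oversample(P, cfg: SmoteConfig) -> SyntheticSet:
    """Generate ``cfg.f`` synthetic examples per positive.

    Draw order (fixed so that seeded runs can be replayed exactly): positives
    are visited in row order; for each positive, each of the ``f`` repetitions
    first draws the neighbour index uniformly from the k-NN list, then the
    interpolation weight ``lambda`` from the unit interval.  Endpoint draws
    (exact duplicates of ``x`` or ``x'``) are allowed.

    With a single positive no interpolation partner exists; the point is
    duplicated ``f`` times and a warning is emitted, preserving the
    ``f * |P|`` cardinality contract.
    """
    P = _as_positive_matrix(P)
    n, d = P.shape
    rng = np.random.default_rng(cfg.seed)

    if n == 1:
        warnings.warn(
            "positive set has a single example; SMOTE interpolation is impossible, "
            "emitting exact duplicates",
            stacklevel=2,
        )
        f = cfg.f
        return SyntheticSet(
            vectors=np.repeat(P, f, axis=0),
            source_idx=np.zeros(f, dtype=int),
            neighbor_idx=np.zeros(f, dtype=int),
            lambdas=np.zeros(f),
        )

    knn = _knn_index_table(P, cfg.k)
    k_eff = knn.shape[1]

    vectors = np.empty((cfg.f * n, d))
    source_idx = np.empty(cfg.f * n, dtype=int)
    neighbor_idx = np.empty(cfg.f * n, dtype=int)
    lambdas = np.empty(cfg.f * n)

    row = 0
    for i in range(n):
        for _ in range(cfg.f):
            j = int(knn[i, rng.integers(k_eff)])
            lam = rng.uniform(0.0, 1.0)
            vectors[row] = P[i] + lam * (P[j] - P[i])
            source_idx[row] = i
            neighbor_idx[row] = j
            lambdas[row] = lam
            row += 1

    return SyntheticSet(vectors=vectors, source_idx=source_idx, neighbor_idx=neighbor_idx, lambdas=lambdas)
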