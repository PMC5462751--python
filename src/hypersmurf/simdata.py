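"""Synthetic imbalanced variant benchmarks.

Generates labelled variant sets with the structure the hyper-ensemble
targets: a handful of deleterious positives drowned in a sea of benign
negatives (real problems sit around 1:700 to 1:36,000), with genomic
coordinates and cytogenetic bands so the genomics-aware CV builders can be
exercised without any external data.

Feature model: negatives are standard multivariate Gaussian noise;
positives come from a small number of Gaussian sub-clusters (unit
within-cluster SD) whose centroids sit at a configurable distance from the
negative centroid.  The sub-cluster structure is deliberate — SMOTE
interpolates between nearby positives, so locality must matter for the
generator to probe it; at zero separation the two classes are identically
distributed by construction.

Coordinate model: a synthetic karyotype of ``n_chrom`` chromosomes, each
divided into ``bands_per_chrom`` equal-width bands; variants get uniform
random positions, and band labels follow from position, so band-atomic
folds are consistent with the interval table by construction.

A companion generator emits reference/alternative chromatin-probability
pairs for the diff/logfold transform: baseline activities are Beta
distributed, negatives perturb the logit only by noise, and positives
additionally shift a random fraction of features by a fixed logit offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import VariantDataset

__all__ = ["SimConfig", "simulate", "simulate_chromatin_pairs", "band_interval_table"]

#: synthetic chromosome length in bp
CHROM_LENGTH = 100_000_000

#: within-cluster SD of positive sub-clusters, equal to the negative
#: within-class SD so that zero separation is an exact null
POSITIVE_CLUSTER_SD = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``separation`` is the distance between each positive sub-cluster
    centroid and the negative centroid, in units of the negative
    within-class SD (= 1); 0 yields a signal-free null, ~2.5 a learnable
    but imperfect signal, >= 4 near-perfect separability.
    """

    n_pos: int = 40
    n_neg: int = 4000
    d: int = 10
    separation: float = 2.5
    n_clusters_pos: int = 3
    n_chrom: int = 5
    bands_per_chrom: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2:
            raise ValueError("need at least 2 positives")
        if self.n_neg < self.n_pos:
            raise ValueError("negatives must be at least as numerous as positives")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.d < 1 or self.n_clusters_pos < 1 or self.n_chrom < 1 or self.bands_per_chrom < 1:
            raise ValueError("dimensions and counts must be >= 1")


def band_interval_table(cfg: SimConfig) -> pd.DataFrame:
    """Half-open (chrom, start, end, name) table of the synthetic bands."""
    width = CHROM_LENGTH // cfg.bands_per_chrom
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        for b in range(cfg.bands_per_chrom):
            rows.append((f"chr{c}", b * width + 1, (b + 1) * width + 1, f"chr{c}_b{b}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _band_of(cfg: SimConfig, pos: np.ndarray) -> np.ndarray:
    width = CHROM_LENGTH // cfg.bands_per_chrom
    return np.minimum((pos - 1) // width, cfg.bands_per_chrom - 1)


def simulate(cfg: SimConfig) -> VariantDataset:
    """Draw an imbalanced labelled variant set with loci and bands."""
    rng = np.random.default_rng(cfg.seed)

    neg = rng.standard_normal((cfg.n_neg, cfg.d))

    # sub-cluster centroids: random directions scaled to |centroid| = separation
    dirs = rng.standard_normal((cfg.n_clusters_pos, cfg.d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centroids = dirs * cfg.separation
    assign = rng.integers(cfg.n_clusters_pos, size=cfg.n_pos)
    pos = centroids[assign] + POSITIVE_CLUSTER_SD * rng.standard_normal((cfg.n_pos, cfg.d))

    features = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(cfg.n_pos, dtype=int), np.zeros(cfg.n_neg, dtype=int)])

    n = cfg.n_pos + cfg.n_neg
    chrom_idx = rng.integers(cfg.n_chrom, size=n)
    positions = rng.integers(1, CHROM_LENGTH + 1, size=n)
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    bands = np.array(
        [f"{c}_b{b}" for c, b in zip(chroms, _band_of(cfg, positions))]
    )
    loci = pd.DataFrame({"chrom": chroms, "pos": positions, "band": bands})

    # shuffle rows so label order carries no information
    order = rng.permutation(n)
    return VariantDataset(
        features=features[order],
        labels=labels[order],
        loci=loci.iloc[order].reset_index(drop=True),
    )


def simulate_chromatin_pairs(
    cfg: SimConfig,
    effect_fraction: float,
    n_chromatin_features: int = 50,
    logit_shift: float = 2.0,
    noise_sd: float = 0.1,
):
    """Reference/alternative probability pairs for the diff/logfold transform.

    Baselines ``p_ref`` are Beta(2, 2); every variant's ``p_alt`` adds
    Gaussian logit noise, and positives additionally shift a random
    ``effect_fraction`` of their features by ±``logit_shift`` on the logit
    scale.  Returns ``(p_ref, p_alt, labels, effect_mask)`` with matrices of
    shape ``(n_pos + n_neg, n_chromatin_features)`` (positives first).
    """
    if not 0 <= effect_fraction <= 1:
        raise ValueError("effect_fraction must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pos + cfg.n_neg
    labels = np.concatenate([np.ones(cfg.n_pos, dtype=int), np.zeros(cfg.n_neg, dtype=int)])

    p_ref = rng.beta(2.0, 2.0, size=(n, n_chromatin_features))
    logit = np.log(p_ref / (1 - p_ref))
    logit_alt = logit + noise_sd * rng.standard_normal(logit.shape)

    effect_mask = np.zeros((n, n_chromatin_features), dtype=bool)
    if effect_fraction > 0:
        effect_mask[: cfg.n_pos] = rng.random((cfg.n_pos, n_chromatin_features)) < effect_fraction
        signs = rng.choice([-1.0, 1.0], size=effect_mask.sum())
        logit_alt[effect_mask] += signs * logit_shift

    p_alt = 1 / (1 + np.exp(-logit_alt))
    return p_ref, p_alt, labels, effect_mask
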