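"""The hyperSMURF training and scoring algorithm.

The method targets extreme class imbalance (hundreds of deleterious
variants against millions of presumed-benign ones).  Training proceeds as:

1. shuffle the negatives and split them into ``n`` disjoint, near-equal
   partitions ``N_1 ... N_n``;
2. for each partition ``i``: oversample the positives by SMOTE (factor
   ``f``, giving ``f|P|`` synthetics), undersample ``N_i`` down to
   ``n_ex = m (f+1) |P|`` negatives, and fit a probabilistic random forest
   on the union ``P + synthetics + sampled negatives``;
3. score a variant as the mean probability-of-deleterious over the ``n``
   forests (the hyper-ensemble score).

With ``m = 1`` every training set is exactly balanced; larger ``m`` trades
balance for negative-class coverage (``m = 3`` is a good default in
practice).  Each forest sees a different negative partition and a freshly
drawn synthetic set, which is the ensemble's diversity source.

A master seed deterministically derives independent sub-streams for the
partition shuffle and, per partition, for SMOTE, undersampling and tree
growth, so results do not depend on the order in which the ``n`` base
learners are trained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data import VariantDataset
from .smote import SmoteConfig, SyntheticSet, smote_oversample

__all__ = [
    "HyperSmurfConfig",
    "TrainedHyperEnsemble",
    "partition_negatives",
    "undersample_negatives",
    "fit",
    "predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperSmurfConfig:
    """Learning parameters of the hyper-ensemble.

    ``n`` — number of negative partitions, hence base random forests.
    ``f`` — SMOTE oversampling factor (synthetics per positive).
    ``m`` — undersampling factor: each forest trains on
    ``m (f+1) |P|`` negatives (``m = 1`` gives exactly balanced sets).
    ``k`` — SMOTE neighbour count.
    ``n_trees`` / ``max_features`` — base random-forest settings; the
    default 10 trees with sqrt(d) features per split keeps desk-scale
    runtime while the hyper-ensemble supplies the committee size.
    ``seed`` — master seed from which all sub-streams derive.
    """

    n: int = 10
    f: int = 2
    m: int = 3
    k: int = 5
    n_trees: int = 10
    max_features: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n", "f", "m", "k", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")

    def n_ex(self, n_pos: int) -> int:
        """Negatives drawn per partition: m (f+1) |P|."""
        return self.m * (self.f + 1) * n_pos


@dataclass
class PartitionRecord:
    """Bookkeeping for one base learner: which rows built its training set."""

    partition: np.ndarray  # negative row indices assigned to this partition
    sampled_negatives: np.ndarray  # subset actually used for training
    synthetic: SyntheticSet  # SMOTE output (provenance included)
    n_pos: int


@dataclass
class TrainedHyperEnsemble:
    """The fitted committee ``M_1 ... M_n`` plus its full provenance."""

    models: list[RandomForestClassifier]
    config: HyperSmurfConfig
    feature_dim: int
    records: list[PartitionRecord] = field(repr=False, default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)


def _master_streams(cfg: HyperSmurfConfig):
    """Partition-shuffle stream plus one independent child per partition."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n + 1)
    return children[0], children[1:]


def partition_negatives(negatives: np.ndarray, n: int, seed) -> list[np.ndarray]:
    """Shuffle the negative row indices and split into ``n`` disjoint parts.

    Part sizes differ by at most one; together they cover every negative.
    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    negatives = np.asarray(negatives)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(negatives) < n:
        raise ValueError(f"cannot split {len(negatives)} negatives into {n} partitions")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(negatives)
    return [np.sort(part) for part in np.array_split(shuffled, n)]


def undersample_negatives(partition: np.ndarray, n_ex: int, seed) -> np.ndarray:
    """Draw ``min(n_ex, |partition|)`` indices uniformly without replacement.

    When the partition is smaller than the requested count the whole
    partition is returned (with a warning) rather than sampling with
    replacement, which would bias the trees towards duplicated negatives.
    """
    partition = np.asarray(partition)
    if partition.size == 0:
        raise ValueError("cannot undersample an empty partition")
    if n_ex < 1:
        raise ValueError("n_ex must be >= 1")
    if n_ex >= partition.size:
        if n_ex > partition.size:
            warnings.warn(
                f"partition holds {partition.size} negatives but {n_ex} were requested; "
                "using the whole partition",
                stacklevel=2,
            )
        return partition.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(partition, size=n_ex, replace=False))


def fit(data: VariantDataset, cfg: HyperSmurfConfig) -> TrainedHyperEnsemble:
    """Train the hyper-ensemble on a labelled variant set."""
    pos = data.positives
    neg = data.negatives
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training data must contain at least one positive and one negative")
    n_eff = cfg.n
    if neg.size < cfg.n:
        warnings.warn(
            f"only {neg.size} negatives for n={cfg.n} partitions; reducing n to {neg.size}",
            stacklevel=2,
        )
        n_eff = int(neg.size)
        cfg = replace(cfg, n=n_eff)

    part_seed, child_seeds = _master_streams(cfg)
    partitions = partition_negatives(neg, n_eff, part_seed)

    X, y = data.features, data.labels
    n_ex = cfg.n_ex(pos.size)
    models: list[RandomForestClassifier] = []
    records: list[PartitionRecord] = []
    for i, (part, child) in enumerate(zip(partitions, child_seeds)):
        smote_seed, under_seed, tree_seed = child.spawn(3)
        synth = smote_oversample(
            X[pos], SmoteConfig(f=cfg.f, k=cfg.k, seed=smote_seed.generate_state(1)[0] % 2**31)
        )
        sampled = undersample_negatives(part, n_ex, under_seed)
        T_X = np.vstack([X[pos], synth.vectors, X[sampled]])
        T_y = np.concatenate([np.ones(pos.size + len(synth), dtype=int), np.zeros(sampled.size, dtype=int)])
        logger.info(
            "partition %d/%d: |P|=%d |P_S|=%d |N'|=%d (training rows=%d)",
            i + 1, n_eff, pos.size, len(synth), sampled.size, len(T_y),
        )
        model = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features=cfg.max_features,
            random_state=int(tree_seed.generate_state(1)[0] % 2**31),
            n_jobs=1,
        )
        model.fit(T_X, T_y)
        models.append(model)
        records.append(
            PartitionRecord(partition=part, sampled_negatives=sampled, synthetic=synth, n_pos=pos.size)
        )

    return TrainedHyperEnsemble(models=models, config=cfg, feature_dim=X.shape[1], records=records)


def predict(model: TrainedHyperEnsemble, X: np.ndarray) -> np.ndarray:
    """Hyper-ensemble score: mean probability-of-deleterious over the forests."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.feature_dim:
        raise ValueError(f"expected {model.feature_dim} features, got {X.shape[1]}")
    scores = np.zeros(X.shape[0])
    for m in model.models:
        # class 1 may be absent from a degenerate forest; look it up explicitly
        pos_col = int(np.flatnonzero(m.classes_ == 1)[0])
        scores += m.predict_proba(X)[:, pos_col]
    return scores / len(model.models)


def save_model(model: TrainedHyperEnsemble, path) -> None:
    """Serialize the full ensemble (config + forests + provenance) to one file."""
    joblib.dump(model, path)


def load_model(path) -> TrainedHyperEnsemble:
    model = joblib.load(path)
    if not isinstance(model, TrainedHyperEnsemble):
        raise TypeError(f"{path} does not contain a trained hyper-ensemble")
    return model
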