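"""Labelled variant sets: the in-memory container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VariantDataset"]

#: columns of the locus table; ``band`` may be absent
LOCUS_COLUMNS = ("chrom", "pos", "band")


@dataclass
class VariantDataset:
    """Feature vectors with binary deleteriousness labels and optional loci.

    Parameters
    ----------
    features
        ``(n_variants, n_features)`` real matrix.
    labels
        Per-variant label: 1 = deleterious (positive), 0 = presumed benign
        (negative).  ``-1`` marks an unlabelled variant (prediction only).
    ids
        Unique variant identifiers; generated as ``v000001...`` if omitted.
    loci
        Optional frame with columns ``chrom`` (str), ``pos`` (1-based int)
        and optionally ``band`` (cytogenetic-band identifier).
    feature_names
        Column names of ``features``; generated as ``feat_0...`` if omitted.
    """

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None
    loci: pd.DataFrame | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-d matrix")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must have one entry per feature row")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain missing or non-finite values")
        if self.ids is None:
            self.ids = np.array([f"v{i + 1:06d}" for i in range(len(self.labels))])
        else:
            self.ids = np.asarray(self.ids, dtype=str)
            if len(np.unique(self.ids)) != len(self.ids):
                ids, counts = np.unique(self.ids, return_counts=True)
                raise ValueError(f"duplicate variant id(s): {', '.join(ids[counts > 1][:5])}")
        if not self.feature_names:
            self.feature_names = [f"feat_{j}" for j in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length does not match feature count")
        if self.loci is not None:
            missing = {"chrom", "pos"} - set(self.loci.columns)
            if missing:
                raise ValueError(f"loci frame lacks required column(s): {sorted(missing)}")
            if len(self.loci) != len(self.labels):
                raise ValueError("loci must have one row per variant")
            if (self.loci["pos"] < 1).any():
                raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_variants(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def positives(self) -> np.ndarray:
        """Row indices of deleterious variants."""
        return np.flatnonzero(self.labels == 1)

    @property
    def negatives(self) -> np.ndarray:
        """Row indices of presumed-benign variants."""
        return np.flatnonzero(self.labels == 0)

    def subset(self, rows: np.ndarray) -> "VariantDataset":
        rows = np.asarray(rows)
        return VariantDataset(
            features=self.features[rows],
            labels=self.labels[rows],
            ids=self.ids[rows],
            loci=None if self.loci is None else self.loci.iloc[rows].reset_index(drop=True),
            feature_names=list(self.feature_names),
        )
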