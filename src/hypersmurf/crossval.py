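"""Genomics-aware cross-validation and negative-selection procedures.

Random CV folds leak information in genomics: variants sharing a locus,
gene or regulatory neighbourhood carry near-identical features, so placing
them on both sides of a train/test split inflates performance.  The fold
builders here keep genomic units atomic:

* cytoband-aware folds — every cytogenetic band lands wholly in one fold;
  bands carrying positives are spread so fold positive counts stay similar;
* topologically-aware folds — negatives are kept only within a fixed
  genomic window of some positive (or inside the same TAD), overlapping
  windows are merged, and each merged window / positive-bearing TAD becomes
  its own fold, so each positive is ranked against its matched negatives;
* progressive subsampling — negatives thinned at a fixed genomic step so
  the imbalance ratio varies while genomic coverage is preserved.

``run_cv`` then produces pooled out-of-fold hyper-ensemble scores with full
per-fold provenance, auditable by :func:`audit_no_leakage`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import VariantDataset
from .ensemble import HyperSmurfConfig, TrainedHyperEnsemble, fit, predict

__all__ = [
    "FoldAssignment",
    "CVResult",
    "LeakageError",
    "assign_cytoband_folds",
    "build_matched_negative_folds",
    "progressive_negative_subsample",
    "genomic_sort_order",
    "run_cv",
    "audit_no_leakage",
    "read_interval_table",
]


@dataclass
class FoldAssignment:
    """Fold id (0-based) per variant; every variant belongs to exactly one fold."""

    fold: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=int)
        if self.fold.size and (self.fold.min() < 0 or self.fold.max() >= self.n_folds):
            raise ValueError("fold ids must lie in [0, n_folds)")

    def to_frame(self, ids) -> pd.DataFrame:
        return pd.DataFrame({"id": np.asarray(ids), "fold": self.fold})


class LeakageError(AssertionError):
    """A variant was scored by a model that saw it (or a fold audit failed)."""


# ---------------------------------------------------------------------------
# genomic ordering


def _chrom_key(chrom: str):
    c = re.sub("^chr", "", str(chrom), flags=re.IGNORECASE)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def genomic_sort_order(chrom, pos) -> np.ndarray:
    """Row order sorting by chromosome (1..22, X, Y, MT, then others) and position."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    keys = [(_chrom_key(c), p, i) for i, (c, p) in enumerate(zip(chrom, pos))]
    return np.array([i for _, _, i in sorted(keys)], dtype=int)


# ---------------------------------------------------------------------------
# cytoband-aware folds


def assign_cytoband_folds(bands, labels, n_folds: int, seed) -> FoldAssignment:
    """Band-atomic folds with balanced per-fold positive counts.

    Bands holding at least one positive are assigned greedily — descending
    positive count, each to the fold currently lightest in positives — so
    fold totals differ by at most the largest band's positive count.  Bands
    with no positives are assigned uniformly at random; every variant
    (negatives included) inherits its band's fold.
    """
    bands = np.asarray(bands, dtype=object)
    labels = np.asarray(labels).astype(int)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if pd.isna(bands).any() or (bands == "").any():
        raise ValueError("every variant needs a cytogenetic band for band-aware CV")

    pos_per_band: dict[str, int] = {}
    for b in np.unique(bands):
        pos_per_band[b] = int(labels[bands == b].sum())

    pos_bands = [b for b, c in pos_per_band.items() if c > 0]
    if len(pos_bands) < n_folds:
        warnings.warn(
            f"only {len(pos_bands)} positive-bearing bands for {n_folds} folds; "
            "some folds will lack positives",
            stacklevel=2,
        )
    # largest first; name tie-break keeps the greedy assignment deterministic
    pos_bands.sort(key=lambda b: (-pos_per_band[b], str(b)))

    band_fold: dict[str, int] = {}
    fold_load = np.zeros(n_folds, dtype=int)
    for b in pos_bands:
        target = int(np.argmin(fold_load))
        band_fold[b] = target
        fold_load[target] += pos_per_band[b]

    rng = np.random.default_rng(seed)
    empty_bands = sorted((b for b, c in pos_per_band.items() if c == 0), key=str)
    for b in empty_bands:
        band_fold[b] = int(rng.integers(n_folds))

    fold = np.array([band_fold[b] for b in bands], dtype=int)
    return FoldAssignment(fold=fold, n_folds=n_folds)


# ---------------------------------------------------------------------------
# matched-negative (window / TAD) folds


def read_interval_table(path) -> pd.DataFrame:
    """Read a BED-like TSV of (chrom, start, end, name), half-open coordinates."""
    tab = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    if (tab["start"] >= tab["end"]).any():
        raise ValueError("interval table contains start >= end")
    return tab


def _merge_intervals(iv: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    merged = []
    for chrom, grp in iv.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # superposed windows collapse into one fold
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def build_matched_negative_folds(
    pos_loci: pd.DataFrame,
    neg_loci: pd.DataFrame,
    window_size: int | None = None,
    tad_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, FoldAssignment]:
    """Select negatives genomically close to a positive; fold per region.

    Window mode: a closed interval ``[pos - size, pos + size]`` around each
    positive; overlapping windows on a chromosome are merged, and each
    merged window is one fold.  TAD mode: each TAD (half-open interval)
    containing at least one positive is one fold; negatives elsewhere are
    dropped.  Should a locus fall inside more than one candidate region
    (overlapping TADs), it joins the fold of its nearest positive.

    Returns the kept negative row indices (into ``neg_loci``) and a
    :class:`FoldAssignment` covering positives first, then the kept
    negatives, in that order.
    """
    if (window_size is None) == (tad_table is None):
        raise ValueError("give exactly one of window_size or tad_table")
    pos_loci = pos_loci.reset_index(drop=True)
    neg_loci = neg_loci.reset_index(drop=True)

    if window_size is not None:
        if window_size <= 0:
            raise ValueError("window size must be a positive number of base pairs")
        win = pd.DataFrame(
            {
                "chrom": pos_loci["chrom"],
                "start": np.maximum(1, pos_loci["pos"] - window_size),
                # closed window -> half-open representation adds 1
                "end": pos_loci["pos"] + window_size + 1,
            }
        )
        regions = _merge_intervals(win)
    else:
        hits = _region_indices(tad_table, pos_loci)
        keep = sorted({r for rs in hits for r in rs})
        if not keep:
            raise ValueError("no TAD contains a positive")
        regions = tad_table.iloc[keep].reset_index(drop=True)[["chrom", "start", "end"]]

    regions = regions.reset_index(drop=True)
    n_folds = len(regions)

    pos_hits = _region_indices(regions, pos_loci)
    pos_fold = np.array(
        [_resolve_region(h, i, pos_loci, pos_loci, regions) for i, h in enumerate(pos_hits)]
    )
    if (pos_fold < 0).any():
        raise ValueError("a positive fell outside every fold region (inconsistent input)")

    neg_hits = _region_indices(regions, neg_loci)
    neg_fold_all = np.array(
        [_resolve_region(h, i, neg_loci, pos_loci, regions) for i, h in enumerate(neg_hits)]
    )
    kept = np.flatnonzero(neg_fold_all >= 0)

    lonely = set(range(n_folds)) - set(neg_fold_all[kept])
    if lonely:
        warnings.warn(
            f"{len(lonely)} fold region(s) contain no matched negatives; "
            "their positives are retained",
            stacklevel=2,
        )

    fold = np.concatenate([pos_fold, neg_fold_all[kept]])
    return kept, FoldAssignment(fold=fold, n_folds=n_folds)


def _region_indices(regions: pd.DataFrame, loci: pd.DataFrame) -> list[list[int]]:
    """For each locus, the indices of regions (half-open) containing it."""
    out: list[list[int]] = []
    by_chrom = {c: g for c, g in regions.groupby("chrom", sort=False)}
    for chrom, pos in zip(loci["chrom"], loci["pos"]):
        grp = by_chrom.get(chrom)
        if grp is None:
            out.append([])
            continue
        mask = (grp["start"] <= pos) & (pos < grp["end"])
        out.append(list(grp.index[mask]))
    return out


def _resolve_region(
    hits: list[int], row: int, loci: pd.DataFrame, pos_loci: pd.DataFrame, regions: pd.DataFrame
) -> int:
    if not hits:
        return -1
    hits = sorted(hits)
    if len(hits) == 1:
        return hits[0]
    # ambiguous (overlapping regions): join the fold of the nearest positive
    chrom = loci["chrom"].iloc[row]
    pos = loci["pos"].iloc[row]
    same = pos_loci[pos_loci["chrom"] == chrom]
    if not same.empty:
        nearest = int(same["pos"].iloc[int(np.argmin(np.abs(same["pos"].to_numpy() - pos)))])
        for h in hits:
            if regions["start"].iloc[h] <= nearest < regions["end"].iloc[h]:
                return h
    return hits[0]


# ---------------------------------------------------------------------------
# progressive imbalance subsampling


def progressive_negative_subsample(
    neg_loci: pd.DataFrame, target_count: int, assume_sorted: bool = False
) -> np.ndarray:
    """Thin negatives to ``target_count`` by taking every s-th along the genome.

    Negatives are ordered by genomic position (chromosome in natural order,
    then position), the step ``s = floor(|N| / target_count)`` is computed,
    and ranks ``0, s, 2s, ...`` are selected until ``target_count`` rows are
    chosen.  Density drops uniformly while first-to-last genomic coverage is
    preserved.  Returns row indices into ``neg_loci``.
    """
    n = len(neg_loci)
    if not 1 <= target_count <= n:
        raise ValueError(f"target_count must be in [1, {n}], got {target_count}")
    order = (
        np.arange(n)
        if assume_sorted
        else genomic_sort_order(neg_loci["chrom"].to_numpy(), neg_loci["pos"].to_numpy())
    )
    s = n // target_count
    picks = order[np.arange(target_count) * s]
    return np.sort(picks)


# ---------------------------------------------------------------------------
# cross-validated scoring


@dataclass
class FoldRecord:
    """Provenance of one CV fold: which rows trained the model that scored it."""

    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    model: TrainedHyperEnsemble = field(repr=False, default=None)


@dataclass
class CVResult:
    """Pooled out-of-fold scores plus per-fold provenance."""

    scores: np.ndarray
    folds: FoldAssignment
    records: list[FoldRecord] = field(repr=False, default_factory=list)


def run_cv(
    data: VariantDataset,
    folds: FoldAssignment,
    cfg: HyperSmurfConfig,
    keep_models: bool = False,
) -> CVResult:
    """Out-of-fold hyper-ensemble scores.

    For every fold: fit on all other folds (SMOTE synthetics therefore
    derive only from training-fold positives) and score the held-out fold.
    Each fold's model derives its seed from the master seed and the fold id,
    so reruns are bit-identical and fold order is immaterial.
    """
    if len(folds.fold) != data.n_variants:
        raise ValueError("fold assignment does not cover the dataset")
    scores = np.full(data.n_variants, np.nan)
    records: list[FoldRecord] = []
    root = np.random.SeedSequence(cfg.seed)
    fold_seeds = root.spawn(folds.n_folds)
    from dataclasses import replace

    for j in range(folds.n_folds):
        test_idx = np.flatnonzero(folds.fold == j)
        train_idx = np.flatnonzero(folds.fold != j)
        if test_idx.size == 0:
            continue
        train_labels = data.labels[train_idx]
        if (train_labels == 1).sum() == 0:
            raise ValueError(f"fold {j}: training split contains no positives")
        if (train_labels == 0).sum() == 0:
            raise ValueError(f"fold {j}: training split contains no negatives")
        fold_cfg = replace(cfg, seed=int(fold_seeds[j].generate_state(1)[0] % 2**31))
        model = fit(data.subset(train_idx), fold_cfg)
        scores[test_idx] = predict(model, data.features[test_idx])
        records.append(
            FoldRecord(
                fold_id=j,
                train_indices=train_idx,
                test_indices=test_idx,
                model=model if keep_models else None,
            )
        )

    result = CVResult(scores=scores, folds=folds, records=records)
    audit_no_leakage(result, data.n_variants)
    return result


def audit_no_leakage(result: CVResult, n_variants: int) -> None:
    """Verify that no variant was scored by a model trained on it.

    Checks, for every fold record, that train and test rows are disjoint,
    and that the test sets tile the dataset exactly once.  Raises
    :class:`LeakageError` on any violation — including a deliberately
    planted duplicate of a held-out row in the training indices.
    """
    seen = np.zeros(n_variants, dtype=int)
    for rec in result.records:
        overlap = np.intersect1d(rec.train_indices, rec.test_indices)
        if overlap.size:
            raise LeakageError(
                f"fold {rec.fold_id}: row(s) {overlap[:5].tolist()} appear in both "
                "its training and its test set"
            )
        seen[rec.test_indices] += 1
    if (seen > 1).any():
        raise LeakageError("some variants were scored in more than one fold")
    if (seen == 0).any():
        raise LeakageError("some variants were never scored out-of-fold")
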