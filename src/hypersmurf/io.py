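"""Reading and writing the native tab-separated exchange formats.

The native variant table is a TSV with header columns ``id``, ``chrom``,
``pos`` (1-based), ``band`` (optional), ``label`` (0, 1 or NA, NA allowed
only for prediction inputs), followed by real-valued feature columns.  TSV
rather than VCF is deliberate: the scorer consumes feature matrices, not
genotypes.  Every file written by the package embeds the fully resolved run
configuration as ``# key=value`` comment lines, sufficient to reproduce the
run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import VariantDataset

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_scores",
    "write_scores",
    "read_header_config",
]

RESERVED_COLUMNS = ("id", "chrom", "pos", "band", "label")

#: fixed float format so identical runs produce byte-identical files
FLOAT_FORMAT = "%.10g"


def _config_header(config: dict | None) -> str:
    if not config:
        return ""
    return "".join(f"# {key}={config[key]}\n" for key in sorted(config))


def read_header_config(path) -> dict:
    """Parse the ``# key=value`` comment header of any package-written file."""
    config = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                config[key.strip()] = value.strip()
    return config


def read_variant_table(path) -> VariantDataset:
    """Read and validate a native variant TSV."""
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str, "chrom": str, "band": str})
    if "id" not in tab.columns or "label" not in tab.columns:
        raise ValueError(f"{path}: missing required column(s) 'id'/'label' in header")
    dup = tab["id"][tab["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate variant id '{dup.iloc[0]}'")

    feature_cols = [c for c in tab.columns if c not in RESERVED_COLUMNS]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns found after {RESERVED_COLUMNS}")
    for col in feature_cols:
        values = pd.to_numeric(tab[col], errors="coerce")
        bad = values.index[values.isna() & tab[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value '{tab[col].iloc[bad[0]]}' in feature column "
                f"'{col}' at data line {bad[0] + 2}"
            )
        if values.isna().any():
            raise ValueError(f"{path}: missing value in feature column '{col}'")
        tab[col] = values

    labels = tab["label"].map(lambda v: -1 if pd.isna(v) else int(v)).to_numpy()
    if not np.isin(labels, (-1, 0, 1)).all():
        raise ValueError(f"{path}: labels must be 0, 1 or NA")

    loci = None
    if {"chrom", "pos"} <= set(tab.columns):
        loci = tab[["chrom", "pos"]].copy()
        if "band" in tab.columns:
            loci["band"] = tab["band"]
    return VariantDataset(
        features=tab[feature_cols].to_numpy(dtype=float),
        labels=labels,
        ids=tab["id"].to_numpy(),
        loci=loci,
        feature_names=feature_cols,
    )


def write_variant_table(data: VariantDataset, path, config: dict | None = None) -> None:
    """Write a dataset as the native TSV, with a reproducibility header."""
    frame = pd.DataFrame({"id": data.ids})
    if data.loci is not None:
        frame["chrom"] = data.loci["chrom"].to_numpy()
        frame["pos"] = data.loci["pos"].to_numpy()
        if "band" in data.loci.columns:
            frame["band"] = data.loci["band"].to_numpy()
    frame["label"] = pd.array(data.labels).astype("object")
    frame.loc[np.asarray(data.labels) == -1, "label"] = "NA"
    for j, name in enumerate(data.feature_names):
        frame[name] = data.features[:, j]
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_scores(ids, scores, path, config: dict | None = None, labels=None, folds=None) -> None:
    """Write per-variant scores (optionally with labels and fold ids) as TSV."""
    frame = pd.DataFrame({"id": np.asarray(ids), "score": np.asarray(scores, dtype=float)})
    if labels is not None:
        frame.insert(1, "label", np.asarray(labels))
    if folds is not None:
        frame["fold"] = np.asarray(folds)
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_scores(path) -> pd.DataFrame:
    """Read a score TSV (columns ``id``, ``score``, optionally ``label``/``fold``)."""
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    if "score" not in tab.columns:
        raise ValueError(f"{path}: missing 'score' column")
    return tab
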