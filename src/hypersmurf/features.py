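"""Chromatin-effect feature transforms.

Deep sequence models score a variant by predicting, for each of hundreds of
chromatin features (DNase hypersensitivity, TF binding, histone marks), the
probability that the feature is active in the 1000-bp window carrying the
reference allele and in the window carrying the alternative allele.  Two
complementary summaries of each probability pair feed the classifier:

    diff    = |P(ref) - P(alt)|                       (bounded by 1)
    logfold = |logit(P(ref)) - logit(P(alt))|          (unbounded)

``diff`` measures the raw probability change; ``logfold`` amplifies changes
near the saturated ends of the probability scale.  The assembled matrix is
all diffs, then all logfolds, then any appended conservation columns, and
is globally standardised to zero mean and unit variance before training.
"""

from __future__ import annotations

import numpy as np
from sklearn.preprocessing import StandardScaler

__all__ = ["diff_logfold", "assemble_feature_matrix", "standardize", "apply_standardization"]

#: probabilities are clipped into [CLIP_EPS, 1 - CLIP_EPS] so logits stay finite
CLIP_EPS = 1e-6


def diff_logfold(p_ref, p_alt, eps: float = CLIP_EPS):
    """Absolute probability difference and absolute log-odds change.

    Accepts scalars or arrays (broadcast together).  Inputs must lie in
    [0, 1]; values are clipped to ``[eps, 1 - eps]`` before the logit.
    The natural logarithm is used; the base only rescales the feature and
    is immaterial after standardisation.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_alt = np.asarray(p_alt, dtype=float)
    for name, p in (("p_ref", p_ref), ("p_alt", p_alt)):
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            raise ValueError(f"{name} must contain probabilities in [0, 1]")
    p_ref = np.clip(p_ref, eps, 1 - eps)
    p_alt = np.clip(p_alt, eps, 1 - eps)
    diff = np.abs(p_ref - p_alt)
    logit = lambda p: np.log(p / (1 - p))  # noqa: E731
    logfold = np.abs(logit(p_ref) - logit(p_alt))
    return diff, logfold


def assemble_feature_matrix(p_ref, p_alt, conservation=None):
    """Build the per-variant feature matrix from probability pairs.

    ``p_ref`` and ``p_alt`` are ``(n_variants, n_chromatin_features)``
    matrices.  Output columns are ordered: all diffs (one per chromatin
    feature), all logfolds, then conservation columns, giving
    ``2 * n_chromatin_features + n_conservation`` columns — e.g. 919
    chromatin features yield 1838 transform columns, 1842 with the four
    standard conservation scores appended.

    Returns ``(matrix, column_names)``.
    """
    p_ref = np.atleast_2d(np.asarray(p_ref, dtype=float))
    p_alt = np.atleast_2d(np.asarray(p_alt, dtype=float))
    if p_ref.shape != p_alt.shape:
        raise ValueError(f"p_ref {p_ref.shape} and p_alt {p_alt.shape} shapes differ")
    diff, logfold = diff_logfold(p_ref, p_alt)
    blocks = [diff, logfold]
    names = [f"diff_{j}" for j in range(p_ref.shape[1])] + [
        f"logfold_{j}" for j in range(p_ref.shape[1])
    ]
    if conservation is not None:
        conservation = np.atleast_2d(np.asarray(conservation, dtype=float))
        if conservation.shape[0] != p_ref.shape[0]:
            raise ValueError("conservation rows do not match the variant count")
        blocks.append(conservation)
        names += [f"cons_{j}" for j in range(conservation.shape[1])]
    return np.hstack(blocks), names


def standardize(matrix):
    """Column-wise zero-mean unit-variance scaling (population variance).

    Constant columns map to zero with a recorded scale of 1, so the
    transform is always invertible.  Returns ``(standardized, mean, scale)``;
    reuse the parameters on new variants via :func:`apply_standardization`.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("need a non-empty 2-d matrix")
    scaler = StandardScaler().fit(matrix)
    return scaler.transform(matrix), scaler.mean_.copy(), scaler.scale_.copy()


def apply_standardization(matrix, mean, scale, inverse: bool = False):
    """Apply (or invert) a previously fitted standardisation."""
    matrix = np.asarray(matrix, dtype=float)
    if inverse:
        return matrix * scale + mean
    return (matrix - mean) / scale
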