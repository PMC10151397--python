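"""Between-array quantile normalization, log2-ratio transform, and PCA."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .exceptions import ParameterError
from .io_core import ExpressionMatrix


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean order statistics.

    After normalization all samples share the same sorted value vector;
    within-sample rank order is preserved and ties receive the mean of the
    corresponding reference quantiles. Idempotent.
    """
    if len(expr.samples) < 2:
        raise ParameterError("quantile normalization needs >= 2 samples")
    values = expr.values
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return ExpressionMatrix(
        spots=expr.spots, samples=expr.samples, values=out, metadata=expr.metadata
    )


def log2_ratio_to_mean(expr: ExpressionMatrix) -> np.ndarray:
    """Per-spot log2 ratio to the spot's mean across samples.

    Inputs are log2 intensities, so the ratio to the (geometric) mean is
    simply mean-centering in log space:  R_ij = y_ij - mean_j(y_i.).
    Returns a spots x samples array whose rows are exactly mean-centered.
    """
    return expr.values - expr.values.mean(axis=1, keepdims=True)


def pca_scores(ratios: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of samples from a spots x samples matrix.

    Spots are centered and scaled to unit variance across samples before
    the decomposition (zero-variance spots are dropped), matching the
    convention of R's ``prcomp(..., scale = TRUE)`` on the transposed
    matrix. Returns (scores, variance_fractions) with ``scores`` of shape
    (n_samples, n_components).
    """
    ratios = np.asarray(ratios, dtype=float)
    n_samples = ratios.shape[1]
    if n_components > n_samples - 1:
        raise ParameterError(
            f"n_components={n_components} exceeds n_samples-1={n_samples - 1}"
        )
    sd = ratios.std(axis=1, ddof=1)
    keep = sd > 0
    X = ratios[keep]
    X = (X - X.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    M = X.T  # samples x spots, columns centered and unit variance
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    eig = s**2 / (n_samples - 1)
    fractions = eig / keep.sum()  # total variance = number of scaled spots
    scores = u * s
    return scores[:, :n_components], fractions[:n_components]
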