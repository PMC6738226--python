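"""PCA of the haploid SNP matrix with percent variance explained.

Samples are rows, biallelic loci columns (0/1 allele codes).  Missing
calls are mean-imputed per locus, columns are centered (no unit-variance
scaling: allele indicators share a common scale), and the sample
covariance matrix is eigendecomposed via SVD.  Axis signs are fixed by
making the largest-magnitude loading on each axis positive, so outputs
are reproducible across runs and BLAS backends.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .variants import MISSING, GenotypeMatrix


@dataclasses.dataclass
class PCAResult:
    """Scores, eigenvalues and percent variance per principal axis."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: np.ndarray
    n_axes: int
    total_variance: float


def pca(matrix: GenotypeMatrix, n_axes: int = 2) -> PCAResult:
    """Principal component analysis of a genotype matrix.

    Eigenvalues are variances of the scores along each axis (sample
    covariance with denominator n-1, axes ordered by decreasing
    eigenvalue); percent_variance is each eigenvalue as a percentage of
    the total variance of the centered matrix, so it sums to 100 over
    all axes.  `n_axes` beyond the matrix rank bound
    min(n_samples - 1, n_loci) is clipped with a warning.
    """
    n, m = matrix.n_samples, matrix.n_loci
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_axes = max(min(n - 1, m), 1)
    if n_axes > max_axes:
        warnings.warn(
            f"n_axes={n_axes} clipped to {max_axes} "
            f"(min(n_samples-1, n_loci))",
            stacklevel=2,
        )
        n_axes = max_axes
    X = matrix.calls.astype(float)
    X[matrix.calls == MISSING] = np.nan
    if m:
        col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_mask = np.isnan(X)
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
        Xc = X - X.mean(axis=0)
    else:
        Xc = np.zeros((n, 0))
    denom = n - 1
    total_var = float(np.sum(Xc**2)) / denom
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / denom
    k = n_axes
    U, s, Vt, eig = U[:, :k], s[:k], Vt[:k], eig[:k]
    # deterministic axis signs: largest-magnitude loading positive
    for a in range(k):
        load = Vt[a]
        if load.size and load[np.argmax(np.abs(load))] < 0:
            Vt[a] = -load
            U[:, a] = -U[:, a]
    scores = U * s
    pct = 100.0 * eig / total_var if total_var > 0 else np.zeros_like(eig)
    return PCAResult(
        scores=scores,
        eigenvalues=eig,
        percent_variance=pct,
        loadings=Vt.T,
        n_axes=k,
        total_variance=total_var,
    )
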