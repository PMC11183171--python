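"""Ecosystem multifunctionality: z-scored functions, averaging index, PCA axes.

Three facets are computed from a samples x 12 function table: (i) the
standardized single functions, (ii) average multifunctionality (the row mean
of the z-scores), and (iii) multidimensional functioning, the leading
principal axes of the standardized functions (correlation-matrix PCA, which
coincides with covariance PCA on z-scored columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FunctionTable


class DegenerateColumnError(ValueError):
    """A function column is constant and cannot be z-standardized."""


@dataclass
class MultifunctionalityResult:
    standardized: pd.DataFrame
    average_mf: pd.Series
    dim_scores: pd.DataFrame
    explained_variance: np.ndarray
    loadings: pd.DataFrame


def z_standardize(functions: FunctionTable | pd.DataFrame) -> pd.DataFrame:
    """Per-column z-transform: (x - mean) / sample sd (n-1 denominator).

    Raises :class:`DegenerateColumnError` naming the function if a column is
    constant; 12 functions are a fixed design, so silent dropping would bias
    every downstream index.
    """
    df = functions.data if isinstance(functions, FunctionTable) else functions
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = df.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise DegenerateColumnError(
            f"constant function column(s): {', '.join(map(str, constant))}"
        )
    return (df - df.mean(axis=0)) / sd


def average_multifunctionality(standardized: pd.DataFrame) -> pd.Series:
    """Averaging multifunctionality index: per-sample mean of z-scores."""
    return standardized.mean(axis=1).rename("average_mf")


def multidimensional_functioning(
    standardized: pd.DataFrame, n_dims: int = 3
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Principal axes of the standardized function matrix.

    Returns (dim_scores, explained_variance, loadings). Axis orientation is
    fixed by making the largest-magnitude loading of each axis positive.
    explained_variance fractions are eigenvalue / total variance over all
    possible axes.
    """
    x = standardized.to_numpy(dtype=float)
    n, p = x.shape
    max_dims = min(n - 1, p)
    if not (1 <= n_dims <= max_dims):
        raise ValueError(f"n_dims must be in [1, {max_dims}]")
    xc = x - x.mean(axis=0)
    # SVD of the centered matrix == eigendecomposition of its covariance
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    # orientation: largest-|loading| entry of each axis positive
    for k in range(n_dims):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :n_dims] * s[:n_dims]
    dim_cols = [f"dim{k + 1}" for k in range(n_dims)]
    dim_scores = pd.DataFrame(scores, index=standardized.index, columns=dim_cols)
    loadings = pd.DataFrame(
        vt[:n_dims].T, index=standardized.columns, columns=dim_cols
    )
    explained = eigvals[:n_dims] / total
    return dim_scores, explained, loadings


def compute_multifunctionality(
    functions: FunctionTable, n_dims: int = 3
) -> MultifunctionalityResult:
    """All three multifunctionality facets in one pass."""
    z = z_standardize(functions)
    scores, explained, loadings = multidimensional_functioning(z, n_dims=n_dims)
    return MultifunctionalityResult(
        standardized=z,
        average_mf=average_multifunctionality(z),
        dim_scores=scores,
        explained_variance=explained,
        loadings=loadings,
    )
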