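"""Permutation-based multivariate statistics on distance matrices.

Bray-Curtis dissimilarities, Mantel tests (Spearman by default), PERMANOVA
(pseudo-F with R-squared), constrained principal coordinate analysis
(fraction of distance-space variance explained by a grouping), and
distance-based variation partitioning with adjusted R-squared.

Every permutation p-value uses the (1 + exceedances) / (1 + n_permutations)
estimator, so p is never exactly 0. All routines are deterministic given a
seed. Permutations are over the whole sample set (no strata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import AbundanceTable


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    extra: dict = field(default_factory=dict)


def _check_distance(dist: pd.DataFrame) -> pd.DataFrame:
    m = dist.to_numpy(dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("non-finite dissimilarities")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    if (m < -1e-12).any():
        raise ValueError("negative dissimilarities")
    return dist


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    df = table.data if isinstance(table, AbundanceTable) else table
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _perm_p(obs: float, perm_stats: np.ndarray) -> float:
    return (1 + int((perm_stats >= obs - 1e-12).sum())) / (1 + len(perm_stats))


def mantel_test(
    dist_a: pd.DataFrame,
    dist_b: pd.DataFrame,
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson or Spearman correlation of the lower
    triangles; the null permutes rows and columns of one matrix
    simultaneously. One-sided (positive association) p-value.
    """
    _check_distance(dist_a)
    _check_distance(dist_b)
    if set(dist_a.index) != set(dist_b.index):
        raise ValueError("distance matrices must share sample ids")
    dist_b = dist_b.loc[dist_a.index, dist_a.index]
    n = dist_a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a Mantel test")

    a = dist_a.to_numpy(dtype=float)
    b = dist_b.to_numpy(dtype=float)
    il = np.tril_indices(n, k=-1)

    if method == "spearman":
        # rank transform is order-preserving, so ranking the full triangles
        # once commutes with the row/column permutation of the null
        a = squareform(rankdata(a[il]))
        b = squareform(rankdata(b[il]))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    va = a[il]
    vb = b[il]
    sa = va.std()
    sb = vb.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant distance matrix; correlation undefined")

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        return float(((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std()))

    obs = corr(va, vb)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for k in range(n_permutations):
        p = rng.permutation(n)
        perm_stats[k] = corr(a[np.ix_(p, p)][il], vb)
    return PermutationTestResult(
        statistic=obs,
        p_value=_perm_p(obs, perm_stats),
        n_permutations=n_permutations,
        seed=seed,
        extra={"method": method},
    )


def _permanova_ss(w: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_between, SS_within) from squared distances and group labels."""
    n = w.shape[0]
    ss_total = w[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = w[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


def permanova(
    dist: pd.DataFrame,
    grouping: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA: pseudo-F and R-squared.

    pseudo-F = (SS_between / (a - 1)) / (SS_within / (N - a)) from the
    distance-based partition of sums of squares; the null permutes group
    labels. R-squared = SS_between / SS_total is reported in ``extra``.
    """
    _check_distance(dist)
    grouping = pd.Series(grouping).loc[dist.index]
    labels, counts = np.unique(grouping.to_numpy(), return_counts=True)
    if len(labels) < 2:
        raise ValueError("grouping must have at least 2 levels")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    n = dist.shape[0]
    a = len(labels)
    w = dist.to_numpy(dtype=float) ** 2
    codes = pd.Categorical(grouping).codes

    def pseudo_f(lab: np.ndarray) -> tuple[float, float]:
        ss_b, ss_w = _permanova_ss(w, lab)
        with np.errstate(divide="ignore"):  # ss_w = 0 -> F = inf
            f = (ss_b / (a - 1)) / (ss_w / (n - a))
        return f, ss_b / (ss_b + ss_w)

    obs_f, r2 = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for k in range(n_permutations):
        perm_stats[k] = pseudo_f(rng.permutation(codes))[0]
    return PermutationTestResult(
        statistic=obs_f,
        p_value=_perm_p(obs_f, perm_stats),
        n_permutations=n_permutations,
        seed=seed,
        extra={"R2": r2, "n_groups": a},
    )


def _pcoa_coordinates(dist: pd.DataFrame) -> tuple[np.ndarray, bool]:
    """Principal-coordinate embedding of a distance matrix.

    Applies the Lingoes correction (add 2c to off-diagonal squared
    distances, c = |most negative eigenvalue|) when the matrix is
    non-Euclidean, as Bray-Curtis generally is. Returns the coordinates on
    positive axes and whether a correction was applied.
    """
    d2 = dist.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n

    def gower(sq: np.ndarray) -> np.ndarray:
        return -0.5 * j @ sq @ j

    eigvals, eigvecs = np.linalg.eigh(gower(d2))
    corrected = False
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        c = -eigvals.min()
        d2c = d2 + 2 * c
        np.fill_diagonal(d2c, 0.0)
        eigvals, eigvecs = np.linalg.eigh(gower(d2c))
        corrected = True
    keep = eigvals > 1e-9 * max(eigvals.max(), 1.0)
    y = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    return y, corrected


def _r_squared(y: np.ndarray, x: np.ndarray) -> float:
    """Fraction of total variance of Y explained by projection on X."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    total = (yc**2).sum()
    if total == 0:
        raise ValueError("response has zero variance")
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    return float((fitted**2).sum() / total)


def _indicator(grouping: pd.Series) -> np.ndarray:
    return pd.get_dummies(pd.Categorical(grouping)).to_numpy(dtype=float)


def constrained_pcoa(
    dist: pd.DataFrame,
    grouping: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Constrained PCoA: PCoA followed by redundancy on group indicators.

    Reports the fraction of total distance-space variance constrained by
    the grouping, constrained axis scores (centered), and a permutation p
    on that fraction.
    """
    _check_distance(dist)
    grouping = pd.Series(grouping).loc[dist.index]
    levels, counts = np.unique(grouping.to_numpy(), return_counts=True)
    if len(levels) < 2:
        raise ValueError("grouping must have at least 2 levels")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    y, corrected = _pcoa_coordinates(dist)
    x = _indicator(grouping)
    obs = _r_squared(y, x)

    # constrained axes: SVD of the fitted values
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int((s > 1e-9 * max(s.max(), 1.0)).sum()) if s.size else 0
    scores = pd.DataFrame(
        (u * s)[:, :n_axes],
        index=dist.index,
        columns=[f"CPCoA{k + 1}" for k in range(n_axes)],
    )

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for k in range(n_permutations):
        perm_stats[k] = _r_squared(y, x[rng.permutation(len(x))])
    return {
        "constrained_fraction": obs,
        "p_value": _perm_p(obs, perm_stats),
        "scores": scores,
        "lingoes_corrected": corrected,
        "n_permutations": n_permutations,
        "seed": seed,
    }


def _adjusted_r2(r2: float, n: int, k: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - k)


def variation_partitioning(
    response_dist: pd.DataFrame,
    predictors_a: pd.DataFrame,
    predictors_b: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Distance-based variation partitioning between two predictor sets.

    Distance-based redundancy with adjusted R-squared:
    unique_a = adjR2(A+B) - adjR2(B), unique_b symmetric,
    shared = adjR2(A) + adjR2(B) - adjR2(A+B),
    residual = 1 - adjR2(A+B). Fractions may be slightly negative
    (adjusted-R2 artifact) and are reported unclipped. A permutation p is
    reported for the full-model R-squared.
    """
    _check_distance(response_dist)
    ids = list(response_dist.index)

    def prep(df: pd.DataFrame, name: str) -> np.ndarray:
        if df is None or df.shape[1] == 0:
            return np.empty((len(ids), 0))
        x = df.loc[ids].to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        if np.linalg.matrix_rank(xc) < xc.shape[1]:
            raise ValueError(
                f"predictor set {name} is rank deficient after centering: "
                f"columns {list(df.columns)}"
            )
        return x
    xa = prep(predictors_a, "A")
    xb = prep(predictors_b, "B")
    ka, kb = xa.shape[1], xb.shape[1]
    n = len(ids)
    if n <= ka + kb + 1:
        raise ValueError("too few samples for the number of predictors")
    xab = np.hstack([xa, xb])
    if ka and kb and np.linalg.matrix_rank(xab - xab.mean(axis=0)) < ka + kb:
        raise ValueError("predictor sets A and B are jointly collinear")

    y, _ = _pcoa_coordinates(response_dist)
    r2_a = _r_squared(y, xa) if ka else 0.0
    r2_b = _r_squared(y, xb) if kb else 0.0
    r2_ab = _r_squared(y, xab) if ka + kb else 0.0
    adj_a = _adjusted_r2(r2_a, n, ka) if ka else 0.0
    adj_b = _adjusted_r2(r2_b, n, kb) if kb else 0.0
    adj_ab = _adjusted_r2(r2_ab, n, ka + kb) if ka + kb else 0.0

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for k in range(n_permutations):
        perm_stats[k] = _r_squared(y, xab[rng.permutation(n)]) if ka + kb else 0.0
    return {
        "unique_a": adj_ab - adj_b,
        "unique_b": adj_ab - adj_a,
        "shared": adj_a + adj_b - adj_ab,
        "residual": 1.0 - adj_ab,
        "adj_r2": {"A": adj_a, "B": adj_b, "AB": adj_ab},
        "p_value": _perm_p(r2_ab, perm_stats),
        "n_permutations": n_permutations,
        "seed": seed,
    }
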