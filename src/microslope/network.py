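"""Signed co-occurrence network inference from abundance tables.

The pipeline is the compositionally robust sparse-graphical-model approach
standard in microbiome ecology: prevalence/relative-abundance filtering,
centered log-ratio (CLR) transform, per-taxon L1-penalized neighborhood
regressions (Meinshausen-Buhlmann), and StARS stability selection of the
sparsity penalty. The result is an undirected signed weighted network.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .containers import AbundanceTable, SchemaError, SignedNetwork


class EmptyResultError(ValueError):
    """A filtering step removed every taxon."""


def filter_asvs(
    table: AbundanceTable,
    min_prevalence: float = 0.25,
    min_rel_abund: float = 1e-5,
) -> AbundanceTable:
    """Keep dominant taxa: present in > ``min_prevalence`` of samples AND with
    mean relative abundance > ``min_rel_abund``.

    Both rules use strict inequalities; relative abundance is computed within
    each taxon's own kingdom (each kingdom was profiled by its own marker
    gene, so proportions are only comparable within a kingdom).
    """
    if table.n_taxa == 0:
        raise EmptyResultError("empty abundance table")
    n = table.n_samples
    prevalence = (table.data > 0).sum(axis=0)
    keep_prev = prevalence > min_prevalence * n

    keep_abund = pd.Series(False, index=table.data.columns)
    for k in table.kingdoms.unique():
        taxa = table.kingdoms.index[table.kingdoms == k]
        sub = table.data[list(taxa)]
        totals = sub.sum(axis=1)
        rel = sub.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
        keep_abund[taxa] = rel.mean(axis=0) > min_rel_abund

    keep = table.data.columns[(keep_prev & keep_abund)]
    if len(keep) == 0:
        raise EmptyResultError("all taxa removed by prevalence/abundance filter")
    return table.subset_taxa(keep)


def merge_kingdom_tables(tables: list[AbundanceTable]) -> AbundanceTable:
    """Column-concatenate kingdom tables sharing the same samples."""
    if not tables:
        raise SchemaError("no tables to merge")
    ref = tables[0]
    sample_order = ref.sample_ids
    seen: set[str] = set()
    frames, kingdoms = [], []
    for t in tables:
        if set(t.sample_ids) != set(sample_order):
            raise SchemaError("tables do not share the same sample set")
        dup = seen & set(t.taxon_ids)
        if dup:
            raise SchemaError(f"duplicate taxon ids across tables: {sorted(dup)[:5]}")
        seen |= set(t.taxon_ids)
        frames.append(t.data.loc[sample_order])
        kingdoms.append(t.kingdoms)
    return AbundanceTable(
        pd.concat(frames, axis=1), pd.concat(kingdoms), ref.metadata.copy()
    )


def clr_transform(
    table: AbundanceTable | pd.DataFrame, pseudocount_rule: str = "auto"
) -> pd.DataFrame:
    """Centered log-ratio transform, one row per sample.

    A pseudocount is added (fixed 1 for count data; half the smallest
    positive value for non-integer absolute abundances; ``pseudocount_rule``
    in {"auto", "fixed", "half-min"}), each sample is closed to proportions,
    logged, and centered by its mean log. Every output row sums to zero, and
    the transform is invariant to rescaling any sample by a positive constant.
    """
    df = table.data if isinstance(table, AbundanceTable) else table
    x = df.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        bad = df.index[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"sample(s) with zero total abundance: {bad[:5]}")
    if pseudocount_rule == "auto":
        is_counts = np.allclose(x, np.round(x))
        pseudocount_rule = "fixed" if is_counts else "half-min"
    if pseudocount_rule == "fixed":
        pc = 1.0
    elif pseudocount_rule == "half-min":
        pc = x[x > 0].min() / 2.0
    else:
        raise ValueError(f"unknown pseudocount rule {pseudocount_rule!r}")
    y = x + pc
    y = y / y.sum(axis=1, keepdims=True)
    logy = np.log(y)
    clr = logy - logy.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


def lambda_max(clr_matrix: pd.DataFrame) -> float:
    """Largest penalty with a non-empty model: max |off-diagonal covariance|."""
    x = clr_matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / x.shape[0]
    np.fill_diagonal(cov, 0.0)
    return float(np.abs(cov).max())


def default_lambda_path(clr_matrix: pd.DataFrame, n_lambda: int = 30) -> np.ndarray:
    """30 log-spaced penalties from lambda_max down to 0.01 * lambda_max."""
    lmax = lambda_max(clr_matrix)
    if lmax <= 0:
        raise ValueError("degenerate input: zero cross-covariance everywhere")
    return np.geomspace(lmax, 0.01 * lmax, n_lambda)


def _neighborhood_coefs(xc: np.ndarray, lam: float) -> np.ndarray:
    """Directed coefficient matrix B: B[j, k] = coefficient of k in the
    lasso regression of column j on all others (diagonal 0)."""
    n, p = xc.shape
    b = np.zeros((p, p))
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=5000, tol=1e-6)
    others = np.arange(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(p):
            mask = others != j
            model.fit(xc[:, mask], xc[:, j])
            b[j, mask] = model.coef_
    return b


def _edges_from_coefs(
    b: np.ndarray, rule: str = "or"
) -> list[tuple[int, int, int, float]]:
    """Symmetrize the directed coefficient matrix into signed edges.

    OR rule: an edge exists if either regression selected the pair (AND
    switchable). Sign and weight come from the mean of the two directed
    coefficients; an exact-zero mean drops the edge.
    """
    p = b.shape[0]
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            sel = (b[i, j] != 0) or (b[j, i] != 0)
            if rule == "and":
                sel = (b[i, j] != 0) and (b[j, i] != 0)
            if not sel:
                continue
            m = 0.5 * (b[i, j] + b[j, i])
            if m == 0:
                continue
            edges.append((i, j, 1 if m > 0 else -1, abs(m)))
    return edges


def neighborhood_fit(
    clr_matrix: pd.DataFrame, lam: float, rule: str = "or"
) -> list[tuple[str, str, int, float]]:
    """Signed edge set from L1-penalized neighborhood selection at penalty
    ``lam`` (sklearn's 1/(2n) least-squares scaling)."""
    x = clr_matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in CLR matrix")
    if x.shape[0] <= 2:
        raise ValueError("need more than 2 samples")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("degenerate input: zero variance in all taxa")
    b = _neighborhood_coefs(xc, lam)
    cols = list(clr_matrix.columns)
    return [(cols[i], cols[j], s, w) for i, j, s, w in _edges_from_coefs(b, rule)]


def _path_adjacency(xc: np.ndarray, lambdas: np.ndarray, rule: str) -> np.ndarray:
    """Boolean adjacency (n_lambda, p, p) along a decreasing penalty path,
    computed with coordinate-descent warm starts (sklearn lasso_path)."""
    n, p = xc.shape
    nl = len(lambdas)
    directed = np.zeros((nl, p, p), dtype=bool)
    others = np.arange(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(p):
            mask = others != j
            _, coefs, _ = lasso_path(xc[:, mask], xc[:, j], alphas=lambdas)
            directed[:, j, mask] = coefs.T != 0
    if rule == "and":
        return directed & directed.transpose(0, 2, 1)
    return directed | directed.transpose(0, 2, 1)


def stars_select(
    clr_matrix: pd.DataFrame,
    lambda_path: np.ndarray | None = None,
    n_subsamples: int = 50,
    subsample_fraction: float = 0.8,
    instability_threshold: float = 0.05,
    seed: int = 0,
    rule: str = "or",
    kingdoms: pd.Series | None = None,
) -> SignedNetwork:
    """StARS: pick the penalty by edge-selection stability under subsampling.

    For each penalty on a decreasing path, the fraction of subsamples
    selecting each edge gives a per-edge instability 2*theta*(1-theta);
    their average, monotonized along the path, is compared with the
    threshold (0.05 default). The selected penalty is the smallest one whose
    monotonized instability stays below the threshold; the final network is
    a full-data neighborhood fit at that penalty. Falls back to the largest
    penalty (with a warning recorded in provenance) if none qualifies.
    """
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be >= 2")
    x = clr_matrix.to_numpy(dtype=float)
    n, p = x.shape
    if lambda_path is None:
        lambda_path = default_lambda_path(clr_matrix)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(lambda_path) > 0):
        raise ValueError("lambda_path must be sorted decreasing")

    rng = np.random.default_rng(seed)
    b = int(np.floor(subsample_fraction * n))
    if b < 3:
        raise ValueError("subsample too small; increase n or subsample_fraction")

    freq = np.zeros((len(lambda_path), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        xs = x[idx]
        xs = xs - xs.mean(axis=0)
        if np.allclose(xs, 0):
            raise ValueError("degenerate input: zero variance in all taxa")
        freq += _path_adjacency(xs, lambda_path, rule)
    theta = freq / n_subsamples
    iu = np.triu_indices(p, k=1)
    instability = (2 * theta * (1 - theta))[:, iu[0], iu[1]].mean(axis=1)
    monotone = np.maximum.accumulate(instability)

    ok = np.flatnonzero(monotone <= instability_threshold)
    warning = None
    if len(ok):
        sel_idx = int(ok[-1])  # smallest qualifying lambda on decreasing path
    else:
        sel_idx = 0
        warning = "no lambda met the instability threshold; using largest"
    lam = float(lambda_path[sel_idx])

    edges = neighborhood_fit(clr_matrix, lam, rule=rule)
    cols = list(clr_matrix.columns)
    if kingdoms is None:
        kingdoms = pd.Series("bacteria", index=cols)
    provenance = {
        "lambda_path": lambda_path.tolist(),
        "selected_lambda": lam,
        "instability": instability.tolist(),
        "n_subsamples": n_subsamples,
        "subsample_fraction": subsample_fraction,
        "instability_threshold": instability_threshold,
        "rule": rule,
        "seed": seed,
    }
    if warning:
        provenance["warning"] = warning
    nodes = {t: kingdoms[t] for t in cols}
    return SignedNetwork(nodes, edges, provenance)


def infer_network(
    table: AbundanceTable,
    lambda_path: np.ndarray | None = None,
    n_subsamples: int = 50,
    subsample_fraction: float = 0.8,
    instability_threshold: float = 0.05,
    seed: int = 0,
    rule: str = "or",
    pseudocount_rule: str = "auto",
) -> SignedNetwork:
    """CLR-transform a (filtered) abundance table and run StARS selection."""
    clr = clr_transform(table, pseudocount_rule=pseudocount_rule)
    return stars_select(
        clr,
        lambda_path=lambda_path,
        n_subsamples=n_subsamples,
        subsample_fraction=subsample_fraction,
        instability_threshold=instability_threshold,
        seed=seed,
        rule=rule,
        kingdoms=table.kingdoms,
    )
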