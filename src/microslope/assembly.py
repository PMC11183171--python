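"""Community assembly quantification via phylogenetic and taxonomic null models.

Implements the pairwise QPEN framework: abundance-weighted beta mean nearest
taxon distance (betaMNTD), its null-model z-score betaNTI (tip-label shuffle
nulls), the Bray-Curtis-based Raup-Crick metric RC_Bray (probabilistic
community-assembly nulls), and the five-process classification:

* |betaNTI| > 2       -> deterministic: variable selection (betaNTI > 2) or
                         homogeneous selection (betaNTI < -2)
* |betaNTI| < 2       -> stochastic, split by RC_Bray: dispersal limitation
                         (RC > 0.95), homogenizing dispersal (RC < -0.95),
                         or drift (|RC| <= 0.95)

Boundary equality resolves toward the stochastic/drift side (strict
inequalities throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AbundanceTable
from .trees import PhylogeneticTree

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

_TIE_TOL = 1e-12


@dataclass
class AssemblyClassification:
    """Pairwise assembly metrics, per-pair process labels, process fractions."""

    bnti: pd.DataFrame
    rc: pd.DataFrame
    pairs: pd.DataFrame  # long format: sample_a, sample_b, bNTI, RC, process
    fractions: pd.Series
    n_null: int
    seed: int
    n_excluded: int = 0


def _community_matrix(comm: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    df = comm.data if isinstance(comm, AbundanceTable) else comm
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    return df


def beta_mntd(
    comm_a: pd.Series, comm_b: pd.Series, tree: PhylogeneticTree | pd.DataFrame
) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two
    communities: 0.5 * (sum_i f_i min_j d_ij + sum_j f_j min_i d_ij) with f
    the relative abundances and the minimum taken over taxa present in the
    other community (a shared taxon contributes distance 0)."""
    dmat = tree.tip_distance_matrix() if isinstance(tree, PhylogeneticTree) else tree
    a = comm_a[comm_a > 0]
    b = comm_b[comm_b > 0]
    if a.empty or b.empty:
        raise ValueError("empty community")
    missing = (set(a.index) | set(b.index)) - set(dmat.index)
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]}")
    fa = a / a.sum()
    fb = b / b.sum()
    d_ab = dmat.loc[list(a.index), list(b.index)].to_numpy()
    term_a = float(fa.to_numpy() @ d_ab.min(axis=1))
    term_b = float(fb.to_numpy() @ d_ab.min(axis=0))
    return 0.5 * (term_a + term_b)


def _beta_mntd_matrix(f: np.ndarray, present: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Pairwise betaMNTD for all sample pairs.

    f: (s, t) relative abundances; present: (s, t) boolean; d: (t, t).
    """
    s, t = f.shape
    # dmin[s2] = for each taxon, distance to its nearest taxon present in s2
    dmin = np.empty((s, t))
    for k in range(s):
        dmin[k] = d[:, present[k]].min(axis=1)
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            val = 0.5 * (f[i] @ dmin[j] + f[j] @ dmin[i])
            out[i, j] = out[j, i] = val
    return out


def beta_mntd_matrix(
    comm: AbundanceTable | pd.DataFrame, tree: PhylogeneticTree | pd.DataFrame
) -> pd.DataFrame:
    """Observed pairwise betaMNTD over all samples of a community matrix."""
    df = _community_matrix(comm)
    dmat = tree.tip_distance_matrix() if isinstance(tree, PhylogeneticTree) else tree
    missing = set(df.columns) - set(dmat.index)
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]}")
    d = dmat.loc[list(df.columns), list(df.columns)].to_numpy()
    x = df.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total abundance")
    f = x / x.sum(axis=1, keepdims=True)
    present = x > 0
    m = _beta_mntd_matrix(f, present, d)
    return pd.DataFrame(m, index=df.index, columns=df.index)


def beta_nti(
    comm: AbundanceTable | pd.DataFrame,
    tree: PhylogeneticTree | pd.DataFrame,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """betaNTI: z-score of observed betaMNTD against a taxa-shuffle null.

    The null shuffles taxon labels across all tree tips (equivalently,
    permutes rows/columns of the patristic distance matrix), recomputing
    betaMNTD ``n_null`` times. Pairs whose null distribution has zero
    standard deviation are undefined and reported as NaN with a warning.
    Deterministic given ``seed``.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    df = _community_matrix(comm)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dmat = tree.tip_distance_matrix() if isinstance(tree, PhylogeneticTree) else tree
    missing = set(df.columns) - set(dmat.index)
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]}")
    d = dmat.loc[list(df.columns), list(df.columns)].to_numpy()
    x = df.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total abundance")
    f = x / x.sum(axis=1, keepdims=True)
    present = x > 0
    obs = _beta_mntd_matrix(f, present, d)

    rng = np.random.default_rng(seed)
    t = d.shape[0]
    s = x.shape[0]
    nulls = np.empty((n_null, s, s))
    for r in range(n_null):
        perm = rng.permutation(t)
        nulls[r] = _beta_mntd_matrix(f, present, d[np.ix_(perm, perm)])
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    if np.isnan(z[np.triu_indices(s, k=1)]).any():
        warnings.warn("betaNTI undefined (zero null sd) for some sample pair(s)")
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=df.index, columns=df.index)


def rc_bray(
    comm: AbundanceTable | pd.DataFrame,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick metric in [-1, 1].

    Null communities preserve each sample's richness and total abundance:
    taxa are drawn without replacement with probability proportional to
    their occupancy (number of samples occupied), then individuals are
    assigned by a multinomial with probabilities proportional to regional
    relative abundances of the drawn taxa. RC = 2 * (fraction of null
    Bray-Curtis below the observed + half the ties) - 1. Deterministic
    given ``seed``.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    df = _community_matrix(comm)
    x = df.to_numpy(dtype=float)
    s, t = x.shape
    if (x.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total abundance")
    obs = squareform(pdist(x, metric="braycurtis"))

    occupancy = (x > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    regional = x.sum(axis=0)
    richness = (x > 0).sum(axis=1)
    totals = np.maximum(np.round(x.sum(axis=1)).astype(int), 1)

    rng = np.random.default_rng(seed)
    p_occ = occupancy[pool] / occupancy[pool].sum()
    below = np.zeros((s, s))
    ties = np.zeros((s, s))
    null = np.empty((s, t))
    for _ in range(n_null):
        null[:] = 0.0
        for k in range(s):
            rich = min(richness[k], len(pool))
            chosen = rng.choice(pool, size=rich, replace=False, p=p_occ)
            p_ab = regional[chosen]
            p_ab = (
                p_ab / p_ab.sum()
                if p_ab.sum() > 0
                else np.full(rich, 1.0 / rich)
            )
            null[k, chosen] = rng.multinomial(totals[k], p_ab)
        nbc = squareform(pdist(null, metric="braycurtis"))
        below += nbc < obs - _TIE_TOL
        ties += np.abs(nbc - obs) <= _TIE_TOL
    rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=df.index, columns=df.index)


def classify_assembly(
    bnti: pd.DataFrame, rc: pd.DataFrame, n_null: int = 0, seed: int = 0
) -> AssemblyClassification:
    """Assign each sample pair to one of the five assembly processes.

    Pairs with undefined (NaN) betaNTI are excluded from the fractions and
    counted in ``n_excluded``.
    """
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise ValueError("betaNTI and RC matrices are not aligned")
    if (rc.to_numpy()[~np.isnan(rc.to_numpy())] > 1 + 1e-9).any() or (
        rc.to_numpy()[~np.isnan(rc.to_numpy())] < -1 - 1e-9
    ).any():
        raise ValueError("RC values outside [-1, 1]")
    samples = list(bnti.index)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            b = bnti.iloc[i, j]
            r = rc.iloc[i, j]
            if np.isnan(b):
                label = None
            elif b > 2:
                label = "variable_selection"
            elif b < -2:
                label = "homogeneous_selection"
            elif r > 0.95:
                label = "dispersal_limitation"
            elif r < -0.95:
                label = "homogenizing_dispersal"
            else:
                label = "drift"
            rows.append(
                {
                    "sample_a": samples[i],
                    "sample_b": samples[j],
                    "bNTI": b,
                    "RC": r,
                    "process": label,
                }
            )
    pairs = pd.DataFrame(rows)
    valid = pairs[pairs["process"].notna()]
    n_excluded = len(pairs) - len(valid)
    counts = valid["process"].value_counts()
    fractions = pd.Series(
        {p: counts.get(p, 0) / len(valid) if len(valid) else 0.0 for p in PROCESSES}
    )
    return AssemblyClassification(
        bnti=bnti,
        rc=rc,
        pairs=pairs,
        fractions=fractions,
        n_null=n_null,
        seed=seed,
        n_excluded=n_excluded,
    )


def quantify_assembly(
    comm: AbundanceTable | pd.DataFrame,
    tree: PhylogeneticTree | pd.DataFrame,
    n_null: int = 1000,
    seed: int = 0,
) -> AssemblyClassification:
    """betaNTI + RC_Bray + five-process classification in one call."""
    bnti = beta_nti(comm, tree, n_null=n_null, seed=seed)
    rc = rc_bray(comm, n_null=n_null, seed=seed + 1)
    return classify_assembly(bnti, rc, n_null=n_null, seed=seed)
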