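"""Synthetic slope-microbiome data with planted ground truth.

Emulates the study design the package targets: 18 samples (3 slope positions
x 6 replicate plots), three co-measured kingdoms (bacteria, rhizobia,
arbuscular mycorrhizal fungi) with a shared latent Gaussian association
structure, per-kingdom phylogenies, and 12 ecosystem functions causally
linked to AM-fungal richness and community-level biotic-association scores.

The generative model is a stand-in, not a claim about the real data: taxa
abundances are exp-transformed draws from a multivariate normal whose
precision matrix encodes the planted signed association network, Poisson
count noise on top, and either a phylogenetically conserved habitat
preference (selection scenario) or spatially autocorrelated plot effects
(neutral scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    FUNCTION_IDS,
    KINGDOMS,
    AbundanceTable,
    FunctionTable,
    SchemaError,
    SignedNetwork,
)
from .trees import PhylogeneticTree, generate_phylogeny

#: Default per-kingdom taxon counts for minutes-scale test runs.
DEFAULT_N_TAXA = {"bacteria": 60, "rhizobia": 25, "am_fungi": 20}

#: Default effects of diversity/association predictors on functions.
DEFAULT_EFFECTS = {"am_richness": 1.0, "ppa": 0.5, "pna": 0.5}

#: Per-predictor sign with which its (standardized) value enters functions.
PREDICTOR_SIGNS = {"am_richness": 1.0, "ppa": 1.0, "pna": -1.0}

_PREFIX = {"bacteria": "B", "rhizobia": "R", "am_fungi": "F"}


@dataclass
class GroundTruth:
    """Planted generative state: association structure and causal effects.

    ``precision_matrix`` is the latent Gaussian precision over all taxa of
    all kingdoms; the signed ``true_network`` has an edge wherever an
    off-diagonal entry is nonzero, with sign of the implied partial
    correlation -Omega_ij / sqrt(Omega_ii * Omega_jj).
    """

    precision_matrix: pd.DataFrame
    true_network: SignedNetwork
    habitat_optima: pd.Series
    scenario: str
    effect_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    seed: int | None = None

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision_matrix.to_numpy())


def _taxon_ids(n_taxa_per_kingdom: dict[str, int]) -> tuple[list[str], pd.Series]:
    ids: list[str] = []
    kingdoms: dict[str, str] = {}
    for k in KINGDOMS:
        n = int(n_taxa_per_kingdom.get(k, 0))
        for i in range(n):
            tid = f"{_PREFIX[k]}{i + 1:04d}"
            ids.append(tid)
            kingdoms[tid] = k
    return ids, pd.Series(kingdoms)


def network_from_precision(
    precision: pd.DataFrame, kingdoms: pd.Series, provenance: dict | None = None
) -> SignedNetwork:
    """Signed network implied by a precision matrix.

    Edge (i, j) exists iff Omega_ij != 0; sign and weight come from the
    partial correlation -Omega_ij / sqrt(Omega_ii * Omega_jj).
    """
    omega = precision.to_numpy()
    ids = list(precision.index)
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if omega[i, j] != 0:
                pc = -omega[i, j] / np.sqrt(omega[i, i] * omega[j, j])
                edges.append((ids[i], ids[j], 1 if pc > 0 else -1, abs(pc)))
    nodes = {t: kingdoms[t] for t in ids}
    return SignedNetwork(nodes, edges, provenance)


def generate_truth_network(
    n_taxa_per_kingdom: dict[str, int] | None = None,
    edge_density: float = 0.1,
    positive_fraction: float = 0.7,
    seed: int = 0,
    *,
    min_magnitude: float = 0.35,
    max_magnitude: float = 0.5,
    eigen_floor: float = 0.1,
) -> GroundTruth:
    """Plant a sparse symmetric positive-definite precision matrix.

    The graph is parameterized directly by partial-correlation magnitude:
    the precision matrix has unit diagonal and off-diagonal entries
    -pc_ij, with |pc| uniform on [min_magnitude, max_magnitude] and sign
    positive with probability ``positive_fraction`` (a positive partial
    correlation is a *negative* precision entry). If the smallest eigenvalue
    falls below ``eigen_floor``, all partial correlations are shrunk by a
    common factor — a global rescale that preserves the support and signs.
    """
    if n_taxa_per_kingdom is None:
        n_taxa_per_kingdom = dict(DEFAULT_N_TAXA)
    if not (0 < edge_density <= 0.2):
        raise ValueError("edge_density must be in (0, 0.2]")
    if not (0 <= positive_fraction <= 1):
        raise ValueError("positive_fraction must be in [0, 1]")
    ids, kingdoms = _taxon_ids(n_taxa_per_kingdom)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    n_pairs = n * (n - 1) // 2
    m = int(round(edge_density * n_pairs))
    rng = np.random.default_rng(seed)
    pair_idx = rng.choice(n_pairs, size=m, replace=False)
    iu = np.triu_indices(n, k=1)
    b = np.zeros((n, n))
    for p in pair_idx:
        i, j = iu[0][p], iu[1][p]
        mag = rng.uniform(min_magnitude, max_magnitude)
        pos = rng.random() < positive_fraction
        # positive partial correlation <=> negative precision entry
        b[i, j] = b[j, i] = -mag if pos else mag
    omega = np.eye(n) + b
    eigmin = np.linalg.eigvalsh(omega).min() if m else 1.0
    if eigmin < eigen_floor:
        omega = np.eye(n) + b * (1.0 - eigen_floor) / (1.0 - eigmin)
    precision = pd.DataFrame(omega, index=ids, columns=ids)
    truth = GroundTruth(
        precision_matrix=precision,
        true_network=network_from_precision(precision, kingdoms, {"seed": seed}),
        habitat_optima=pd.Series(rng.normal(0, 1, n), index=ids),
        scenario="neutral",
        seed=seed,
    )
    return truth


def generate_kingdom_trees(
    truth: GroundTruth, seed: int = 0
) -> dict[str, PhylogeneticTree]:
    """One random phylogeny per kingdom over that kingdom's taxa."""
    kingdoms = pd.Series(
        {t: truth.true_network.kingdom_of(t) for t in truth.precision_matrix.index}
    )
    trees = {}
    for i, k in enumerate(KINGDOMS):
        taxa = list(kingdoms.index[kingdoms == k])
        if len(taxa) >= 2:
            trees[k] = generate_phylogeny(len(taxa), seed + 1000 * (i + 1), labels=taxa)
    return trees


def _slope_metadata(n_samples: int) -> pd.DataFrame:
    """3 slope positions x equal replicate plots (remainder to the last)."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples (one per slope position)")
    per = n_samples // 3
    sizes = [per, per, n_samples - 2 * per]
    rows = []
    i = 0
    for p_idx, pos in enumerate(("top", "middle", "bottom")):
        for r in range(sizes[p_idx]):
            i += 1
            rows.append(
                {
                    "sample": f"S{i:03d}",
                    "position": pos,
                    "plot": f"P{i:03d}",
                    "position_score": p_idx + 1,
                    "slope_coord": p_idx + r / sizes[p_idx],
                }
            )
    meta = pd.DataFrame(rows).set_index("sample")
    meta.index.name = None
    return meta


def simulate_abundances(
    truth: GroundTruth,
    trees: dict[str, PhylogeneticTree],
    n_samples: int = 18,
    depth: float = 1000.0,
    scenario: str = "selection",
    seed: int = 0,
    *,
    selection_strength: float = 3.0,
    bm_within_sigma: float = 0.3,
    spatial_scale: float = 1.0,
    spatial_sd: float = 1.0,
    baseline_sd: float = 1.0,
    latent_scale: float = 1.5,
    depth_cv: float = 0.2,
    poisson: bool = True,
) -> dict[str, AbundanceTable]:
    """Draw per-kingdom abundance tables from the planted model.

    Latent log-abundances are multivariate normal with covariance equal to
    the inverse of the planted precision matrix, plus a scenario term:

    * ``selection`` — a phylogenetically conserved habitat preference
      (Brownian trait on each kingdom tree) times the centered ordinal slope
      position score (top=1, middle=2, bottom=3);
    * ``neutral`` — per-taxon spatially autocorrelated plot effects with
      exponential distance decay along the slope coordinate.

    Counts are Poisson draws on exp(latent) scaled so each sample's expected
    total equals its depth; depth varies log-normally (cv ~ ``depth_cv``)
    across samples. Deterministic given ``seed``.
    """
    if scenario not in ("selection", "neutral"):
        raise ValueError("scenario must be 'selection' or 'neutral'")
    if depth <= 0:
        raise ValueError("depth must be positive")
    ids = list(truth.precision_matrix.index)
    kingdoms = pd.Series({t: truth.true_network.kingdom_of(t) for t in ids})
    for k, tree in trees.items():
        expected = set(kingdoms.index[kingdoms == k])
        if set(tree.tip_labels) != expected:
            raise SchemaError(f"tree tips do not match {k} taxa")
    meta = _slope_metadata(n_samples)
    rng = np.random.default_rng(seed)
    n, s = len(ids), n_samples

    cov = truth.covariance()
    chol = np.linalg.cholesky(cov)
    latent = latent_scale * (rng.standard_normal((s, n)) @ chol.T)

    baseline = rng.normal(0.0, baseline_sd, n)
    latent += baseline

    if scenario == "selection":
        # habitat preference conserved at the deepest split of each kingdom
        # tree (deep-clade contrast), plus Brownian within-clade variation
        optima = pd.Series(0.0, index=ids)
        for i, (k, tree) in enumerate(sorted(trees.items())):
            contrast = tree.deep_clade_contrast()
            bm = tree.brownian_trait(sigma=1.0, seed=seed + 7 * (i + 1))
            if bm.std() > 0:
                bm = bm / bm.std()
            optima.update(contrast + bm_within_sigma * bm)
        sd = optima.std()
        if sd > 0:
            optima = optima / sd
        truth.habitat_optima = optima
        centered = (meta["position_score"].to_numpy() - 2.0)[:, None]
        latent += selection_strength * centered * optima.loc[ids].to_numpy()[None, :]
    else:
        coords = meta["slope_coord"].to_numpy()
        corr = np.exp(-np.abs(coords[:, None] - coords[None, :]) / spatial_scale)
        chol_sp = np.linalg.cholesky(corr + 1e-10 * np.eye(s))
        plot_eff = spatial_sd * (chol_sp @ rng.standard_normal((s, n)))
        latent += plot_eff
    truth.scenario = scenario

    expz = np.exp(latent)
    tables = {}
    for k in KINGDOMS:
        taxa = [t for t in ids if kingdoms[t] == k]
        if not taxa:
            continue
        # each kingdom is profiled by its own marker gene, so sequencing
        # depth is drawn per sample *per kingdom*
        if depth_cv > 0:
            sigma = np.sqrt(np.log(1 + depth_cv**2))
            depths = depth * np.exp(rng.normal(-sigma**2 / 2, sigma, s))
        else:
            depths = np.full(s, depth)
        cols = [ids.index(t) for t in taxa]
        sub = expz[:, cols]
        lam = sub / sub.sum(axis=1, keepdims=True) * depths[:, None]
        counts = rng.poisson(lam).astype(float) if poisson else np.round(lam)
        df = pd.DataFrame(counts, index=meta.index, columns=taxa)
        tables[k] = AbundanceTable(df, kingdoms.loc[taxa], meta)
    return tables


def simulate_functions(
    tables: dict[str, AbundanceTable],
    truth: GroundTruth,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> FunctionTable:
    """Generate 12 ecosystem functions from planted causal effects.

    Each function is a linear combination of the per-sample AM-fungal
    richness, the positive biotic-association score (PPA) and the negative
    score (PNA) of the planted network (predictors standardized;
    PNA enters with a negative sign), plus Gaussian noise.
    """
    from .topology import biotic_association_scores  # local to avoid cycle

    sample_sets = {frozenset(t.sample_ids) for t in tables.values()}
    if len(sample_sets) != 1:
        raise SchemaError("abundance tables do not share sample ids")

    merged_df = pd.concat([t.data for t in tables.values()], axis=1)
    kingdoms = pd.concat([t.kingdoms for t in tables.values()])
    meta = next(iter(tables.values())).metadata
    merged = AbundanceTable(merged_df, kingdoms, meta)

    predictors = pd.DataFrame(index=merged.data.index, dtype=float)
    if "am_fungi" in tables:
        predictors["am_richness"] = (tables["am_fungi"].data > 0).sum(axis=1).astype(float)
    else:
        predictors["am_richness"] = 0.0
    scores = biotic_association_scores(merged, truth.true_network)
    predictors["ppa"] = scores["PPA"]
    predictors["pna"] = scores["PNA"]

    z = predictors.copy()
    for c in z.columns:
        sd = z[c].std()
        z[c] = (z[c] - z[c].mean()) / sd if sd > 0 else 0.0

    rng = np.random.default_rng(seed)
    signal = sum(
        truth.effect_coefficients.get(p, 0.0) * PREDICTOR_SIGNS[p] * z[p]
        for p in ("am_richness", "ppa", "pna")
    )
    data = {}
    for f in FUNCTION_IDS:
        data[f] = signal + rng.normal(0.0, noise_sd, len(z))
    return FunctionTable(pd.DataFrame(data, index=merged.data.index))
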