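"""Network topology: summary metrics, module roles, keystones, association scores.

Covers the descriptive side of the co-occurrence analysis: whole-network
topological characteristics, greedy-modularity module detection, Zi-Pi node
roles (module hubs, network hubs, connectors, peripherals), Kleinberg hub
centrality with keystone thresholding, per-sample induced subnetworks, and
community-level positive/negative biotic-association scores (PPA/PNA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceTable, SignedNetwork

#: Zi-Pi role thresholds: module hubs (Z > 2.5, P < 0.62),
#: network hubs (Z > 2.5, P > 0.62), connectors (Z < 2.5, P > 0.62).
Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62

#: Hub-centrality score above which a node is called a keystone taxon.
KEYSTONE_THRESHOLD = 0.7


@dataclass
class TopologySummary:
    node_count: int
    edge_count: int
    positive_edge_count: int
    negative_edge_count: int
    average_degree: float
    average_path_length: float
    diameter: float
    density: float
    clustering_coefficient: float
    modularity: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def summary_metrics(network: SignedNetwork, seed: int = 0) -> TopologySummary:
    """Whole-network topological characteristics.

    Average path length and diameter are computed on the unweighted graph
    over connected node pairs only (0 if no pair is connected); clustering is
    the mean local clustering coefficient; modularity is evaluated at the
    detected module partition.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty node set")
    e = g.number_of_edges()
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0

    path_sum, path_pairs, diameter = 0.0, 0, 0.0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        for a, dists in lengths.items():
            for b, d in dists.items():
                if a < b:
                    path_sum += d
                    path_pairs += 1
                    diameter = max(diameter, d)
    apl = path_sum / path_pairs if path_pairs else 0.0

    clustering = float(np.mean(list(nx.clustering(g).values()))) if n else 0.0

    if e:
        modules = detect_modules(network, seed=seed)
        communities = _as_communities(modules)
        modularity = nx.community.modularity(g, communities)
    else:
        modularity = 0.0

    return TopologySummary(
        node_count=n,
        edge_count=e,
        positive_edge_count=len(network.positive_edges()),
        negative_edge_count=len(network.negative_edges()),
        average_degree=avg_degree,
        average_path_length=apl,
        diameter=diameter,
        density=density,
        clustering_coefficient=clustering,
        modularity=modularity,
    )


def _as_communities(modules: pd.Series) -> list[set]:
    return [set(modules.index[modules == m]) for m in sorted(modules.unique())]


def detect_modules(network: SignedNetwork, seed: int = 0) -> pd.Series:
    """Greedy modularity maximization; returns taxon -> module id.

    Deterministic for a given graph (the greedy algorithm uses no
    randomness; ``seed`` is accepted for interface uniformity and recorded
    use elsewhere). An edgeless network puts every node in its own module.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        return pd.Series(
            {node: i for i, node in enumerate(sorted(g.nodes))}, dtype=int
        )
    communities = nx.community.greedy_modularity_communities(g)
    assignment: dict[str, int] = {}
    for m, comm in enumerate(communities):
        for node in comm:
            assignment[node] = m
    return pd.Series(assignment, dtype=int).loc[list(g.nodes)]


def zi_pi(network: SignedNetwork, modules: pd.Series) -> pd.DataFrame:
    """Within-module degree z-score (Z) and participation coefficient (P).

    Z_i = (kappa_i - mean kappa over i's module) / sd kappa over the module,
    where kappa is the within-module degree (sd = 0 gives Z = 0).
    P_i = 1 - sum_m (kappa_im / k_i)^2; isolated nodes get P = 0.
    Roles follow the standard thresholds (Z 2.5, P 0.62); boundary equality
    falls to the peripheral/connector side of each strict inequality.
    """
    g = network.graph
    missing = set(g.nodes) - set(modules.index)
    if missing:
        raise ValueError(f"module assignment missing nodes: {sorted(missing)[:5]}")

    within_degree: dict[str, float] = {}
    part: dict[str, float] = {}
    for node in g.nodes:
        k_i = g.degree(node)
        counts: dict[int, int] = {}
        for nb in g.neighbors(node):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        within_degree[node] = counts.get(modules[node], 0)
        if k_i == 0:
            part[node] = 0.0
        else:
            part[node] = 1.0 - sum((c / k_i) ** 2 for c in counts.values())

    z: dict[str, float] = {}
    for m in modules.unique():
        members = [n for n in g.nodes if modules[n] == m]
        kappas = np.array([within_degree[n] for n in members], dtype=float)
        mu, sd = kappas.mean(), kappas.std(ddof=0)
        for node, kappa in zip(members, kappas):
            z[node] = 0.0 if sd == 0 else (kappa - mu) / sd

    rows = []
    for node in g.nodes:
        zi, pi = z[node], part[node]
        if zi > Z_THRESHOLD and pi < P_THRESHOLD:
            role = "module_hub"
        elif zi > Z_THRESHOLD and pi > P_THRESHOLD:
            role = "network_hub"
        elif zi < Z_THRESHOLD and pi > P_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"taxon": node, "Z": zi, "P": pi, "role": role,
                     "module": int(modules[node])})
    return pd.DataFrame(rows).set_index("taxon")


def hub_centrality(network: SignedNetwork) -> pd.Series:
    """Kleinberg hub scores on the unsigned adjacency, max-normalized to 1.

    On an undirected graph the hub and authority scores coincide with the
    principal adjacency eigenvector. Scores are computed per connected
    component (each component's principal eigenvector, scaled by the
    component's spectral radius so denser components dominate) and then
    normalized globally so the overall maximum is 1.
    """
    g = network.graph
    scores = pd.Series(0.0, index=list(g.nodes))
    if g.number_of_edges() == 0:
        return scores
    best = 0.0
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        a = nx.to_numpy_array(g.subgraph(comp), nodelist=comp, weight=None)
        eigvals, eigvecs = np.linalg.eigh(a)
        lam = eigvals[-1]
        if lam <= 0:
            continue
        v = np.abs(eigvecs[:, -1])
        v = v / v.max() * lam  # weight component by its spectral radius
        for node, s in zip(comp, v):
            scores[node] = s
        best = max(best, lam)
    if best > 0:
        scores = scores / scores.max()
    return scores


def keystones(scores: pd.Series, threshold: float = KEYSTONE_THRESHOLD) -> list[str]:
    """Taxa whose hub-centrality score is >= ``threshold``."""
    return sorted(scores.index[scores >= threshold])


def sample_subnetwork(
    network: SignedNetwork, sample_abundances: pd.Series
) -> tuple[SignedNetwork, TopologySummary]:
    """Induced subgraph on taxa present (abundance > 0) in one sample.

    Taxa missing from the abundance vector count as absent. An empty
    subnetwork gets all-zero metrics rather than an error, so per-sample
    sweeps never abort.
    """
    present = [
        t for t in network.graph.nodes if sample_abundances.get(t, 0.0) > 0
    ]
    sub = network.subgraph(present)
    if sub.n_nodes == 0:
        return sub, TopologySummary(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return sub, summary_metrics(sub)


def per_sample_topology(
    network: SignedNetwork, table: AbundanceTable
) -> pd.DataFrame:
    """Subnetwork metrics for every sample of an abundance table."""
    rows = {}
    for sid in table.sample_ids:
        _, summ = sample_subnetwork(network, table.data.loc[sid])
        rows[sid] = summ.as_series()
    return pd.DataFrame(rows).T


def edge_share(network: SignedNetwork, kingdom_a: str, kingdom_b: str) -> float:
    """Fraction of edges joining ``kingdom_a`` and ``kingdom_b`` nodes."""
    e = network.n_edges
    if e == 0:
        return 0.0
    count = sum(
        1
        for a, b in network.graph.edges
        if {network.kingdom_of(a), network.kingdom_of(b)} == {kingdom_a, kingdom_b}
        or (
            kingdom_a == kingdom_b
            and network.kingdom_of(a) == network.kingdom_of(b) == kingdom_a
        )
    )
    return count / e


def biotic_association_scores(
    table: AbundanceTable,
    network: SignedNetwork,
    scope: tuple[str, str] | None = None,
    mode: str = "product",
) -> pd.DataFrame:
    """Per-sample positive (PPA) and negative (PNA) biotic-association scores.

    For each sample, PPA sums r_i * r_j over positive edges (i, j) whose
    endpoints are both present, with r the within-sample relative abundance;
    PNA does the same over negative edges. ``scope`` restricts edges to a
    kingdom pair, e.g. ("rhizobia", "am_fungi"). ``mode="degree"`` is the
    alternative abundance-times-signed-degree formulation.
    """
    missing = set(network.graph.nodes) - set(table.taxon_ids)
    if missing:
        raise ValueError(f"network taxa absent from table: {sorted(missing)[:5]}")
    rel = table.relative_abundance()

    def in_scope(a: str, b: str) -> bool:
        if scope is None:
            return True
        ka, kb = network.kingdom_of(a), network.kingdom_of(b)
        return {ka, kb} == set(scope) or (
            scope[0] == scope[1] and ka == kb == scope[0]
        )

    pos = [(a, b) for a, b in network.positive_edges() if in_scope(a, b)]
    neg = [(a, b) for a, b in network.negative_edges() if in_scope(a, b)]
    if not pos and not neg:
        warnings.warn("scope selects no edges; PPA/PNA are all zero")

    out = pd.DataFrame(0.0, index=table.data.index, columns=["PPA", "PNA"])
    if mode == "product":
        for col, edges in (("PPA", pos), ("PNA", neg)):
            for a, b in edges:
                out[col] += rel[a].to_numpy() * rel[b].to_numpy()
    elif mode == "degree":
        for col, edges in (("PPA", pos), ("PNA", neg)):
            deg: dict[str, int] = {}
            for a, b in edges:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            for t, d in deg.items():
                out[col] += rel[t].to_numpy() * d
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
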