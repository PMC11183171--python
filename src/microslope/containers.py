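"""Core data containers for slope-microbiome analyses.

All containers are thin, validated wrappers around pandas/networkx objects:
an :class:`AbundanceTable` (samples x taxa, with kingdom labels and slope
metadata), a :class:`FunctionTable` (samples x 12 ecosystem functions grouped
into four services), and a :class:`SignedNetwork` (undirected signed weighted
co-occurrence graph with per-node kingdom labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "rhizobia", "am_fungi")
POSITIONS = ("top", "middle", "bottom")

#: The 12 ecosystem functions and their grouping into four services.
FUNCTION_SERVICES: dict[str, str] = {
    "DOC": "C_pools",
    "MBC": "C_pools",
    "TDN": "nutrient_cycling",
    "OlsenP": "nutrient_cycling",
    "MBN": "nutrient_cycling",
    "MBP": "nutrient_cycling",
    "BG": "decomposition",
    "NAG": "decomposition",
    "LAP": "decomposition",
    "AP": "decomposition",
    "leafC": "plant_production",
    "litterC": "plant_production",
}

FUNCTION_IDS = tuple(FUNCTION_SERVICES)


class SchemaError(ValueError):
    """Raised when an input object violates its declared schema."""


@dataclass
class AbundanceTable:
    """Samples x taxa non-negative abundance matrix with metadata.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id with one column per taxon. Values are
        counts or absolute gene-copy abundances (non-negative reals).
    kingdoms :
        Series mapping taxon id -> kingdom label in ``KINGDOMS``.
    metadata :
        DataFrame indexed by sample id with at least columns ``position``
        (one of ``POSITIONS``) and ``plot``.
    """

    data: pd.DataFrame
    kingdoms: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise SchemaError("duplicate taxon ids")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (vals < 0).any():
            raise SchemaError("negative abundances")
        self.kingdoms = pd.Series(self.kingdoms)
        missing = set(self.data.columns) - set(self.kingdoms.index)
        if missing:
            raise SchemaError(f"taxa without kingdom label: {sorted(missing)[:5]}")
        bad = set(self.kingdoms.loc[list(self.data.columns)]) - set(KINGDOMS)
        if bad:
            raise SchemaError(f"unknown kingdom labels: {bad}")
        if not set(self.data.index) <= set(self.metadata.index):
            raise SchemaError("samples missing from metadata")
        for col in ("position", "plot"):
            if col not in self.metadata.columns:
                raise SchemaError(f"metadata lacks required column {col!r}")
        badpos = set(self.metadata.loc[list(self.data.index), "position"]) - set(
            POSITIONS
        )
        if badpos:
            raise SchemaError(f"unknown slope positions: {badpos}")
        # align metadata and kingdom labels to the table
        self.metadata = self.metadata.loc[list(self.data.index)]
        self.kingdoms = self.kingdoms.loc[list(self.data.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def positions(self) -> pd.Series:
        """Per-sample slope position."""
        return self.metadata["position"]

    def subset_taxa(self, taxa: Iterable[str]) -> "AbundanceTable":
        taxa = list(taxa)
        return AbundanceTable(
            self.data[taxa].copy(), self.kingdoms.loc[taxa], self.metadata.copy()
        )

    def relative_abundance(self) -> pd.DataFrame:
        """Close each sample to proportions (rows sum to 1)."""
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            raise SchemaError("sample with zero total abundance")
        return self.data.div(totals, axis=0)


@dataclass
class FunctionTable:
    """Samples x 12 ecosystem-function measurements.

    Functions are fixed by design (``FUNCTION_IDS``) and grouped into four
    services: microbially driven C pools, nutrient cycling, decomposition,
    and plant production.
    """

    data: pd.DataFrame
    service_groups: Mapping[str, str] = field(
        default_factory=lambda: dict(FUNCTION_SERVICES)
    )

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(FUNCTION_IDS):
            if set(self.data.columns) == set(FUNCTION_IDS):
                self.data = self.data[list(FUNCTION_IDS)]
            else:
                raise SchemaError(
                    "function table must contain exactly the 12 design functions"
                )
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate sample ids")
        if dict(self.service_groups) != FUNCTION_SERVICES:
            raise SchemaError("service grouping must match the four-service design")
        if self.data.isna().any().any():
            raise SchemaError("missing function measurements")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


class SignedNetwork:
    """Undirected signed weighted co-occurrence network over taxa.

    Nodes carry a ``kingdom`` attribute; edges carry ``sign`` (+1/-1) and
    ``weight`` (non-negative association magnitude). ``provenance`` records
    how the network was inferred (selected lambda, subsample count, seed).
    """

    def __init__(
        self,
        nodes: Mapping[str, str] | Iterable[tuple[str, str]],
        edges: Iterable[tuple[str, str, int, float]] = (),
        provenance: dict | None = None,
    ) -> None:
        g = nx.Graph()
        node_map = dict(nodes)
        for n, k in node_map.items():
            if k not in KINGDOMS:
                raise SchemaError(f"unknown kingdom {k!r} for node {n!r}")
            g.add_node(n, kingdom=k)
        for a, b, sign, weight in edges:
            if a == b:
                raise SchemaError(f"self-loop on {a!r}")
            if a not in node_map or b not in node_map:
                raise SchemaError(f"edge endpoint not declared: ({a!r}, {b!r})")
            if sign not in (1, -1):
                raise SchemaError(f"edge sign must be +1/-1, got {sign!r}")
            if not np.isfinite(weight):
                raise SchemaError("non-finite edge weight")
            if g.has_edge(a, b):
                raise SchemaError(f"duplicate edge ({a!r}, {b!r})")
            g.add_edge(a, b, sign=int(sign), weight=float(weight))
        self.graph = g
        self.provenance = dict(provenance or {})

    @classmethod
    def from_graph(cls, g: nx.Graph, provenance: dict | None = None) -> "SignedNetwork":
        nodes = {n: d.get("kingdom", "bacteria") for n, d in g.nodes(data=True)}
        edges = [
            (a, b, d.get("sign", 1), d.get("weight", 1.0))
            for a, b, d in g.edges(data=True)
        ]
        return cls(nodes, edges, provenance)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def kingdom_of(self, node: str) -> str:
        return self.graph.nodes[node]["kingdom"]

    def edges_signed(self) -> list[tuple[str, str, int, float]]:
        return [
            (a, b, d["sign"], d["weight"]) for a, b, d in self.graph.edges(data=True)
        ]

    def positive_edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, s, _ in self.edges_signed() if s > 0]

    def negative_edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, s, _ in self.edges_signed() if s < 0]

    def subgraph(self, nodes: Iterable[str]) -> "SignedNetwork":
        sub = self.graph.subgraph(list(nodes)).copy()
        return SignedNetwork.from_graph(sub, dict(self.provenance))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and nx.utils.graphs_equal(self.graph, other.graph)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SignedNetwork nodes={self.n_nodes} edges={self.n_edges}>"
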