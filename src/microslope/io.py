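"""Plain-text I/O: TSV tables, Newick trees, GraphML/edge-list networks, JSON.

Abundance tables are written taxa-as-rows (one ``kingdom`` column after the
taxon id, then one column per sample) with the sample metadata in a sidecar
TSV. Networks round-trip through GraphML (authoritative, keeps kingdom
labels) and are also exported as edge-list TSV for spreadsheet use.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import AbundanceTable, FunctionTable, SchemaError, SignedNetwork
from .synthetic import GroundTruth
from .trees import PhylogeneticTree


def write_abundance_table(
    table: AbundanceTable, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    df = table.data.T.copy()
    df.insert(0, "kingdom", table.kingdoms.loc[df.index])
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")
    if metadata_path is not None:
        write_metadata(table.metadata, metadata_path)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise SchemaError(f"duplicate sample ids in {path}")
    meta.index.name = None
    return meta


def read_abundance_table(
    path: str | Path, metadata_path: str | Path
) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "kingdom" not in df.columns:
        raise SchemaError(f"{path} lacks the 'kingdom' column")
    kingdoms = df["kingdom"]
    data = df.drop(columns="kingdom").T
    data = data.apply(pd.to_numeric)
    data.index.name = None
    data.columns.name = None
    meta = read_metadata(metadata_path)
    return AbundanceTable(data, kingdoms, meta)


def write_function_table(table: FunctionTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_function_table(path: str | Path) -> FunctionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return FunctionTable(df.apply(pd.to_numeric))


def write_tree(tree: PhylogeneticTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_tree(path: str | Path) -> PhylogeneticTree:
    return PhylogeneticTree.from_newick(Path(path).read_text())


def write_network_edgelist(network: SignedNetwork, path: str | Path) -> None:
    rows = [
        {"taxon_a": a, "taxon_b": b, "sign": s, "weight": w}
        for a, b, s, w in network.edges_signed()
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_network_graphml(network: SignedNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, path)


def read_network_graphml(path: str | Path, provenance: dict | None = None) -> SignedNetwork:
    g = nx.read_graphml(path)
    return SignedNetwork.from_graph(g, provenance)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "scenario": truth.scenario,
        "seed": truth.seed,
        "effect_coefficients": truth.effect_coefficients,
        "edges": [
            {"taxon_a": a, "taxon_b": b, "sign": s, "weight": w}
            for a, b, s, w in truth.true_network.edges_signed()
        ],
        "habitat_optima": {
            k: float(v) for k, v in truth.habitat_optima.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_distance_matrix(dist: pd.DataFrame, path: str | Path) -> None:
    out = dist.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    return df.apply(pd.to_numeric)


def check_sample_intersection(
    tables: dict[str, AbundanceTable],
    functions: FunctionTable | None = None,
    allow_subset: bool = False,
) -> list[str]:
    """Shared sample ids across inputs; mismatches fatal unless allowed."""
    sets = [set(t.sample_ids) for t in tables.values()]
    if functions is not None:
        sets.append(set(functions.sample_ids))
    common = set.intersection(*sets)
    union = set.union(*sets)
    if common != union and not allow_subset:
        raise SchemaError(
            f"sample ids differ across inputs ({len(common)} shared of {len(union)})"
        )
    if not common:
        raise SchemaError("no shared sample ids across inputs")
    return sorted(common)
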