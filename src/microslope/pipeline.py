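"""End-to-end orchestration: simulate -> multifunctionality -> networks ->
topology/associations -> assembly -> community statistics.

A :class:`PipelineConfig` fully determines a run; every stage writes TSV/
GraphML/JSON outputs under the configured directory, and a manifest records
the config hash and every seed so deterministic stages are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .assembly import quantify_assembly
from .containers import AbundanceTable, FunctionTable
from .multifunctionality import compute_multifunctionality
from .network import filter_asvs, infer_network, merge_kingdom_tables
from .stats import (
    bray_curtis,
    constrained_pcoa,
    mantel_test,
    permanova,
    variation_partitioning,
)
from .synthetic import (
    DEFAULT_N_TAXA,
    generate_kingdom_trees,
    generate_truth_network,
    simulate_abundances,
    simulate_functions,
)
from .topology import (
    biotic_association_scores,
    detect_modules,
    hub_centrality,
    keystones,
    per_sample_topology,
    summary_metrics,
    zi_pi,
)

log = logging.getLogger("microslope")


@dataclass
class PipelineConfig:
    """Everything a run needs; a config hash stamps every output."""

    output_dir: str = "microslope_out"
    seed: int = 0
    # simulation
    n_taxa: dict = field(default_factory=lambda: dict(DEFAULT_N_TAXA))
    n_samples: int = 18
    depth: float = 1000.0
    scenario: str = "selection"
    edge_density: float = 0.1
    positive_fraction: float = 0.7
    noise_sd: float = 0.5
    # filtering
    min_prevalence: float = 0.25
    min_rel_abund: float = 1e-5
    # network inference
    n_subsamples: int = 50
    subsample_fraction: float = 0.8
    stars_threshold: float = 0.05
    # null models / permutations
    n_null: int = 1000
    n_permutations: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def simulate_stage(config: PipelineConfig) -> dict:
    truth = generate_truth_network(
        config.n_taxa,
        edge_density=config.edge_density,
        positive_fraction=config.positive_fraction,
        seed=config.seed,
    )
    trees = generate_kingdom_trees(truth, seed=config.seed)
    tables = simulate_abundances(
        truth,
        trees,
        n_samples=config.n_samples,
        depth=config.depth,
        scenario=config.scenario,
        seed=config.seed,
    )
    functions = simulate_functions(
        tables, truth, noise_sd=config.noise_sd, seed=config.seed
    )
    return {"truth": truth, "trees": trees, "tables": tables, "functions": functions}


def run_all(
    config: PipelineConfig,
    tables: dict[str, AbundanceTable] | None = None,
    functions: FunctionTable | None = None,
    trees: dict | None = None,
) -> dict:
    """Run the full analysis; simulate inputs when none are supplied.

    Returns the in-memory result bundle and writes all outputs under
    ``config.output_dir``. Any stage failure is re-raised after the partial
    outputs are moved under ``<output_dir>/failed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seeds": {"master": config.seed},
        "stages": [],
        "warnings": [],
    }
    results: dict = {}
    stage = "setup"
    try:
        if tables is None:
            stage = "simulate"
            t0 = time.time()
            sim = simulate_stage(config)
            tables, functions, trees = sim["tables"], sim["functions"], sim["trees"]
            results["truth"] = sim["truth"]
            for k, t in tables.items():
                msio.write_abundance_table(t, out / f"abundance_{k}.tsv")
            msio.write_metadata(
                next(iter(tables.values())).metadata, out / "metadata.tsv"
            )
            for k, tr in (trees or {}).items():
                msio.write_tree(tr, out / f"tree_{k}.nwk")
            msio.write_function_table(functions, out / "functions.tsv")
            msio.write_ground_truth(sim["truth"], out / "ground_truth.json")
            manifest["stages"].append({"stage": stage, "elapsed": time.time() - t0})
        results["tables"] = tables
        results["functions"] = functions
        results["trees"] = trees

        stage = "multifunctionality"
        t0 = time.time()
        mf = compute_multifunctionality(functions)
        results["multifunctionality"] = mf
        mf.standardized.to_csv(out / "functions_standardized.tsv", sep="\t")
        mf.average_mf.to_frame().to_csv(out / "average_multifunctionality.tsv", sep="\t")
        axes = mf.dim_scores.copy()
        axes.to_csv(out / "multifunctionality_axes.tsv", sep="\t")
        pd.DataFrame(
            {
                "axis": axes.columns,
                "explained_variance_pct": 100 * mf.explained_variance,
            }
        ).to_csv(out / "multifunctionality_variance.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "elapsed": time.time() - t0})

        stage = "network"
        t0 = time.time()
        filtered = {
            k: filter_asvs(t, config.min_prevalence, config.min_rel_abund)
            for k, t in tables.items()
        }
        results["filtered"] = filtered
        network_specs = {
            "bacteria": [filtered["bacteria"]],
            "rhizobia": [filtered["rhizobia"]],
            "bacteria_am": [filtered["bacteria"], filtered["am_fungi"]],
            "rhizobia_am": [filtered["rhizobia"], filtered["am_fungi"]],
        }
        networks = {}
        for name, parts in network_specs.items():
            table = parts[0] if len(parts) == 1 else merge_kingdom_tables(parts)
            net = infer_network(
                table,
                n_subsamples=config.n_subsamples,
                subsample_fraction=config.subsample_fraction,
                instability_threshold=config.stars_threshold,
                seed=config.seed,
            )
            networks[name] = net
            msio.write_network_edgelist(net, out / f"network_{name}.tsv")
            msio.write_network_graphml(net, out / f"network_{name}.graphml")
            (out / f"network_{name}_provenance.json").write_text(
                json.dumps(net.provenance, indent=1)
            )
            if "warning" in net.provenance:
                manifest["warnings"].append(f"{name}: {net.provenance['warning']}")
        results["networks"] = networks
        manifest["stages"].append({"stage": stage, "elapsed": time.time() - t0})

        stage = "topology"
        t0 = time.time()
        topo_rows = {}
        roles = {}
        keystone_map = {}
        subnet_metrics = {}
        assoc_scores = {}
        for name, net in networks.items():
            topo_rows[name] = summary_metrics(net, seed=config.seed).as_series()
            if net.n_edges:
                modules = detect_modules(net, seed=config.seed)
                roles[name] = zi_pi(net, modules)
                roles[name].to_csv(out / f"node_roles_{name}.tsv", sep="\t")
            scores = hub_centrality(net)
            keystone_map[name] = keystones(scores)
            scores.rename("hub_centrality").to_frame().assign(
                keystone=scores.index.isin(keystone_map[name])
            ).to_csv(out / f"hub_centrality_{name}.tsv", sep="\t")
        for name, parts in network_specs.items():
            table = parts[0] if len(parts) == 1 else merge_kingdom_tables(parts)
            subnet_metrics[name] = per_sample_topology(networks[name], table)
            subnet_metrics[name].to_csv(out / f"subnetwork_metrics_{name}.tsv", sep="\t")
            scope = None
            if name == "bacteria_am":
                scope = ("bacteria", "am_fungi")
            elif name == "rhizobia_am":
                scope = ("rhizobia", "am_fungi")
            assoc_scores[name] = biotic_association_scores(
                table, networks[name], scope=scope
            )
            assoc_scores[name].to_csv(out / f"biotic_associations_{name}.tsv", sep="\t")
        pd.DataFrame(topo_rows).T.to_csv(out / "topology_summary.tsv", sep="\t")
        (out / "keystones.json").write_text(json.dumps(keystone_map, indent=1))
        results.update(
            topology=pd.DataFrame(topo_rows).T,
            roles=roles,
            keystones=keystone_map,
            subnetworks=subnet_metrics,
            associations=assoc_scores,
        )
        manifest["stages"].append({"stage": stage, "elapsed": time.time() - t0})

        stage = "assembly"
        t0 = time.time()
        assembly = {}
        for k in ("bacteria", "rhizobia"):
            if trees is None or k not in trees:
                continue
            dmat = trees[k].tip_distance_matrix()
            comm = filtered[k].data[
                [t for t in filtered[k].taxon_ids if t in dmat.index]
            ]
            res = quantify_assembly(
                comm, dmat.loc[comm.columns, comm.columns],
                n_null=config.n_null, seed=config.seed,
            )
            assembly[k] = res
            res.pairs.to_csv(out / f"assembly_pairs_{k}.tsv", sep="\t", index=False)
            res.fractions.rename("fraction").to_frame().to_csv(
                out / f"assembly_fractions_{k}.tsv", sep="\t"
            )
        results["assembly"] = assembly
        manifest["stages"].append({"stage": stage, "elapsed": time.time() - t0})

        stage = "stats"
        t0 = time.time()
        stats_records = []
        meta = next(iter(tables.values())).metadata
        grouping = meta["position"]
        func_dist = pd.DataFrame(
            np.abs(
                mf.average_mf.to_numpy()[:, None] - mf.average_mf.to_numpy()[None, :]
            ),
            index=mf.average_mf.index,
            columns=mf.average_mf.index,
        )
        # distances on the full tables: the prevalence/abundance filter is a
        # network-analysis step, not part of the community profile
        dists = {}
        for k, t in tables.items():
            dists[k] = bray_curtis(t)
            msio.write_distance_matrix(dists[k], out / f"bray_curtis_{k}.tsv")
            pr = permanova(
                dists[k], grouping, n_permutations=config.n_permutations,
                seed=config.seed,
            )
            stats_records.append(
                {"analysis": "permanova_position", "scope": k,
                 "statistic": pr.statistic, "R2": pr.extra["R2"],
                 "p_value": pr.p_value, "n_permutations": pr.n_permutations,
                 "seed": pr.seed}
            )
            mr = mantel_test(
                dists[k], func_dist, n_permutations=config.n_permutations,
                seed=config.seed,
            )
            stats_records.append(
                {"analysis": "mantel_community_vs_multifunctionality", "scope": k,
                 "statistic": mr.statistic, "p_value": mr.p_value,
                 "n_permutations": mr.n_permutations, "seed": mr.seed}
            )
            cp = constrained_pcoa(
                dists[k], grouping, n_permutations=config.n_permutations,
                seed=config.seed,
            )
            cp["scores"].to_csv(out / f"cpcoa_scores_{k}.tsv", sep="\t")
            stats_records.append(
                {"analysis": "cpcoa_position", "scope": k,
                 "statistic": cp["constrained_fraction"], "p_value": cp["p_value"],
                 "n_permutations": config.n_permutations, "seed": config.seed}
            )
        abiotic = pd.get_dummies(grouping, prefix="pos", drop_first=True).astype(float)
        cross = "bacteria_am" if "bacteria_am" in assoc_scores else None
        if cross:
            biotic = assoc_scores[cross].copy()
            biotic["am_richness"] = (
                (tables["am_fungi"].data > 0).sum(axis=1).astype(float)
            )
            vp = variation_partitioning(
                dists["bacteria"], abiotic, biotic,
                n_permutations=config.n_permutations, seed=config.seed,
            )
            stats_records.append(
                {"analysis": "varpart_abiotic_vs_biotic", "scope": "bacteria",
                 "statistic": vp["adj_r2"]["AB"], "p_value": vp["p_value"],
                 "unique_a": vp["unique_a"], "unique_b": vp["unique_b"],
                 "shared": vp["shared"], "residual": vp["residual"],
                 "n_permutations": vp["n_permutations"], "seed": vp["seed"]}
            )
            results["varpart"] = vp
        stats_df = pd.DataFrame(stats_records)
        stats_df.to_csv(out / "stats_results.tsv", sep="\t", index=False)
        results["stats"] = stats_df
        results["distances"] = dists
        manifest["stages"].append({"stage": stage, "elapsed": time.time() - t0})

        manifest["seeds"].update(
            network=config.seed, null_models=config.seed, permutations=config.seed
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        results["manifest"] = manifest
        return results
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        manifest["failed_stage"] = stage
        (failed / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
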