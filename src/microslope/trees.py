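"""Rooted phylogenies with branch lengths, backed by dendropy.

Provides simulation of random rooted trees (pure-birth topology), Brownian
trait evolution along a tree (used for phylogenetically conserved habitat
preferences), and patristic tip-distance matrices consumed by the
phylogenetic null models.
"""

from __future__ import annotations

import random
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim


class PhylogeneticTree:
    """A rooted tree with strictly positive branch lengths over taxon tips."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhylogeneticTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'!r}"
                )
        return cls(tree)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def tip_distance_matrix(self) -> pd.DataFrame:
        """Patristic (sum of branch lengths) distances between all tip pairs."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.tip_labels
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return pd.DataFrame(d, index=labels, columns=labels)

    def brownian_trait(self, sigma: float, seed: int) -> pd.Series:
        """Evolve a trait by Brownian motion from root to tips.

        Increments along each branch are N(0, sigma^2 * branch_length), so
        tip values are phylogenetically autocorrelated: close relatives get
        similar values.
        """
        rng = np.random.default_rng(seed)
        values: dict[int, float] = {id(self.tree.seed_node): 0.0}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            parent_val = values[id(node.parent_node)]
            bl = node.edge.length or 0.0
            values[id(node)] = parent_val + rng.normal(0.0, sigma * np.sqrt(bl))
        out = {
            leaf.taxon.label: values[id(leaf)] for leaf in self.tree.leaf_node_iter()
        }
        return pd.Series(out)

    def deep_clade_contrast(self) -> pd.Series:
        """+1/-1 tip labels by the deepest split (the root's child clades).

        Models habitat preferences conserved at a deep phylogenetic level:
        all members of one root clade share one preference sign. With a root
        polytomy, clades alternate signs.
        """
        vals: dict[str, float] = {}
        for i, kid in enumerate(self.tree.seed_node.child_nodes()):
            sign = 1.0 if i % 2 == 0 else -1.0
            for leaf in kid.leaf_iter():
                vals[leaf.taxon.label] = sign
        return pd.Series(vals)

    def relabel_tips(self, labels: Sequence[str]) -> None:
        """Assign new tip labels in leaf-iteration order."""
        leaves = list(self.tree.leaf_node_iter())
        if len(labels) != len(leaves):
            raise ValueError("label count does not match tip count")
        for leaf, lab in zip(leaves, labels):
            leaf.taxon.label = lab


def generate_phylogeny(n_tips: int, seed: int, labels: Sequence[str] | None = None) -> PhylogeneticTree:
    """Simulate a rooted binary tree with ``n_tips`` tips (pure-birth process).

    Deterministic given ``seed``. Branch lengths are strictly positive
    exponential waiting times of a Yule process with birth rate 1.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=int(n_tips),
        rng=rng,
    )
    # guard against zero-length edges from simultaneous events
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if not edge.length or edge.length <= 0:
            edge.length = 1e-6
    ptree = PhylogeneticTree(tree)
    if labels is None:
        width = len(str(n_tips))
        labels = [f"t{str(i + 1).zfill(width)}" for i in range(n_tips)]
    ptree.relabel_tips(labels)
    return ptree
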