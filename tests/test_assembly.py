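"""Phylogenetic and taxonomic null models: betaMNTD, betaNTI, RC_Bray, QPEN."""

import numpy as np
import pandas as pd
import pytest

from microslope.assembly import (
    beta_mntd,
    beta_mntd_matrix,
    beta_nti,
    classify_assembly,
    rc_bray,
)
from microslope.trees import PhylogeneticTree, generate_phylogeny


@pytest.fixture(scope="module")
def balanced_tree():
    return PhylogeneticTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def brute_force_beta_mntd(comm_a, comm_b, dmat):
    """Independent double-loop oracle."""
    a = {t: v for t, v in comm_a.items() if v > 0}
    b = {t: v for t, v in comm_b.items() if v > 0}
    fa = {t: v / sum(a.values()) for t, v in a.items()}
    fb = {t: v / sum(b.values()) for t, v in b.items()}
    term_a = sum(f * min(dmat.loc[t, u] for u in b) for t, f in fa.items())
    term_b = sum(f * min(dmat.loc[u, t] for u in a) for t, f in fb.items())
    return 0.5 * (term_a + term_b)


class TestBetaMntd:
    def test_identical_communities_zero(self, balanced_tree):
        c = pd.Series({"A": 3.0, "C": 1.0})
        assert beta_mntd(c, c, balanced_tree) == 0.0

    def test_single_taxon_communities(self, balanced_tree):
        # d(A, C) = 1 + 1 + 1 + 1 = 4
        a = pd.Series({"A": 1.0})
        c = pd.Series({"C": 1.0})
        assert beta_mntd(a, c, balanced_tree) == pytest.approx(4.0)

    def test_matches_brute_force_oracle(self, balanced_tree):
        dmat = balanced_tree.tip_distance_matrix()
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = pd.Series(rng.integers(0, 5, 4).astype(float), index=list("ABCD"))
            b = pd.Series(rng.integers(0, 5, 4).astype(float), index=list("ABCD"))
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert beta_mntd(a, b, dmat) == pytest.approx(
                brute_force_beta_mntd(a, b, dmat), abs=1e-12
            )

    def test_matrix_agrees_with_pairwise(self):
        tree = generate_phylogeny(12, seed=2)
        rng = np.random.default_rng(4)
        comm = pd.DataFrame(
            rng.poisson(2.0, (5, 12)).astype(float),
            index=[f"S{i}" for i in range(5)],
            columns=tree.tip_labels,
        )
        comm[comm.sum(axis=1) == 0] = 1.0
        dmat = tree.tip_distance_matrix()
        mat = beta_mntd_matrix(comm, dmat)
        for i in range(5):
            for j in range(i + 1, 5):
                assert mat.iloc[i, j] == pytest.approx(
                    beta_mntd(comm.iloc[i], comm.iloc[j], dmat), abs=1e-12
                )

    def test_empty_community_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="empty"):
            beta_mntd(pd.Series({"A": 0.0}), pd.Series({"C": 1.0}), balanced_tree)


def independent_beta_nti(comm, dmat, n_null, seed):
    """Dual implementation with its own shuffle loop (same RNG protocol:
    one full tip permutation per null round)."""
    samples = list(comm.index)
    labels = list(dmat.index)
    obs = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            obs[(a, b)] = brute_force_beta_mntd(comm.loc[a], comm.loc[b], dmat)
    rng = np.random.default_rng(seed)
    nulls = {k: [] for k in obs}
    arr = dmat.to_numpy()
    for _ in range(n_null):
        perm = rng.permutation(len(labels))
        shuffled = pd.DataFrame(
            arr[np.ix_(perm, perm)], index=labels, columns=labels
        )
        for (a, b) in obs:
            nulls[(a, b)].append(
                brute_force_beta_mntd(comm.loc[a], comm.loc[b], shuffled)
            )
    out = {}
    for k, v in nulls.items():
        v = np.array(v)
        out[k] = (obs[k] - v.mean()) / v.std(ddof=0)
    return out


class TestBetaNti:
    def test_matches_independent_reimplementation(self, balanced_tree):
        comm = pd.DataFrame(
            [[3.0, 1.0, 0.0, 0.0], [0.0, 0.0, 2.0, 2.0], [1.0, 0.0, 1.0, 0.0]],
            index=["S1", "S2", "S3"],
            columns=list("ABCD"),
        )
        dmat = balanced_tree.tip_distance_matrix()
        got = beta_nti(comm, dmat, n_null=100, seed=7)
        want = independent_beta_nti(comm, dmat, n_null=100, seed=7)
        for (a, b), z in want.items():
            assert got.loc[a, b] == pytest.approx(z, abs=1e-12)

    def test_degenerate_pair_reported_missing(self, balanced_tree):
        comm = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]],
            index=["S1", "S2"],
            columns=list("ABCD"),
        )
        # identical full communities: observed and all nulls are 0
        with pytest.warns(UserWarning, match="undefined"):
            z = beta_nti(comm, balanced_tree.tip_distance_matrix(),
                         n_null=100, seed=1)
        assert np.isnan(z.loc["S1", "S2"])

    def test_branch_length_scale_invariance(self):
        tree = generate_phylogeny(15, seed=9)
        rng = np.random.default_rng(10)
        comm = pd.DataFrame(
            rng.poisson(1.5, (4, 15)).astype(float),
            index=[f"S{i}" for i in range(4)],
            columns=tree.tip_labels,
        )
        comm.iloc[:, 0] += 1.0  # no empty samples
        dmat = tree.tip_distance_matrix()
        z1 = beta_nti(comm, dmat, n_null=100, seed=3)
        z2 = beta_nti(comm, dmat * 7.5, n_null=100, seed=3)
        assert np.allclose(z1.fillna(0), z2.fillna(0), atol=1e-9)

    def test_seed_determinism(self, balanced_tree):
        comm = pd.DataFrame(
            [[3.0, 1.0, 0.0, 1.0], [0.0, 1.0, 2.0, 2.0]],
            index=["S1", "S2"],
            columns=list("ABCD"),
        )
        d = balanced_tree.tip_distance_matrix()
        assert beta_nti(comm, d, n_null=100, seed=5).equals(
            beta_nti(comm, d, n_null=100, seed=5)
        )


class TestRcBray:
    def test_identical_pair_at_distribution_minimum(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(3.0, 12).astype(float) + 1.0
        comm = pd.DataFrame(
            [base, base, rng.poisson(3.0, 12).astype(float) + 1.0],
            index=["S1", "S2", "S3"],
            columns=[f"t{i}" for i in range(12)],
        )
        rc = rc_bray(comm, n_null=100, seed=2)
        assert rc.loc["S1", "S2"] <= -0.99

    def test_values_bounded(self):
        rng = np.random.default_rng(6)
        comm = pd.DataFrame(
            rng.poisson(2.0, (6, 20)).astype(float) + (rng.random((6, 20)) < 0.1),
            index=[f"S{i}" for i in range(6)],
            columns=[f"t{i}" for i in range(20)],
        )
        comm.iloc[:, 0] += 1.0
        rc = rc_bray(comm, n_null=100, seed=3)
        assert (rc.to_numpy() <= 1.0 + 1e-12).all()
        assert (rc.to_numpy() >= -1.0 - 1e-12).all()
        assert rc.equals(rc_bray(comm, n_null=100, seed=3))

    def test_disjoint_pair_with_shared_pool_high_rc(self):
        # observed BC = 1 between disjoint halves, but the regional pool
        # makes null communities overlap almost surely
        comm = pd.DataFrame(
            [
                [5.0, 5.0, 5.0, 5.0, 0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0],
                [3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
                [3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
            ],
            index=["S1", "S2", "S3", "S4"],
            columns=[f"t{i}" for i in range(8)],
        )
        rc = rc_bray(comm, n_null=200, seed=4)
        assert rc.loc["S1", "S2"] > 0.9


class TestClassifyAssembly:
    @pytest.mark.parametrize(
        "b,r,expected",
        [
            (3.0, 0.0, "variable_selection"),
            (-3.0, 0.0, "homogeneous_selection"),
            (0.0, 0.99, "dispersal_limitation"),
            (0.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "drift"),
            (2.0, 0.99, "dispersal_limitation"),  # boundary |bNTI|=2 stochastic
            (0.0, 0.95, "drift"),  # boundary RC=0.95 -> drift
        ],
    )
    def test_threshold_rules(self, b, r, expected):
        ids = ["S1", "S2"]
        bnti = pd.DataFrame([[0.0, b], [b, 0.0]], index=ids, columns=ids)
        rc = pd.DataFrame([[0.0, r], [r, 0.0]], index=ids, columns=ids)
        res = classify_assembly(bnti, rc)
        assert res.pairs.iloc[0]["process"] == expected

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        n = 8
        ids = [f"S{i}" for i in range(n)]
        b = rng.normal(0, 3, (n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r = np.clip(rng.normal(0, 0.8, (n, n)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        res = classify_assembly(
            pd.DataFrame(b, index=ids, columns=ids),
            pd.DataFrame(r, index=ids, columns=ids),
        )
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_bnti_excluded_and_counted(self):
        ids = ["S1", "S2", "S3"]
        b = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        b.loc["S1", "S2"] = b.loc["S2", "S1"] = np.nan
        r = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        res = classify_assembly(b, r)
        assert res.n_excluded == 1
        assert res.fractions.sum() == pytest.approx(1.0)
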