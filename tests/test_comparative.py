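"""Phylogenetic signal, PLS, PGLS and ancestral-state estimation."""

import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from talarmorph.comparative import (ancestral_bm, gls_mean,
                                    interpolate_branches, kmult,
                                    pgls_multivariate, phylo_transform,
                                    pls_phylo, pls_two_block)
from talarmorph.dataio import PhyloTree
from talarmorph.synthetic import sim_traits, sim_tree


def univariate_blomberg_k(y, tree):
    """Independent oracle: Blomberg's K from its direct univariate formula."""
    C = tree.vcv()
    n = len(y)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Cinv @ y) / (one @ Cinv @ one)
    d = y - a
    mse0 = d @ d
    mse = d @ Cinv @ d
    expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    return (mse0 / mse) / expected


class TestKmult:
    def test_single_trait_equals_blomberg_k(self, yule16, rng):
        y = sim_traits(yule16, np.eye(1), seed=9).ravel()
        res = kmult(y[:, None], yule16, n_perm=10, seed=0)
        assert res.K == pytest.approx(univariate_blomberg_k(y, yule16),
                                      rel=1e-9)

    def test_brownian_data_centered_on_one(self, yule64):
        Ks = [kmult(sim_traits(yule64, np.eye(3), seed=s), yule64,
                    n_perm=0 or 1, seed=0).K for s in range(60)]
        assert 0.9 <= np.mean(Ks) <= 1.1

    def test_iid_data_has_low_signal(self, yule32):
        rng = np.random.default_rng(4)
        hits = 0
        Ks = []
        for s in range(40):
            Y = rng.standard_normal((yule32.n_tips, 3))
            res = kmult(Y, yule32, n_perm=199, seed=s)
            Ks.append(res.K)
            hits += res.p_value > 0.05
        assert np.median(Ks) < 0.5
        assert hits >= 0.9 * 40 * 0.8  # non-significant in the vast majority

    def test_constant_trait_rejected(self, yule16):
        Y = np.ones((yule16.n_tips, 2))
        with pytest.raises(ValueError):
            kmult(Y, yule16, n_perm=10, seed=0)

    def test_permutation_p_reproducible(self, yule16):
        Y = sim_traits(yule16, np.eye(2), seed=5)
        a = kmult(Y, yule16, n_perm=199, seed=7)
        b = kmult(Y, yule16, n_perm=199, seed=7)
        assert a.p_value == b.p_value
        assert np.array_equal(a.permuted, b.permuted)


class TestPlsTwoBlock:
    def test_exact_linear_map_gives_perfect_covariation(self, rng):
        # orthonormal map: block 2 is an isometric copy of block 1, so the
        # first-dimension scores must be perfectly correlated
        Y1 = rng.standard_normal((25, 4))
        A, _ = np.linalg.qr(rng.standard_normal((4, 3)))
        res = pls_two_block(Y1, Y1 @ A, n_perm=99, seed=0)
        assert res.r_pls >= 0.999
        assert res.p_value < 0.05
        # a general invertible map still yields near-perfect covariation
        res2 = pls_two_block(Y1, Y1 @ rng.standard_normal((4, 4)), n_perm=1,
                             seed=0)
        assert res2.r_pls >= 0.9

    def test_rotation_invariance(self, rng):
        Y1 = rng.standard_normal((20, 3))
        Y2 = rng.standard_normal((20, 4))
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        r0 = pls_two_block(Y1, Y2, n_perm=0 or 1, seed=0).r_pls
        r1 = pls_two_block(Y1, Y2 @ Q, n_perm=0 or 1, seed=0).r_pls
        assert r0 == pytest.approx(r1, abs=1e-9)

    def test_null_p_values_roughly_uniform(self):
        """Independent blocks: permutation p-values should be uniform."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            Y1 = rng.standard_normal((15, 3))
            Y2 = rng.standard_normal((15, 2))
            ps.append(pls_two_block(Y1, Y2, n_perm=99,
                                    seed=int(rng.integers(2 ** 31))).p_value)
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_singular_vectors_unit_norm(self, rng):
        res = pls_two_block(rng.standard_normal((15, 3)),
                            rng.standard_normal((15, 5)), n_perm=1, seed=0)
        assert np.linalg.norm(res.left_vectors) == pytest.approx(1.0)
        assert np.linalg.norm(res.right_vectors) == pytest.approx(1.0)


class TestPlsPhylo:
    def test_star_tree_equals_standard_pls(self, rng):
        star = PhyloTree.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
        Y1 = rng.standard_normal((12, 3))
        Y2 = rng.standard_normal((12, 4))
        r_std = pls_two_block(Y1, Y2, n_perm=1, seed=0).r_pls
        r_phy = pls_phylo(Y1, Y2, star, star.tip_labels, n_perm=1,
                          seed=0).r_pls
        assert r_std == pytest.approx(r_phy, abs=1e-9)

    def test_shared_brownian_factor_detected(self, yule32):
        detected = 0
        for s in range(20):
            # shared Brownian factor plus independent Brownian noise in
            # each block, so the Brownian working model is well specified
            f = sim_traits(yule32, np.eye(1), seed=1000 + s)
            rng = np.random.default_rng(2000 + s)
            Y1 = f @ rng.standard_normal((1, 3)) + sim_traits(
                yule32, 0.09 * np.eye(3), seed=3000 + s)
            Y2 = f @ rng.standard_normal((1, 2)) + sim_traits(
                yule32, 0.09 * np.eye(2), seed=4000 + s)
            res = pls_phylo(Y1, Y2, yule32, n_perm=99, seed=s)
            detected += res.p_value < 0.05
        assert detected >= 18


class TestPgls:
    def test_exact_linear_relation_r2_one(self, yule16, rng):
        X = rng.standard_normal((yule16.n_tips, 2))
        B = rng.standard_normal((2, 3))
        Y = X @ B + 1.0
        res = pgls_multivariate(Y, X, yule16, n_perm=49, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_star_tree_matches_ols(self, rng):
        star = PhyloTree.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        X = rng.standard_normal((20, 1))
        Y = 0.5 * X + rng.standard_normal((20, 1))
        res = pgls_multivariate(Y, X, star, star.tip_labels, n_perm=1, seed=0)
        # OLS oracle
        x = np.hstack([np.ones((20, 1)), X])
        beta, *_ = np.linalg.lstsq(x, Y, rcond=None)
        resid = Y - x @ beta
        sst = ((Y - Y.mean()) ** 2).sum()
        r2_ols = 1 - (resid ** 2).sum() / sst
        assert res.r_squared == pytest.approx(r2_ols, abs=1e-9)


class TestAncestralBm:
    def test_two_tip_midpoint(self):
        t = PhyloTree.from_newick("(A:1,B:1);")
        anc = ancestral_bm(np.array([2.0, 4.0]), t, ["A", "B"])
        assert anc.states[0, 0] == pytest.approx(3.0)

    def test_constant_tips_constant_nodes(self, yule16):
        y = np.full(yule16.n_tips, 7.0)
        anc = ancestral_bm(y, yule16)
        assert np.allclose(anc.states, 7.0, atol=1e-9)
        assert np.allclose(anc.sigma2, 0.0, atol=1e-12)

    def test_matches_numeric_squared_change_minimization(self):
        """Oracle: general-purpose optimizer on sum(delta^2 / branch)."""
        tree = sim_tree(6, 1.0, seed=77)
        y = sim_traits(tree, np.eye(1), seed=78).ravel()
        anc = ancestral_bm(y, tree)
        internal = list(anc.node_ids)
        tip_val = {int(t): y[k] for k, t in enumerate(tree.tip_ids)}

        def objective(states):
            lookup = dict(zip(internal, states))
            lookup.update(tip_val)
            total = 0.0
            for child in range(1, tree.n_nodes):
                parent = int(tree.parent[child])
                d = lookup[child] - lookup[parent]
                total += d * d / tree.edge_length[child]
            return total

        x0 = np.full(len(internal), y.mean())
        res = scipy.optimize.minimize(objective, x0, method="BFGS",
                                      options={"gtol": 1e-12})
        assert np.allclose(anc.states[:, 0], res.x, atol=1e-6)

    def test_root_equals_gls_phylogenetic_mean(self, yule16):
        Y = sim_traits(yule16, np.eye(2), seed=80)
        anc = ancestral_bm(Y, yule16)
        C, _ = phylo_transform(yule16, yule16.tip_labels)
        a = gls_mean(Y, np.linalg.inv(C))
        root_row = list(anc.node_ids).index(0)
        assert np.allclose(anc.states[root_row], a, atol=1e-9)

    def test_single_trait_root_within_tip_hull(self, yule32):
        y = sim_traits(yule32, np.eye(1), seed=81).ravel()
        anc = ancestral_bm(y, yule32)
        root_row = list(anc.node_ids).index(0)
        assert y.min() <= anc.states[root_row, 0] <= y.max()
        assert np.all(anc.lo95 <= anc.states)
        assert np.all(anc.hi95 >= anc.states)


class TestInterpolation:
    def test_midpoint_and_endpoints(self):
        t = PhyloTree.from_newick("(A:1,B:1);")
        anc = ancestral_bm(np.array([0.0, 1.0]), t, ["A", "B"])
        prof = interpolate_branches(anc, t, np.array([0.0, 1.0]),
                                    ["A", "B"], resolution=3)
        # edge into tip A: parent state 0.5, child 0.0
        tip_a = int(t.tip_ids[t.tip_labels.index("A")])
        assert prof[tip_a][0, 0] == pytest.approx(0.5)
        assert prof[tip_a][1, 0] == pytest.approx(0.25)
        assert prof[tip_a][2, 0] == pytest.approx(0.0)

    def test_constant_states_constant_profiles(self, yule16):
        y = np.full(yule16.n_tips, 3.0)
        anc = ancestral_bm(y, yule16)
        prof = interpolate_branches(anc, yule16, y, resolution=5)
        for arr in prof.values():
            assert np.allclose(arr, 3.0, atol=1e-9)
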