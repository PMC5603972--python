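"""Regime painting, BM/EB/OU likelihoods and the AICc model ledger."""

import itertools

import numpy as np
import pytest

from talarmorph.dataio import PhyloTree
from talarmorph.evomodels import (EvoModelFit, aicc, akaike_weights,
                                  clade_painting, fit_bm, fit_eb, fit_ou,
                                  model_table, paint_regimes, param_count,
                                  parsimony_score, single_regime)
from talarmorph.synthetic import sim_traits, sim_tree


class TestPaintRegimes:
    def test_uniform_tips_give_single_regime(self, yule16):
        states = {t: "arb" for t in yule16.tip_labels}
        p = paint_regimes(yule16, states)
        assert set(p.edge_regime.values()) == {"arb"}
        assert p.root_regime == "arb"

    def test_reciprocal_monophyly_shifts_on_stem(self, balanced8):
        states = {t: ("L" if t in "ABCD" else "R") for t in balanced8.tip_labels}
        p = paint_regimes(balanced8, states)
        assert p.n_shifts() == 1
        # every tip edge matches its tip's state
        for k, tip in enumerate(balanced8.tip_ids):
            assert p.edge_regime[int(tip)] == states[balanced8.tip_labels[k]]

    def test_change_count_matches_exhaustive_minimum(self):
        """Oracle: enumerate every internal-state assignment on a 6-tip
        tree and compare the minimal change count with the Fitch score."""
        tree = sim_tree(6, 1.0, seed=61)
        states = {t: ("x" if i % 2 == 0 else "y")
                  for i, t in enumerate(tree.tip_labels)}
        internal = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
        tip_state = {int(t): states[tree.tip_labels[k]]
                     for k, t in enumerate(tree.tip_ids)}
        best = np.inf
        for combo in itertools.product("xy", repeat=len(internal)):
            lookup = dict(zip(internal, combo))
            lookup.update(tip_state)
            changes = sum(
                lookup[c] != lookup[int(tree.parent[c])]
                for c in range(1, tree.n_nodes))
            best = min(best, changes)
        assert parsimony_score(tree, states) == best
        # the returned painting achieves the minimum
        p = paint_regimes(tree, states)
        assert p.n_shifts() == best

    def test_unlabeled_tip_rejected(self, yule16):
        states = {t: "a" for t in yule16.tip_labels[:-1]}
        with pytest.raises(ValueError, match="unlabeled"):
            paint_regimes(yule16, states)

    def test_clade_painting_covers_stem(self, balanced8):
        p = clade_painting(balanced8, {"atelid": ["A", "B"]}, background="bg")
        painted = [e for e, r in p.edge_regime.items() if r == "atelid"]
        assert len(painted) == 3  # stem + two tip edges


class TestParameterCounts:
    @pytest.mark.parametrize("model,m,expected", [
        ("BM", 1, 20), ("EB", 1, 21), ("OU", 1, 35),
        ("OU", 3, 45), ("OU", 4, 50), ("OU", 5, 55), ("OU", 6, 60),
    ])
    def test_five_trait_ledger(self, model, m, expected):
        assert param_count(model, 5, m) == expected


class TestFitBm:
    def test_likelihood_matches_dense_kronecker_oracle(self):
        """ML logL equals a from-scratch dense multivariate-normal density
        with covariance C (x) R on a small tree."""
        tree = sim_tree(8, 1.0, seed=71)
        Y = sim_traits(tree, np.array([[1.0, 0.4], [0.4, 0.8]]), seed=72)
        fit = fit_bm(Y, tree)
        C = tree.vcv()
        V = np.kron(C, fit.R)
        r = (Y - fit.root_state).reshape(-1)
        _, ld = np.linalg.slogdet(V)
        oracle = -0.5 * (len(r) * np.log(2 * np.pi) + ld
                         + r @ np.linalg.solve(V, r))
        assert fit.logL == pytest.approx(oracle, abs=1e-8)

    def test_rate_matrix_recovery(self, yule64):
        R_true = np.array([[1.0, 0.5], [0.5, 2.0]])
        errs = []
        for s in range(30):
            Y = sim_traits(yule64, R_true, seed=s)
            fit = fit_bm(Y, yule64)
            errs.append(np.abs(fit.R - R_true) / np.abs(R_true))
        assert np.median(errs) < 0.25

    def test_likelihood_invariant_to_species_order(self, yule16, rng):
        Y = sim_traits(yule16, np.eye(2), seed=73)
        perm = rng.permutation(yule16.n_tips)
        labels = [yule16.tip_labels[i] for i in perm]
        a = fit_bm(Y, yule16)
        b = fit_bm(Y[perm], yule16, labels)
        assert a.logL == pytest.approx(b.logL, abs=1e-9)

    def test_polytomy_rejected(self):
        t = PhyloTree.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="binary"):
            fit_bm(np.zeros((3, 2)) + np.arange(3)[:, None], t)


class TestFitEb:
    def test_parameter_count(self, yule16):
        Y = sim_traits(yule16, np.eye(5), seed=74)
        assert fit_eb(Y, yule16).k == 21

    def test_a_zero_nests_to_bm(self, yule16):
        Y = sim_traits(yule16, np.eye(2), seed=75)
        eb = fit_eb(Y, yule16, bounds=(-1e-12, 0.0))
        bm = fit_bm(Y, yule16)
        assert eb.logL == pytest.approx(bm.logL, abs=1e-6)

    def test_exponent_recovery(self, yule64):
        # rescale the tree so a = -0.5 is visible over the tree height
        hits = 0
        for s in range(25):
            Y = sim_traits(yule64, np.eye(2), model="EB", a=-0.5, seed=200 + s)
            fit = fit_eb(Y, yule64)
            hits += -1.0 <= fit.a <= -0.1
        assert hits >= 18


class TestFitOu:
    def test_parameter_counts_by_regime_number(self, yule16):
        Y = sim_traits(yule16, np.eye(2), seed=76)
        states3 = {t: "abc"[i % 3] for i, t in enumerate(yule16.tip_labels)}
        assert param_count("OU", 5, 1) == 35
        fit1 = fit_ou(Y, yule16, single_regime(yule16), n_restarts=1, seed=0,
                      maxiter=40)
        assert fit1.k == param_count("OU", 2, 1) == 8
        p3 = paint_regimes(yule16, states3)
        fit3 = fit_ou(Y, yule16, p3, n_restarts=1, seed=0, maxiter=40)
        assert fit3.k == param_count("OU", 2, 3) == 12

    def test_small_alpha_limit_matches_bm(self, yule16):
        Y = sim_traits(yule16, np.eye(2), seed=77)
        bm = fit_bm(Y, yule16)
        ou = fit_ou(Y, yule16, single_regime(yule16),
                    fix_alpha=1e-6 * np.eye(2), n_restarts=2, seed=0)
        assert abs(ou.logL - bm.logL) < 0.5

    def test_regime_optima_recovery_single_dataset(self, yule32):
        T = yule32.tree_height
        states = {t: ("A" if i < 16 else "B")
                  for i, t in enumerate(yule32.tip_labels)}
        paint = paint_regimes(yule32, states)
        alpha = (np.log(2) / (0.1 * T)) * np.eye(2)
        theta = np.array([[0.0, 0.0], [3.0, -3.0]])
        Y = sim_traits(yule32, 0.5 * np.eye(2), model="OU", alpha=alpha,
                       theta=theta, painting=paint, seed=78)
        fit = fit_ou(Y, yule32, paint, n_restarts=2, seed=1)
        assert np.allclose(fit.theta["A"], theta[0], atol=0.5)
        assert np.allclose(fit.theta["B"], theta[1], atol=0.5)
        assert fit.aicc < fit_bm(Y, yule32).aicc

    def test_non_ultrametric_tree_rejected(self):
        t = PhyloTree.from_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            fit_ou(np.arange(6.0).reshape(3, 2), t, single_regime(t))


class TestModelTable:
    @pytest.mark.parametrize("logL,k,expected", [
        (488.9381, 45, -860.9931),   # three-peak model, printed arithmetic
        (446.2441, 21, -845.2973),   # early-burst row
    ])
    def test_aicc_printed_arithmetic(self, logL, k, expected):
        assert aicc(logL, k, 200) == pytest.approx(expected, abs=0.01)

    def test_weights_sum_to_one_and_split_ties(self):
        w = akaike_weights(np.array([10.0, 10.0]))
        assert np.allclose(w, [0.5, 0.5])
        table = model_table([("m1", -10.0, 3), ("m2", -12.0, 4)],
                            n_species=40, p=5)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["delta_AICc"].min() == 0.0

    def test_table_updates_fit_objects(self, yule16):
        Y = sim_traits(yule16, np.eye(2), seed=79)
        fits = [fit_bm(Y, yule16), fit_eb(Y, yule16)]
        table = model_table(fits)
        assert fits[0].weight is not None
        assert table.loc[table["model"] == "BM", "weight"].iloc[0] == fits[0].weight
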