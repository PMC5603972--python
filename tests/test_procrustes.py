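"""Reflection, rotation, superimposition and missing-landmark imputation."""

import numpy as np
import pytest

from talarmorph.dataio import LandmarkConfiguration
from talarmorph.procrustes import (centroid_size, gpa, impute_missing,
                                   optimal_rotation, procrustes_distance,
                                   reflect)
from talarmorph.synthetic import sim_landmarks, sim_tree, default_template


def _config(coords, spec="s", species="X", side="right"):
    return LandmarkConfiguration(spec, species, side, np.asarray(coords, float))


def _random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


class TestReflect:
    def test_negates_axis_and_flips_side(self):
        c = _config([[1.0, 2.0, 3.0], [0, 0, 0], [1, 1, 1], [2, 0, 1]])
        r = reflect(c, "x")
        assert np.allclose(r.coords[0], [-1, 2, 3])
        assert r.side == "left"

    def test_involution(self, rng):
        c = _config(rng.standard_normal((10, 3)))
        back = reflect(reflect(c, "y"), "y")
        assert np.allclose(back.coords, c.coords)
        assert back.side == c.side

    def test_mirrored_copy_aligns_after_reflection(self, rng):
        """A mirrored talus, re-reflected, matches the original shape."""
        coords = rng.standard_normal((12, 3))
        mirrored = coords.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        restored = reflect(_config(mirrored, side="left"), "x")
        assert procrustes_distance(restored.coords, coords) < 1e-8


class TestCentroidSize:
    def test_square_closed_form(self):
        cfg = _config([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]])
        assert centroid_size(cfg) == pytest.approx(2 * np.sqrt(2))

    def test_homogeneous_in_scale(self, rng):
        coords = rng.standard_normal((8, 3))
        assert centroid_size(coords * 3.7) == pytest.approx(
            3.7 * centroid_size(coords))

    def test_matches_direct_summation(self, rng):
        coords = rng.standard_normal((15, 3))
        c = coords.mean(axis=0)
        brute = np.sqrt(sum(np.sum((x - c) ** 2) for x in coords))
        assert centroid_size(coords) == pytest.approx(brute, rel=1e-12)

    def test_all_missing_is_error(self):
        coords = np.full((5, 3), np.nan)
        with pytest.raises(ValueError):
            centroid_size(LandmarkConfiguration("s", "X", "right", coords))


class TestOptimalRotation:
    def test_recovers_true_rotation(self, rng):
        A = rng.standard_normal((10, 3))
        A -= A.mean(axis=0)
        R_true = _random_rotation(rng)
        B = A @ R_true.T
        R = optimal_rotation(A, B)
        assert np.allclose(R, R_true, atol=1e-10)
        assert np.linalg.norm(A @ R.T - B) < 1e-10

    def test_never_reflects(self, rng):
        A = rng.standard_normal((10, 3))
        A -= A.mean(axis=0)
        B = A.copy()
        B[:, 0] = -B[:, 0]
        R = optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert np.linalg.norm(A @ R.T - B) > 1e-3

    def test_beats_random_rotations(self, rng):
        """Monte-Carlo oracle: no random proper rotation does better."""
        A = rng.standard_normal((8, 3))
        B = rng.standard_normal((8, 3))
        A -= A.mean(axis=0)
        B -= B.mean(axis=0)
        R = optimal_rotation(A, B)
        best = np.linalg.norm(A @ R.T - B)
        for _ in range(10_000):
            Rr = _random_rotation(rng)
            assert np.linalg.norm(A @ Rr.T - B) >= best - 1e-12

    def test_degenerate_configuration_rejected(self):
        A = np.zeros((5, 3))
        A[:, 0] = np.arange(5) - 2.0  # rank 1
        with pytest.raises(ValueError, match="degenerate"):
            optimal_rotation(A, A)


class TestGpa:
    def test_identical_configurations_have_zero_distances(self, rng):
        coords = rng.standard_normal((10, 3))
        ds = gpa([_config(coords, f"s{i}") for i in range(5)])
        for i in range(1, 5):
            assert np.linalg.norm(ds.aligned[i] - ds.aligned[0]) < 1e-8

    def test_alignment_invariant_to_rigid_motion_and_scale(self, rng):
        base = rng.standard_normal((10, 3)) * 5
        configs = [_config(base + rng.standard_normal((10, 3)) * 0.05, f"s{i}")
                   for i in range(6)]
        moved = [c.copy() for c in configs]
        R = _random_rotation(rng)
        moved[2].coords = moved[2].coords * 2.5 @ R.T + np.array([4.0, -7.0, 1.0])
        d0 = gpa(configs)
        d1 = gpa(moved)
        assert np.linalg.norm(d0.aligned[2] - d1.aligned[2]) < 1e-7

    def test_consensus_invariant_to_specimen_order(self, rng):
        tree = sim_tree(6, 1.0, seed=5)
        configs = sim_landmarks(tree, n_specimens=3, seed=6)
        perm = list(rng.permutation(len(configs)))
        a = gpa(configs)
        b = gpa([configs[i] for i in perm])
        assert np.linalg.norm(a.consensus - b.consensus) < 1e-6

    def test_two_configs_differing_by_similarity_align_exactly(self, rng):
        coords = rng.standard_normal((10, 3))
        R = _random_rotation(rng)
        other = coords * 1.8 @ R.T + 3.0
        ds = gpa([_config(coords, "a"), _config(other, "b")])
        assert np.linalg.norm(ds.aligned[0] - ds.aligned[1]) < 1e-8

    def test_residuals_non_increasing(self, rng):
        tree = sim_tree(8, 1.0, seed=15)
        configs = sim_landmarks(tree, n_specimens=2, evo_sd=0.08, seed=16)
        ds = gpa(configs)
        hist = np.array(ds.residual_history)
        assert np.all(np.diff(hist) <= 1e-10)

    def test_unit_centroid_size_and_centering(self, rng):
        tree = sim_tree(5, 1.0, seed=25)
        ds = gpa(sim_landmarks(tree, n_specimens=2, seed=26))
        for i in range(ds.n_specimens):
            assert np.abs(ds.aligned[i].mean(axis=0)).max() < 1e-9
            assert np.sqrt((ds.aligned[i] ** 2).sum()) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(ds.consensus, ds.aligned.mean(axis=0), atol=1e-6)


class TestProcrustesDistanceMetric:
    def test_symmetry_and_triangle_inequality(self, rng):
        shapes = [rng.standard_normal((8, 3)) for _ in range(6)]
        for a in range(6):
            for b in range(a + 1, 6):
                dab = procrustes_distance(shapes[a], shapes[b])
                dba = procrustes_distance(shapes[b], shapes[a])
                assert dab == pytest.approx(dba, abs=1e-9)
                for c in range(6):
                    if c in (a, b):
                        continue
                    dac = procrustes_distance(shapes[a], shapes[c])
                    dcb = procrustes_distance(shapes[c], shapes[b])
                    assert dab <= dac + dcb + 1e-9


class TestImputation:
    def test_complete_dataset_returned_unchanged(self, rng):
        tree = sim_tree(5, 1.0, seed=35)
        configs = sim_landmarks(tree, n_specimens=2, seed=36)
        ds = impute_missing(configs)
        assert not ds.imputed.any()

    def test_holdout_error_below_one_sd(self):
        """Hide one landmark of a known-complete specimen; the regression
        prediction should land within that landmark's across-specimen
        spread."""
        tree = sim_tree(10, 1.0, seed=45)
        configs = sim_landmarks(tree, n_specimens=4, evo_sd=0.05,
                                noise_sd=0.01, seed=46, random_pose=False)
        target = configs[0]
        hidden = target.copy()
        hidden.coords = hidden.coords.copy()
        hidden.coords[7] = np.nan
        hidden.missing = np.isnan(hidden.coords).any(axis=1)
        ds = impute_missing([hidden] + configs[1:])
        ref = gpa(configs)
        # compare imputed landmark 7 against the truth in aligned space
        err = np.linalg.norm(ds.aligned[0, 7] - ref.aligned[0, 7])
        sd = np.linalg.norm(ref.aligned[1:, 7].std(axis=0))
        assert err < sd

    def test_specimen_with_everything_missing_rejected(self):
        coords = np.full((30, 3), np.nan)
        bad = LandmarkConfiguration("f", "X", "right", coords)
        with pytest.raises(ValueError):
            impute_missing([bad])

    def test_landmark_missing_everywhere_rejected(self, rng):
        tree = sim_tree(4, 1.0, seed=55)
        configs = sim_landmarks(tree, n_specimens=2, seed=56)
        for c in configs:
            c.coords[3] = np.nan
            c.missing = np.isnan(c.coords).any(axis=1)
        with pytest.raises(ValueError):
            impute_missing(configs)
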