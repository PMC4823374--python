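import numpy as np
import pytest

from conftest import random_probmap
from oracles import enumerate_min_energy
from vemseg.classifier import argmax_labeling
from vemseg.crf import (CRFConfig, EnergyInstance, build_energy,
                        default_distance_matrix, labeling_energy, minimize,
                        minimize_binary, minimize_multilabel, regularize_tiled)
from vemseg.volumes import LabelVolume


def make_energy(unary, theta_xy=1.0, theta_z=0.5, dist=None, inf_value=1e9,
                label_ids=None):
    unary = np.asarray(unary, dtype=np.float64)
    n_labels = unary.shape[-1]
    if dist is None:
        dist = default_distance_matrix(n_labels)
    ids = tuple(label_ids) if label_ids else tuple(range(1, n_labels + 1))
    return EnergyInstance(
        unary=unary, label_ids=ids, theta_xy=theta_xy, theta_z=theta_z,
        dist=np.asarray(dist, dtype=np.float64), inf_value=inf_value,
        label_table={i: f"l{i}" for i in ids},
    )


def random_energy(rng, shape=(3, 3, 2), n_labels=2, theta_xy=None, theta_z=None,
                  dist=None):
    unary = rng.uniform(0, 5, size=shape + (n_labels,))
    txy = rng.uniform(0, 2) if theta_xy is None else theta_xy
    tz = rng.uniform(0, 2) if theta_z is None else theta_z
    return make_energy(unary, theta_xy=txy, theta_z=tz, dist=dist)


class TestBuildEnergy:
    def test_unary_is_neg_log_posterior(self):
        rng = np.random.default_rng(0)
        pm = random_probmap((2, 2, 1), 2, rng)
        pm.probs[0, 0, 0] = [1.0, 0.0]
        pm.probs[1, 0, 0] = [0.5, 0.5]
        energy = build_energy(pm, CRFConfig(theta_xy=1.0), rho=2.0)
        assert energy.unary[0, 0, 0, 0] == pytest.approx(0.0)
        assert energy.unary[1, 0, 0, 0] == pytest.approx(np.log(2))
        # zero posterior is floored, not infinite
        assert np.isfinite(energy.unary).all()

    def test_theta_z_defaults_to_anisotropy_rule(self):
        rng = np.random.default_rng(1)
        pm = random_probmap((2, 2, 2), 2, rng)
        energy = build_energy(pm, CRFConfig(theta_xy=4.0), rho=2.0)
        assert energy.theta_z == pytest.approx(2.0)
        override = build_energy(pm, CRFConfig(theta_xy=4.0, theta_z=0.7), rho=2.0)
        assert override.theta_z == pytest.approx(0.7)

    def test_edge_sets_follow_geometry(self):
        # a 2x1x1 stack has exactly one in-plane edge and no Z edge
        unary = np.zeros((2, 1, 1, 2))
        energy = make_energy(unary, theta_xy=3.0, theta_z=100.0)
        mixed = np.array([1, 2]).reshape(2, 1, 1)
        assert labeling_energy(mixed, energy) == pytest.approx(3.0)
        unary_z = np.zeros((1, 1, 2, 2))
        energy_z = make_energy(unary_z, theta_xy=100.0, theta_z=3.0)
        mixed_z = np.array([1, 2]).reshape(1, 1, 2)
        assert labeling_energy(mixed_z, energy_z) == pytest.approx(3.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CRFConfig(theta_xy=-1)
        with pytest.raises(ValueError):
            CRFConfig(distance_matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            CRFConfig(distance_matrix=np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestLabelingEnergy:
    def test_zero_theta_sums_chosen_unaries(self):
        rng = np.random.default_rng(2)
        energy = random_energy(rng, shape=(3, 2, 2), theta_xy=0.0, theta_z=0.0)
        labels = rng.integers(1, 3, size=(3, 2, 2))
        expected = sum(
            energy.unary[x, y, z, labels[x, y, z] - 1]
            for x in range(3) for y in range(2) for z in range(2)
        )
        assert labeling_energy(labels, energy) == pytest.approx(expected)

    def test_uniform_labeling_has_no_pairwise_cost(self):
        rng = np.random.default_rng(3)
        energy = random_energy(rng, theta_xy=5.0, theta_z=5.0)
        uniform = np.full(energy.shape, 1)
        unary_only = labeling_energy(uniform, energy)
        assert unary_only == pytest.approx(float(energy.unary[..., 0].sum()))

    def test_two_voxel_hand_example(self):
        # voxels x labels unaries [[1,3],[4,0]], theta_xy=2, Potts distance
        unary = np.array([[1.0, 3.0], [4.0, 0.0]]).reshape(2, 1, 1, 2)
        energy = make_energy(unary, theta_xy=2.0, theta_z=0.0)
        assert labeling_energy(np.array([1, 2]).reshape(2, 1, 1), energy) == pytest.approx(3.0)
        best, argbest = enumerate_min_energy(energy)
        assert best == pytest.approx(3.0)
        np.testing.assert_array_equal(argbest.ravel(), [1, 2])


class TestMinimizeBinary:
    def test_zero_theta_reproduces_argmax(self):
        rng = np.random.default_rng(4)
        pm = random_probmap((4, 4, 3), 2, rng)
        energy = build_energy(pm, CRFConfig(theta_xy=0.0, theta_z=0.0), rho=1.0)
        out = minimize_binary(energy)
        np.testing.assert_array_equal(out.labels, argmax_labeling(pm).labels)

    @pytest.mark.parametrize("seed", range(25))
    def test_global_optimality_vs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        energy = random_energy(rng, shape=(3, 3, 2))
        out = minimize_binary(energy)
        best, _ = enumerate_min_energy(energy)
        assert labeling_energy(out, energy) == pytest.approx(best, abs=1e-4)

    def test_huge_theta_forces_cheapest_uniform_labeling(self):
        rng = np.random.default_rng(99)
        energy = random_energy(rng, shape=(3, 3, 2), theta_xy=1e4, theta_z=1e4)
        out = minimize_binary(energy)
        assert len(np.unique(out.labels)) == 1
        totals = [float(energy.unary[..., j].sum()) for j in range(2)]
        assert out.labels.ravel()[0] == 1 + int(np.argmin(totals))

    def test_requires_two_labels(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="2 labels"):
            minimize_binary(random_energy(rng, n_labels=3))


class TestAlphaBetaSwap:
    def test_two_label_instance_matches_exact_cut(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            energy = random_energy(rng, shape=(4, 3, 2))
            exact = labeling_energy(minimize_binary(energy), energy)
            swap = labeling_energy(minimize_multilabel(energy), energy)
            assert swap == pytest.approx(exact, abs=1e-4)

    def test_energy_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(6)
        energy = random_energy(rng, shape=(5, 5, 3), n_labels=3)
        _, trace = minimize_multilabel(energy, return_trace=True)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_energy_never_exceeds_argmax_initialization(self):
        rng = np.random.default_rng(7)
        energy = random_energy(rng, shape=(5, 4, 2), n_labels=3)
        init = np.asarray(energy.label_ids)[np.argmin(energy.unary, axis=-1)]
        out = minimize_multilabel(energy)
        assert labeling_energy(out, energy) <= labeling_energy(init, energy) + 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_forbidden_pair_never_adjacent(self, seed):
        rng = np.random.default_rng(seed)
        dist = default_distance_matrix(3, [(1, 2)])  # syn-mit style exclusion
        energy = random_energy(rng, shape=(4, 4, 2), n_labels=3, dist=dist)
        out = minimize_multilabel(energy).labels
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            a, b = out[tuple(lo)], out[tuple(hi)]
            assert not np.any((a == 2) & (b == 3))
            assert not np.any((a == 3) & (b == 2))

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(8)
        energy = random_energy(rng, shape=(4, 4, 2), n_labels=3)
        out = minimize_multilabel(energy)
        again = minimize_multilabel(energy, init=out)
        np.testing.assert_array_equal(out.labels, again.labels)


def blobs_probmap(shape, rng, centers, radius=4, p_in=0.97, jitter=0.015):
    """Synthetic 3-label posterior: confident blobs on background with noise.

    Blob centers are kept away from tile cut planes by the caller.
    """
    x, y, z = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    labels = np.ones(shape, dtype=np.int64)
    for (cx, cy, cz), lab in centers:
        inside = (x - cx) ** 2 + (y - cy) ** 2 + ((z - cz) * 2) ** 2 <= radius**2
        labels[inside] = lab
    probs = np.full(shape + (3,), (1 - p_in) / 2)
    for j in range(3):
        probs[labels == j + 1, j] = p_in
    probs = np.clip(probs + rng.uniform(-jitter, jitter, probs.shape), 1e-6, None)
    probs /= probs.sum(axis=-1, keepdims=True)
    from vemseg.classifier import ProbabilityMap

    return ProbabilityMap(probs, (1, 2, 3), {1: "bg", 2: "syn", 3: "mit"}), labels


class TestTiledRegularization:
    def test_single_tile_equals_untiled(self):
        rng = np.random.default_rng(9)
        pm = random_probmap((6, 5, 4), 3, rng)
        config = CRFConfig(theta_xy=1.0, theta_z=0.5, tile_shape=(64, 64, 64), margin=10)
        tiled = regularize_tiled(pm, config, rho=2.0)
        untiled = minimize(build_energy(pm, config, rho=2.0))
        np.testing.assert_array_equal(tiled.labels, untiled.labels)

    def test_margin_recovers_untiled_result_away_from_cuts(self):
        # objects >= 12 voxels from the cut plane at x=32; margin 10
        rng = np.random.default_rng(10)
        shape = (64, 32, 16)
        pm, _ = blobs_probmap(shape, rng, [((14, 16, 8), 3), ((50, 12, 6), 2)])
        config = CRFConfig(theta_xy=1.0, tile_shape=(32, 32, 16), margin=10)
        tiled = regularize_tiled(pm, config, rho=2.0)
        untiled = minimize(build_energy(pm, config, rho=2.0))
        np.testing.assert_array_equal(tiled.labels, untiled.labels)

    def test_margin_prevents_seam_artifacts_for_straddling_object(self):
        from scipy import ndimage

        rng = np.random.default_rng(11)
        shape = (64, 32, 16)
        # one object straddling the cut plane at x=32
        pm, gt = blobs_probmap(shape, rng, [((32, 16, 8), 3)], radius=6)
        untiled = minimize(build_energy(pm, CRFConfig(theta_xy=1.0), rho=2.0))
        config = CRFConfig(theta_xy=1.0, tile_shape=(32, 32, 16), margin=10)
        tiled = regularize_tiled(pm, config, rho=2.0)
        # the object's run across the cut plane is preserved
        s = ndimage.generate_binary_structure(3, 1)
        _, n_untiled = ndimage.label(untiled.labels == 3, structure=s)
        _, n_tiled = ndimage.label(tiled.labels == 3, structure=s)
        assert n_tiled == n_untiled
        np.testing.assert_array_equal(tiled.labels, untiled.labels)
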