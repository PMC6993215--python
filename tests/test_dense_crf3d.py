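"""CRF kernels, exact energy oracle, mean-field refinement behavior."""

import itertools

import numpy as np
import pytest

from mpsseg import (
    CRFParams,
    appearance_kernel,
    crf_energy,
    mean_field_refine,
    smoothness_kernel,
)
from mpsseg.dense_crf3d import VoxelFeature


def random_instance(rng, shape=(4, 5, 5), C=4, intensity_scale=20.0):
    V = int(np.prod(shape))
    p = rng.dirichlet(np.ones(C), size=V).T.reshape((C,) + shape)
    feats = rng.normal(0, intensity_scale, size=(4,) + shape)
    return p, feats


class TestKernels:
    def test_identical_features_give_one(self):
        a = VoxelFeature((3, 4, 5), (1.0, 2.0, 3.0, 4.0))
        assert smoothness_kernel(a, a, CRFParams()) == 1.0
        assert appearance_kernel(a, a, CRFParams()) == 1.0

    def test_smoothness_closed_forms(self):
        params = CRFParams()
        a = VoxelFeature((0, 0, 0), (0, 0, 0, 0))
        b = VoxelFeature((24, 0, 0), (0, 0, 0, 0))
        c = VoxelFeature((24, 24, 24), (0, 0, 0, 0))
        assert smoothness_kernel(a, b, params) == pytest.approx(np.exp(-1), rel=1e-12)
        assert smoothness_kernel(a, c, params) == pytest.approx(np.exp(-3), rel=1e-12)

    def test_appearance_closed_forms(self):
        params = CRFParams()
        a = VoxelFeature((0, 0, 0), (0, 0, 0, 0))
        b = VoxelFeature((17, 0, 0), (0, 0, 0, 0))  # one sigma_beta_x apart
        c = VoxelFeature((0, 0, 0), (8, 0, 0, 0))  # one sigma_gamma apart
        assert appearance_kernel(a, b, params) == pytest.approx(np.exp(-1), rel=1e-12)
        assert appearance_kernel(a, c, params) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_symmetry_and_bounds(self, rng):
        params = CRFParams()
        for _ in range(20):
            a = VoxelFeature(tuple(rng.uniform(0, 30, 3)), tuple(rng.normal(0, 20, 4)))
            b = VoxelFeature(tuple(rng.uniform(0, 30, 3)), tuple(rng.normal(0, 20, 4)))
            for k in (smoothness_kernel, appearance_kernel):
                v1, v2 = k(a, b, params), k(b, a, params)
                assert v1 == pytest.approx(v2, rel=1e-12)
                assert 0.0 < v1 <= 1.0

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            CRFParams(sigma_gamma=0.0)


class TestEnergyOracle:
    def test_zero_pairwise_weights_leave_unary_only(self, rng):
        p, feats = random_instance(rng, shape=(3, 3, 3))
        labels = p.argmax(axis=0)
        params = CRFParams(omega1=0.0, omega2=0.0)
        expect = -np.log(np.take_along_axis(
            p.reshape(4, -1), labels.reshape(1, -1), axis=0)).sum()
        assert crf_energy(labels, p, feats, params) == pytest.approx(expect, rel=1e-10)

    def test_uniform_labeling_has_zero_pairwise_term(self, rng):
        p, feats = random_instance(rng, shape=(3, 3, 3))
        labels = np.zeros((3, 3, 3), dtype=int)
        e_with = crf_energy(labels, p, feats, CRFParams())
        e_without = crf_energy(labels, p, feats, CRFParams(omega1=1e-12, omega2=1e-12))
        assert e_with == pytest.approx(e_without, rel=1e-9)

    def test_matches_literal_double_loop(self, rng):
        p, feats = random_instance(rng, shape=(2, 3, 2))
        labels = rng.integers(0, 4, size=(2, 3, 2))
        params = CRFParams()
        # independent re-implementation: explicit python loop over pairs
        coords = list(np.ndindex(*labels.shape))
        expect = sum(-np.log(p[(labels[c],) + c]) for c in coords)
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                ci, cj = coords[i], coords[j]
                if labels[ci] != labels[cj]:
                    a = VoxelFeature(ci, tuple(feats[(k,) + ci] for k in range(4)))
                    b = VoxelFeature(cj, tuple(feats[(k,) + cj] for k in range(4)))
                    expect += params.omega1 * smoothness_kernel(a, b, params)
                    expect += params.omega2 * appearance_kernel(a, b, params)
        assert crf_energy(labels, p, feats, params) == pytest.approx(expect, abs=1e-8)

    def test_exhaustive_enumeration_confirms_minimum(self, rng):
        p, feats = random_instance(rng, shape=(2, 2, 1), C=2)
        params = CRFParams()
        energies = {
            l: crf_energy(np.array(l).reshape(2, 2, 1), p, feats, params)
            for l in itertools.product([0, 1], repeat=4)
        }
        best = min(energies.values())
        uniform0 = energies[(0, 0, 0, 0)]
        uniform1 = energies[(1, 1, 1, 1)]
        assert best <= uniform0 and best <= uniform1
        assert best > 0

    def test_size_cap_enforced(self, rng):
        p, feats = random_instance(rng, shape=(20, 20, 20))
        with pytest.raises(ValueError, match="energy oracle too large"):
            crf_energy(p.argmax(axis=0), p, feats, CRFParams())


class TestMeanField:
    def test_zero_weights_return_unary_argmax_exactly(self, rng):
        p, feats = random_instance(rng, shape=(3, 4, 3))
        params = CRFParams(omega1=0.0, omega2=0.0)
        Q, lab = mean_field_refine(p, feats, params)
        assert np.array_equal(lab.to_class_indices(), p.argmax(axis=0))

    def test_deterministic(self, rng):
        p, feats = random_instance(rng, shape=(4, 4, 4))
        Q1, l1 = mean_field_refine(p, feats, CRFParams(), mode="dense")
        Q2, l2 = mean_field_refine(p, feats, CRFParams(), mode="dense")
        assert np.array_equal(Q1, Q2)
        assert np.array_equal(l1.labels, l2.labels)

    def test_posterior_stays_on_simplex(self, rng):
        p, feats = random_instance(rng, shape=(4, 4, 4))
        Q, _ = mean_field_refine(p, feats, CRFParams(n_iterations=3), mode="dense")
        assert np.allclose(Q.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(Q >= 0)

    def test_refinement_does_not_increase_energy(self, rng):
        params = CRFParams()
        for seed in range(5):
            r = np.random.default_rng(seed)
            p, feats = random_instance(r, shape=(4, 5, 5))
            Q, lab = mean_field_refine(p, feats, params, mode="dense")
            e_ref = crf_energy(lab.to_class_indices(), p, feats, params)
            e_arg = crf_energy(p.argmax(axis=0), p, feats, params)
            assert e_ref <= e_arg + 1e-9

    def test_isolated_weak_voxel_removed(self):
        shape = (7, 7, 7)
        p = np.zeros((4,) + shape)
        p[0] = 0.95
        p[1:] = 0.05 / 3
        p[:, 3, 3, 3] = [0.45, 0.0, 0.0, 0.55]  # weak isolated foreground voxel
        feats = np.zeros((4,) + shape)  # homogeneous intensities
        _, lab = mean_field_refine(p, feats, CRFParams(), mode="dense")
        assert lab.labels[3, 3, 3] == 0
        assert np.all(lab.labels == 0)

    def test_confident_homogeneous_region_unchanged(self):
        # a large confident foreground block keeps its labels
        shape = (6, 6, 6)
        p = np.zeros((4,) + shape)
        p[0] = 0.98
        p[1:] = 0.02 / 3
        block = (slice(1, 5), slice(1, 5), slice(1, 5))
        p[0][block] = 0.02 / 3 * 0  # reset
        p[:, 1:5, 1:5, 1:5] = 0.0
        p[2, 1:5, 1:5, 1:5] = 0.98
        p[0, 1:5, 1:5, 1:5] = 0.02
        # renormalize safety
        p /= p.sum(axis=0, keepdims=True)
        feats = np.zeros((4,) + shape)
        feats[:, 1:5, 1:5, 1:5] = 60.0  # intensity-distinct block
        _, lab = mean_field_refine(p, feats, CRFParams(), mode="dense")
        assert np.all(lab.labels[2:4, 2:4, 2:4] == 2)

    def test_filtered_path_agrees_with_dense_on_labels(self, rng):
        # moderate smoothing so both paths keep the dominant structure
        shape = (6, 6, 6)
        classes = np.zeros(shape, dtype=int)
        classes[2:5, 2:5, 2:5] = 2
        p = np.stack([(classes == c) * 0.9 + 0.1 / 4 for c in range(4)])
        p /= p.sum(axis=0, keepdims=True)
        feats = np.where(classes[None] > 0, 60.0, 0.0) * np.ones((4, 1, 1, 1))
        params = CRFParams(sigma_alpha=(3, 3, 3), sigma_beta=(3, 3, 3),
                           n_iterations=3, n_codewords=2)
        _, l_filtered = mean_field_refine(p, feats, params, mode="filtered")
        agree = (l_filtered.to_class_indices() == classes).mean()
        assert agree >= 0.95

    def test_unnormalized_input_rejected(self, rng):
        p, feats = random_instance(rng, shape=(3, 3, 3))
        with pytest.raises(ValueError, match="not normalized"):
            mean_field_refine(p * 2.0, feats, CRFParams())
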