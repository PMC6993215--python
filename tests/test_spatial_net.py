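"""Pooling/unpooling contracts, forward properties, gradients, inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpsseg import (
    LossConfig,
    NetworkConfig,
    SpatialSegNet,
    spatial_max_pool,
    spatial_max_unpool,
)
from mpsseg.spatial_net import TrainConfig, predict_slices, predict_volume

SMALL = NetworkConfig(depth=2, base_filters=4)


class TestSpatialPooling:
    def test_simple_window(self):
        y, idx = spatial_max_pool(np.array([[1.0, 3.0], [2.0, 0.0]]), 2)
        assert y[0, 0] == 3.0
        assert divmod(int(idx[0, 0]), 2) == (0, 1)

    def test_constant_window_tie_breaks_first(self):
        y, idx = spatial_max_pool(np.full((2, 2), 5.0), 2)
        assert y[0, 0] == 5.0
        assert divmod(int(idx[0, 0]), 2) == (0, 0)

    def test_matches_brute_force_window_max(self, rng):
        x = rng.uniform(0, 1, size=(3, 8, 8))
        y, _ = spatial_max_pool(x, 2)
        for i in range(4):
            for j in range(4):
                expect = x[:, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max(axis=(1, 2))
                assert np.array_equal(y[:, i, j], expect)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError, match="not divisible"):
            spatial_max_pool(rng.normal(size=(3, 7, 8)), 2)

    def test_unpool_places_value_at_recorded_position(self):
        out = spatial_max_unpool(np.array([[3.0]]), np.array([[1]]), (2, 2))
        assert np.array_equal(out, [[0.0, 3.0], [0.0, 0.0]])

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_contracts(self, seed):
        # nonnegative maps model post-ReLU activations, the pooling domain
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.01, 1.0, size=(2, 3, 8, 8))
        y, idx = spatial_max_pool(x, 2)
        up = spatial_max_unpool(y, idx, (8, 8))
        # nonzero exactly at argmax positions, with the pooled values
        assert np.count_nonzero(up) == y.size
        assert np.array_equal(np.sort(up[up != 0]), np.sort(y.ravel()))
        y2, idx2 = spatial_max_pool(up, 2)
        assert np.array_equal(y2, y)
        assert np.array_equal(idx2, idx)

    def test_unpool_shape_mismatch_rejected(self, rng):
        y, idx = spatial_max_pool(rng.uniform(0, 1, (2, 4, 4)), 2)
        with pytest.raises(ValueError, match="does not match"):
            spatial_max_unpool(y, idx[:1], (4, 4))


class TestForward:
    def test_probabilities_normalized(self, rng):
        net = SpatialSegNet(SMALL, seed=0)
        x = rng.normal(size=(2, 4, 16, 16)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (2, 4, 16, 16)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(p >= 0)

    def test_output_shape_equals_input_shape(self, rng):
        net = SpatialSegNet(SMALL, seed=0)
        for hw in ((16, 16), (16, 24), (32, 16)):
            x = rng.normal(size=(1, 4) + hw).astype(np.float32)
            assert net.forward(x).shape == (1, 4) + hw

    def test_inference_determinism(self, rng):
        net = SpatialSegNet(SMALL, seed=0)
        x = rng.normal(size=(1, 4, 16, 16)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_non_divisible_input_rejected(self, rng):
        net = SpatialSegNet(SMALL, seed=0)
        with pytest.raises(ValueError, match="not divisible"):
            net.forward(rng.normal(size=(1, 4, 18, 18)))

    def test_padded_slice_inference_handles_any_size(self, rng):
        net = SpatialSegNet(SMALL, seed=0)
        x = rng.normal(size=(2, 4, 18, 21)).astype(np.float32)
        p = predict_slices(net, x)
        assert p.shape == (2, 4, 18, 21)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_flip_equivariance_with_flip_symmetric_parameters(self, rng):
        # constant (flip-symmetric) filters: flipping the input must flip
        # the output; not asserted for general learned parameters
        net = SpatialSegNet(NetworkConfig(depth=1, base_filters=2), seed=0)
        for k, v in net.params.items():
            net.params[k] = np.full_like(v, 0.01)
        x = rng.uniform(0, 1, size=(1, 4, 8, 8)).astype(np.float32)
        p = net.forward(x)
        pf = net.forward(x[:, :, :, ::-1].copy())
        assert np.allclose(pf, p[:, :, :, ::-1], atol=1e-5)


class TestGradients:
    def test_parameter_gradients_match_finite_difference(self, rng):
        net = SpatialSegNet(NetworkConfig(depth=2, base_filters=2), seed=0)
        # float64 and nonzero biases: at exactly-zero biases whole dead
        # regions sit on the ReLU kink and finite differences are one-sided
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
            if k.endswith("_b"):
                net.params[k] = rng.normal(0, 0.05, net.params[k].shape)
        x = rng.normal(size=(2, 4, 8, 8))
        lab = rng.integers(0, 4, (2, 8, 8))
        G = np.stack([(lab == c).astype(float) for c in range(4)], axis=1)
        cfg = LossConfig()
        _, grads = net.loss_and_grads(x, G, cfg)
        worst = 0.0
        for k in ("enc0a_W", "enc1b_W", "botb_W", "dec1a_W", "dec0b_b", "head_W"):
            W = net.params[k]
            flat = W.ravel()
            for fi in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                h = 1e-6
                orig = float(flat[fi])
                flat[fi] = orig + h
                lp, _ = net.loss_and_grads(x, G, cfg)
                flat[fi] = orig - h
                lm, _ = net.loss_and_grads(x, G, cfg)
                flat[fi] = orig
                num = (lp - lm) / (2 * h)
                worst = max(worst, abs(num - grads[k].ravel()[fi]) / max(abs(num), 1e-6))
        assert worst < 1e-4


class TestTrainingAndInference:
    def test_one_step_reduces_loss_on_tiny_problem(self, rng):
        net = SpatialSegNet(NetworkConfig(depth=1, base_filters=4), seed=1)
        x = rng.normal(size=(4, 4, 8, 8)).astype(np.float32)
        lab = (x[:, 3] > 0).astype(int)  # learn a thresholding of channel 3
        G = np.stack([(lab == c).astype(np.float32) for c in range(4)], axis=1)
        cfg = LossConfig()
        tc = TrainConfig(learning_rate=1e-2)
        l0, grads = net.loss_and_grads(x, G, cfg)
        for _ in range(30):
            _, grads = net.loss_and_grads(x, G, cfg)
            net.adam_step(grads, tc)
        l1, _ = net.loss_and_grads(x, G, cfg)
        assert l1 < l0 * 0.8

    def test_predict_volume_is_normalized_axial_map(self, small_phantom):
        from mpsseg import standardize

        vol, _, _ = small_phantom
        net = SpatialSegNet(SMALL, seed=0)
        p = predict_volume(standardize(vol), "sagittal", net)
        assert p.shape == (4,) + vol.shape
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-4)

    def test_save_load_round_trip(self, rng, tmp_path):
        net = SpatialSegNet(SMALL, seed=3)
        path = str(tmp_path / "net.npz")
        net.save(path)
        net2 = SpatialSegNet.load(path)
        x = rng.normal(size=(1, 4, 16, 16)).astype(np.float32)
        assert np.array_equal(net.forward(x), net2.forward(x))
        assert net2.cfg == net.cfg
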