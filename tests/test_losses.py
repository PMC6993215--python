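"""Loss identities, closed forms, monotonicity, and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpsseg import (
    LossConfig,
    adaptive_weights,
    aggregated_loss,
    focal_loss,
    static_weights_from_frequencies,
    wgdl,
    wll,
)
from mpsseg.losses import compute_loss


def random_instance(rng, C=4, N=20, one_hot_P=False):
    G = np.eye(C)[rng.integers(0, C, N)].T
    if one_hot_P:
        P = np.eye(C)[rng.integers(0, C, N)].T
    else:
        P = rng.dirichlet(np.ones(C), size=N).T
    return P, G


class TestAdaptiveWeights:
    def test_inverse_square_of_class_volume(self):
        G = np.zeros((4, 111))
        G[0, :100] = 1
        G[1, 100:110] = 1
        G[2, 110:111] = 1
        wa = adaptive_weights(G)
        assert wa[1] == pytest.approx(0.01, rel=1e-4)
        assert wa[2] == pytest.approx(1.0, rel=1e-4)
        assert wa[1] / wa[0] == pytest.approx(100.0, rel=1e-3)  # volumes 10 vs 100

    def test_absent_class_gets_epsilon_guard(self):
        G = np.zeros((4, 5))
        G[0] = 1
        wa = adaptive_weights(G, epsilon=1e-6)
        assert wa[1] == pytest.approx(1e12, rel=1e-3)


class TestWgdl:
    def test_perfect_prediction_is_zero(self, rng):
        for _ in range(20):
            P, G = random_instance(rng)
            # ensure every class appears so the epsilon guard is negligible
            G[:, :4] = np.eye(4)
            assert wgdl(G, G) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_prediction_is_one(self, rng):
        G = np.eye(2)[np.zeros(8, dtype=int)].T  # all class 0
        P = np.eye(2)[np.ones(8, dtype=int)].T  # all class 1
        assert wgdl(P, G) == pytest.approx(1.0, abs=1e-6)

    def test_hand_evaluated_binary_example(self):
        # 8 pixels, 2 classes, 4 foreground; P == G then flip one foreground pixel
        G = np.zeros((2, 8))
        G[1, :4] = 1
        G[0, 4:] = 1
        assert wgdl(G, G) == pytest.approx(0.0, abs=1e-6)
        P = G.copy()
        P[:, 0] = [1.0, 0.0]  # one foreground pixel predicted background
        # independent scalar evaluation of the weighted generalized Dice formula
        eps = 1e-6
        wa = 1.0 / (G.sum(axis=1) + eps) ** 2
        num = 2 * sum(wa[c] * np.dot(G[c], P[c]) for c in range(2))
        den = sum(wa[c] * (G[c] + P[c]).sum() for c in range(2))
        expected = 1 - num / den
        assert wgdl(P, G) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_on_random_simplex(self, seed):
        rng = np.random.default_rng(seed)
        P, G = random_instance(rng)
        assert 0.0 <= wgdl(P, G) <= 1.0


class TestWll:
    def test_perfect_prediction_is_zero(self, rng):
        P, G = random_instance(rng, one_hot_P=True)
        assert wll(G, G) == pytest.approx(0.0, abs=1e-5)

    def test_single_pixel_closed_form(self):
        G = np.array([[0.0], [1.0]])
        P = np.array([[0.5], [0.5]])
        assert wll(P, G, LossConfig(static_weights=[1, 1, 1, 1][:2])) == \
            pytest.approx(-np.log(0.5), rel=1e-5)

    def test_linear_in_static_weights(self, rng):
        P, G = random_instance(rng)
        w1 = LossConfig(static_weights=[1.0, 1.0, 1.0, 1.0])
        w2 = LossConfig(static_weights=[2.0, 2.0, 2.0, 2.0])
        assert wll(P, G, w2) == pytest.approx(2 * wll(P, G, w1), rel=1e-12)


class TestAggregated:
    def test_reductions(self, rng):
        P, G = random_instance(rng)
        cfg_d = LossConfig(combine_weights=(1.0, 0.0))
        cfg_l = LossConfig(combine_weights=(0.0, 1.0))
        assert aggregated_loss(P, G, cfg_d) == wgdl(P, G, cfg_d)
        assert aggregated_loss(P, G, cfg_l) == wll(P, G, cfg_l)

    def test_perfect_prediction_is_zero(self, rng):
        _, G = random_instance(rng)
        G[:, :4] = np.eye(4)
        assert aggregated_loss(G, G) == pytest.approx(0.0, abs=1e-5)

    def test_degenerate_combination_rejected(self, rng):
        P, G = random_instance(rng)
        with pytest.raises(ValueError, match="degenerate loss"):
            aggregated_loss(P, G, LossConfig(combine_weights=(0.0, 0.0)))


class TestFocal:
    def test_gamma_zero_equals_unit_weight_log_loss(self, rng):
        P, G = random_instance(rng)
        cfg = LossConfig(focal_gamma=0.0, static_weights=np.ones(4))
        assert focal_loss(P, G, cfg) == pytest.approx(wll(P, G, cfg), abs=1e-12)

    def test_perfect_prediction_is_zero(self, rng):
        P, G = random_instance(rng, one_hot_P=True)
        assert focal_loss(G, G) == pytest.approx(0.0, abs=1e-6)

    def test_single_pixel_closed_form(self):
        G = np.array([[0.0], [1.0]])
        P = np.array([[0.1], [0.9]])
        expected = 0.01 * -np.log(0.9 + 1e-6)
        assert focal_loss(P, G) == pytest.approx(expected, rel=1e-4)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            LossConfig(focal_gamma=-1.0)


class TestMonotonicity:
    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mass_away_from_truth_never_decreases_loss(self, seed):
        rng = np.random.default_rng(seed)
        P, G = random_instance(rng, N=12)
        n = int(rng.integers(0, 12))
        true_c = int(G[:, n].argmax())
        other = (true_c + 1) % 4
        P2 = P.copy()
        delta = P2[true_c, n] * 0.5
        P2[true_c, n] -= delta
        P2[other, n] += delta
        for fn in (wll, wgdl):
            assert fn(P2, G) >= fn(P, G) - 1e-12


class TestGradients:
    @pytest.mark.parametrize("variant", ["aggregated", "dice_weighted",
                                         "log_weighted", "focal"])
    def test_analytic_matches_finite_difference(self, variant, rng):
        P, G = random_instance(rng, N=10)
        cfg = LossConfig(variant=variant, static_weights=[0.5, 1.0, 2.0, 1.5])
        _, dP = compute_loss(P, G, cfg, grad=True)
        num = np.zeros_like(P)
        h = 1e-7
        for c in range(4):
            for n in range(10):
                Pp, Pm = P.copy(), P.copy()
                Pp[c, n] += h
                Pm[c, n] -= h
                num[c, n] = (compute_loss(Pp, G, cfg) - compute_loss(Pm, G, cfg)) / (2 * h)
        scale = max(np.abs(num).max(), 1e-9)
        assert np.abs(dP - num).max() / scale < 1e-4


def test_static_weights_inverse_frequency_mean_one():
    w = static_weights_from_frequencies(np.array([980, 10, 5, 5]))
    assert w.mean() == pytest.approx(1.0)
    assert w[0] < w[1] < w[2] == w[3]
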