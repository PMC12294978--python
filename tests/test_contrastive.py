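"""Multiscale InfoNCE: pooling, closed forms, oracle equivalence, annealing."""

import math

import numpy as np
import pytest

from stereoddi import autodiff as ad
from stereoddi.autodiff import Tensor
from stereoddi.contrastive import (ContrastiveConfig, ContrastiveState,
                                   contrastive_weight, infonce_scale_loss,
                                   l2_normalize, multiscale_loss, scale_pool,
                                   scale_weights, similarity_matrix,
                                   total_loss)
from stereoddi.nn import AdamW


def infonce_loop_oracle(v1: np.ndarray, v2: np.ndarray, tau: float,
                        s: int) -> float:
    """Per-sample double-loop recomputation of the scale-s InfoNCE loss."""
    def pool(f):
        return f.reshape(-1, s).mean(axis=1)

    def norm(f):
        n = np.linalg.norm(f)
        return f / n if n else f

    f1 = np.array([norm(pool(r)) for r in v1])
    f2 = np.array([norm(pool(r)) for r in v2])
    n = len(f1)
    total = 0.0
    for i in range(n):
        pos = math.exp(f1[i] @ f2[i] / tau)
        denom = pos
        for j in range(n):
            if j != i:
                denom += math.exp(f1[i] @ f1[j] / tau)
                denom += math.exp(f1[i] @ f2[j] / tau)
        total += -math.log(pos / denom)
    return total / n


class TestScalePool:
    def test_scale_one_is_identity(self, rng):
        f = rng.normal(size=8)
        assert np.array_equal(scale_pool(f, 1).data, f)

    def test_window_means(self):
        f = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(scale_pool(f, 2).data, [1.5, 3.5])
        assert np.allclose(scale_pool(f, 4).data, [2.5])

    def test_matrix_input_pools_rows(self, rng):
        f = rng.normal(size=(3, 8))
        out = scale_pool(f, 2)
        assert out.shape == (3, 4)
        assert np.allclose(out.data[1], f[1].reshape(4, 2).mean(axis=1))

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            scale_pool(np.zeros(6), 4)


class TestNormalizeAndSimilarity:
    def test_three_four_five(self):
        assert np.allclose(l2_normalize(np.array([3.0, 4.0])).data,
                           [0.6, 0.8])

    def test_unit_vector_unchanged(self):
        v = np.array([0.0, 1.0, 0.0])
        assert np.allclose(l2_normalize(v).data, v)

    def test_unit_norm_rows(self, rng):
        out = l2_normalize(rng.normal(size=(5, 7))).data
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-7)

    def test_zero_vector_passes_through(self):
        assert np.array_equal(l2_normalize(np.zeros(4)).data, np.zeros(4))

    def test_identity_rows_unit_tau(self):
        f = np.eye(3)
        assert np.allclose(similarity_matrix(f, f, 1.0).data, np.eye(3))

    def test_halving_tau_doubles_entries(self, rng):
        f1 = l2_normalize(rng.normal(size=(4, 6))).data
        f2 = l2_normalize(rng.normal(size=(4, 6))).data
        assert np.allclose(similarity_matrix(f1, f2, 0.5).data,
                           2 * similarity_matrix(f1, f2, 1.0).data)

    def test_against_per_entry_cosine_loop(self, rng):
        f1 = l2_normalize(rng.normal(size=(2, 5))).data
        f2 = l2_normalize(rng.normal(size=(2, 5))).data
        s = similarity_matrix(f1, f2, 0.7).data
        for i in range(2):
            for j in range(2):
                assert np.isclose(s[i, j], f1[i] @ f2[j] / 0.7, atol=1e-12)


class TestInfoNCE:
    def test_single_pair_loss_is_zero(self, rng):
        v = rng.normal(size=(1, 8))
        loss = infonce_scale_loss(v, v.copy(), 1.0, 1)
        assert np.isclose(float(loss.data), 0.0, atol=1e-12)

    def test_two_pair_orthogonal_closed_form(self):
        """Positive aligned, all negatives orthogonal, tau = 1:
        loss = -log(e / (e + 2)) = 0.549306."""
        v1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = infonce_scale_loss(v1, v1.copy(), 1.0, 1)
        expected = -math.log(math.e / (math.e + 2.0))  # = 0.551444
        assert np.isclose(float(loss.data), expected, atol=1e-5)
        assert np.isclose(float(loss.data),
                          infonce_loop_oracle(v1, v1.copy(), 1.0, 1),
                          atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_vectorized_matches_double_loop_oracle(self, n, s, rng):
        v1 = rng.normal(size=(n, 16))
        v2 = rng.normal(size=(n, 16))
        tau = 0.6
        vec = float(infonce_scale_loss(v1, v2, tau, s).data)
        assert np.isclose(vec, infonce_loop_oracle(v1, v2, tau, s), atol=1e-6)

    def test_nonnegative_and_vanishes_when_aligned(self, rng):
        v = rng.normal(size=(4, 8))
        assert float(infonce_scale_loss(v, rng.normal(size=(4, 8)),
                                        1.0, 1).data) >= 0.0
        # positives identical, negatives orthogonal, sharp temperature
        v1 = np.eye(4)
        assert float(infonce_scale_loss(v1, v1.copy(), 0.01, 1).data) < 1e-10


class TestWeightsAndSchedule:
    def test_equal_logits_one_third(self):
        w = scale_weights(np.zeros(3)).data
        assert np.allclose(w, 1.0 / 3.0)

    def test_log2_logit_closed_form(self):
        w = scale_weights(np.array([math.log(2.0), 0.0, 0.0])).data
        assert np.allclose(w, [0.5, 0.25, 0.25], atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        w = scale_weights(rng.normal(size=3)).data
        assert np.isclose(w.sum(), 1.0, atol=1e-7)
        assert (w >= 0).all()

    def test_multiscale_combination(self, rng):
        losses = [Tensor(np.array(x)) for x in (0.5, 0.5, 0.5)]
        assert np.isclose(float(multiscale_loss(losses,
                                                np.ones(3) / 3).data), 0.5)
        one_hot = np.array([0.0, 1.0, 0.0])
        losses = [Tensor(np.array(x)) for x in (1.0, 2.0, 3.0)]
        assert np.isclose(float(multiscale_loss(losses, one_hot).data), 2.0)
        w = scale_weights(rng.normal(size=3)).data
        expected = sum(wi * li.data for wi, li in zip(w, losses))
        assert np.isclose(float(multiscale_loss(losses, w).data), expected)

    def test_annealing_endpoints_and_midpoint(self):
        assert contrastive_weight(0) == pytest.approx(0.1)
        assert contrastive_weight(500) == 0.0
        assert contrastive_weight(250) == pytest.approx(0.05)
        assert contrastive_weight(900) == 0.0  # clamped past T

    def test_annealing_strictly_decreasing_on_window(self):
        vals = [contrastive_weight(t) for t in range(0, 501, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_total_loss_assembly(self):
        assert float(total_loss(1.0, 2.0, 0).data) == pytest.approx(1.2)
        assert float(total_loss(1.0, 2.0, 500).data) == pytest.approx(1.0)
        assert float(total_loss(1.0, 0.0, 100).data) == pytest.approx(1.0)


class TestTemperature:
    def test_tau_initial_value_inside_bounds(self):
        state = ContrastiveState(ContrastiveConfig())
        tau = float(state.tau().data[0])
        assert 0.1 < tau < 2.0

    def test_tau_never_escapes_bounds_under_optimization(self, rng):
        """100 adversarial gradient steps pushing tau out of range."""
        state = ContrastiveState(ContrastiveConfig())
        opt = AdamW(state.parameters(), lr=0.5, weight_decay=0.0)
        for step in range(100):
            tau = state.tau()
            # alternate pushing tau up and down as hard as possible
            loss = ad.mul(tau, -1.0) if step % 2 else tau
            opt.zero_grad()
            loss.backward()
            opt.step()
            val = float(state.tau().data[0])
            assert 0.1 <= val <= 2.0
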