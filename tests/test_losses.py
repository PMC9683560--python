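"""Loss formulas: analytic values, reductions, gradients, monotonicity."""

import numpy as np
import pytest

from fundusmt.losses import (
    EPS,
    JointLossBreakdown,
    VesselLossConfig,
    dice_loss,
    dr_ce,
    joint_loss,
    seg_ce,
    seg_loss,
)
from fundusmt.nn import Parameter, Tensor


class TestSegCE:
    def test_perfect_binary_prediction_hits_clipping_floor(self):
        y = (np.arange(16).reshape(4, 4) % 2).astype(float)
        assert float(seg_ce(y, y)) <= -np.log(1 - EPS) * 1.01 + EPS

    def test_uniform_half_gives_ln2(self):
        y = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        assert float(seg_ce(np.full((4, 4), 0.5), y)) == pytest.approx(np.log(2))

    def test_hand_evaluated_two_pixels(self):
        val = float(seg_ce(np.array([[0.9, 0.1]]), np.array([[1.0, 0.0]])))
        assert val == pytest.approx(-np.log(0.9), abs=1e-6)
        assert val == pytest.approx(0.105361, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg_ce(np.zeros((2, 2)), np.zeros((2, 3)))


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        y = np.zeros((20, 20))
        y[:10] = 1.0  # 200 foreground pixels
        assert float(dice_loss(y, y)) == pytest.approx(0.0, abs=1e-12)

    def test_both_empty_is_zero_by_smoothing(self):
        z = np.zeros((5, 5))
        assert float(dice_loss(z, z)) == 0.0

    def test_hand_evaluated(self):
        val = float(dice_loss(np.array([[1.0, 1.0]]), np.array([[1.0, 0.0]])))
        assert val == pytest.approx(0.25)

    def test_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random((6, 6))
            y = (rng.random((6, 6)) < 0.5).astype(float)
            assert 0.0 <= float(dice_loss(p, y)) < 1.0


class TestSegLoss:
    def test_single_output_reduces_to_ce_plus_dice(self):
        rng = np.random.default_rng(1)
        p = rng.random((8, 8))
        y = (rng.random((8, 8)) < 0.3).astype(float)
        bk = seg_loss(p, y)
        assert bk.total == pytest.approx(float(seg_ce(p, y)) + float(dice_loss(p, y)))
        assert bk.total == bk.ce + bk.dice

    def test_weighted_sum_over_outputs(self):
        rng = np.random.default_rng(2)
        ps = [rng.random((4, 4)) for _ in range(2)]
        ys = [(rng.random((4, 4)) < 0.5).astype(float) for _ in range(2)]
        cfg = VesselLossConfig(n=2, lambdas=(1.0, 0.5))
        bk = seg_loss(ps, ys, cfg)
        per = [float(seg_ce(p, y)) + float(dice_loss(p, y))
               for p, y in zip(ps, ys)]
        assert bk.total == pytest.approx(per[0] + 0.5 * per[1])

    def test_doubling_weights_doubles_loss(self):
        rng = np.random.default_rng(3)
        p, y = rng.random((4, 4)), (rng.random((4, 4)) < 0.5).astype(float)
        one = seg_loss(p, y, VesselLossConfig(1, (1.0,))).total
        two = seg_loss(p, y, VesselLossConfig(1, (2.0,))).total
        assert two == pytest.approx(2 * one)

    def test_output_count_mismatch(self):
        p = np.zeros((2, 2)) + 0.5
        with pytest.raises(ValueError):
            seg_loss([p, p], [p, p], VesselLossConfig(1, (1.0,)))

    def test_spatial_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.random((5, 5))
        y = (rng.random((5, 5)) < 0.5).astype(float)
        perm = rng.permutation(25)
        pp = p.ravel()[perm].reshape(5, 5)
        yp = y.ravel()[perm].reshape(5, 5)
        assert seg_loss(p, y).total == pytest.approx(seg_loss(pp, yp).total)


class TestDrCE:
    def test_uniform_gives_ln5(self):
        assert float(dr_ce(np.full(5, 0.2), 3)) == pytest.approx(np.log(5))
        assert float(dr_ce(np.full(5, 0.2), 3)) == pytest.approx(1.609438, abs=1e-6)

    def test_confident_correct_is_near_zero(self):
        p = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        assert float(dr_ce(p, 2)) == pytest.approx(0.0, abs=1e-6)

    def test_hand_evaluated(self):
        p = np.array([0.7, 0.1, 0.1, 0.05, 0.05])
        assert float(dr_ce(p, 0)) == pytest.approx(0.356675, abs=1e-6)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            dr_ce(np.full(5, 0.2), 5)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            dr_ce(np.full(5, 0.3), 1)

    def test_strictly_decreasing_in_correct_probability(self):
        vals = []
        for p0 in (0.2, 0.4, 0.6, 0.8):
            rest = (1 - p0) / 4
            vals.append(float(dr_ce(np.array([p0] + [rest] * 4), 0)))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestJointLoss:
    def test_zero_terms(self):
        assert joint_loss(0.0, 0.0).total == 0.0

    def test_addition(self):
        bk = joint_loss(1.6094, 0.5)
        assert bk == JointLossBreakdown(1.6094, 0.5, 2.1094)

    def test_zeroing_one_branch(self):
        assert joint_loss(0.0, 0.7).total == 0.7

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            joint_loss(np.inf, 0.0)


class TestGradients:
    """Finite-difference checks of the custom loss backward passes."""

    @staticmethod
    def _fd_check(make_loss, x0, eps=1e-6, tol=1e-4):
        x = Parameter(x0)
        x.data = x0.astype(np.float64)
        loss = make_loss(x)
        loss.backward()
        ana = x.grad
        num = np.zeros_like(x0)
        it = np.nditer(x0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (float(make_loss(Tensor(xp))) - float(make_loss(Tensor(xm)))) / (2 * eps)
        assert np.abs(ana - num).max() < tol

    def test_seg_ce_gradient(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        self._fd_check(lambda x: seg_ce(x, y),
                       np.array([[0.3, 0.6], [0.2, 0.9]]))

    def test_dice_gradient(self):
        y = np.array([[1.0, 0.0], [1.0, 1.0]])
        self._fd_check(lambda x: dice_loss(x, y),
                       np.array([[0.3, 0.6], [0.2, 0.9]]))

    def test_dr_ce_gradient(self):
        # finite differences would break the sum-to-1 precondition, so check
        # the closed-form gradient -1/p at the labelled entry directly
        probs = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        x = Parameter(probs)
        x.data = probs.astype(np.float64)
        loss = dr_ce(x, 1)
        loss.backward()
        assert x.grad[1] == pytest.approx(-1 / probs[1], rel=1e-9)
        assert np.all(x.grad[[0, 2, 3, 4]] == 0)
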