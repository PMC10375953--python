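import numpy as np
import pytest

from stseg import losses as L
from stseg.records import IGNORE_LABEL

RNG = np.random.default_rng(1234)


def random_probs(n_classes, shape, rng):
    raw = rng.random((n_classes,) + shape) + 1e-3
    return raw / raw.sum(axis=0, keepdims=True)


def one_hot_probs(truth, n_classes, eps=0.0):
    p = np.full((n_classes,) + truth.shape, eps / max(n_classes - 1, 1))
    for c in range(n_classes):
        p[c][truth == c] = 1.0 - eps
    return p


class TestDiceLoss:
    def test_perfect_one_hot_gives_zero(self):
        truth = np.array([[0, 1], [1, 0]])
        assert L.dice_loss(one_hot_probs(truth, 2), truth) == pytest.approx(0, abs=1e-5)

    def test_disjoint_prediction_gives_one(self):
        truth = np.zeros((4, 4), int)
        pred = one_hot_probs(np.ones((4, 4), int), 2)
        assert L.dice_loss(pred, truth) == pytest.approx(1.0, abs=1e-5)

    def test_two_pixel_hand_computed_value(self):
        # pred=[(0.8,0.2),(0.4,0.6)], truth=[0,1]; scalar-arithmetic oracle
        pred = np.array([[[0.8, 0.4]], [[0.2, 0.6]]])  # (T=2, H=1, W=2)
        truth = np.array([[0, 1]])
        t0 = 2 * 0.8 / (0.8 ** 2 + 0.4 ** 2 + 1.0 + 1e-6)
        t1 = 2 * 0.6 / (0.2 ** 2 + 0.6 ** 2 + 1.0 + 1e-6)
        expected = 1.0 - (t0 + t1) / 2.0
        assert L.dice_loss(pred, truth) == pytest.approx(expected, rel=1e-12)

    def test_all_ignored_rejected(self):
        truth = np.full((2, 2), IGNORE_LABEL)
        with pytest.raises(ValueError):
            L.dice_loss(random_probs(2, (2, 2), RNG), truth)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        pred = random_probs(3, (3, 3), rng)
        truth = rng.integers(0, 3, (3, 3))
        _, grad = L.dice_loss_with_grad(pred, truth)
        h = 1e-6
        for _ in range(8):
            t, i, j = rng.integers(0, 3, 3)
            bumped = pred.copy()
            bumped[t, i, j] += h
            fd = (L.dice_loss(bumped, truth) - L.dice_loss(pred, truth)) / h
            assert grad[0, t, i, j] == pytest.approx(fd, rel=1e-3, abs=1e-8)


class TestFocalLoss:
    def test_gamma_zero_beta_one_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        pred = random_probs(3, (8, 8), rng)
        truth = rng.integers(0, 3, (8, 8))
        cfg = L.LossConfig(gamma=0.0)
        got = L.focal_loss(pred, truth, cfg)
        # independent sum of the one-vs-rest cross-entropy terms
        expected = 0.0
        for i in range(8):
            for j in range(8):
                for t in range(3):
                    h = pred[t, i, j] if truth[i, j] == t else 1 - pred[t, i, j]
                    expected += -np.log(np.clip(h, 1e-7, 1 - 1e-7))
        expected /= 64
        assert got == pytest.approx(expected, abs=1e-6)

    def test_perfect_prediction_is_zero(self):
        truth = np.array([[0, 1]])
        pred = one_hot_probs(truth, 2)
        assert L.focal_loss(pred, truth, L.LossConfig()) == pytest.approx(0, abs=1e-4)

    def test_single_pixel_hand_computed_value(self):
        # T=2, p=(0.9,0.1), y=class0, gamma=2, beta=1: both one-vs-rest terms
        # contribute (1-0.9)^2 * (-log 0.9)
        pred = np.array([[[0.9]], [[0.1]]])
        truth = np.array([[0]])
        expected = 2 * (0.1 ** 2) * (-np.log(0.9))
        cfg = L.LossConfig(gamma=2.0)
        assert L.focal_loss(pred, truth, cfg) == pytest.approx(expected, rel=1e-9)

    def test_wrong_beta_length_rejected(self):
        cfg = L.LossConfig(beta=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="beta"):
            L.focal_loss(random_probs(2, (2, 2), RNG),
                         np.zeros((2, 2), int), cfg)

    def test_decreases_as_true_class_probability_rises(self):
        truth = np.array([[0]])
        cfg = L.LossConfig()
        vals = [L.focal_loss(np.array([[[p]], [[1 - p]]]), truth, cfg)
                for p in (0.3, 0.5, 0.7, 0.9, 0.99)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_true_class_only_variant_smaller(self):
        rng = np.random.default_rng(3)
        pred = random_probs(4, (5, 5), rng)
        truth = rng.integers(0, 4, (5, 5))
        full = L.focal_loss(pred, truth, L.LossConfig())
        only = L.focal_loss(pred, truth, L.LossConfig(focal_true_class_only=True))
        assert 0 < only < full

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(21)
        pred = random_probs(3, (4, 4), rng)
        truth = rng.integers(0, 3, (4, 4))
        cfg = L.LossConfig(beta=[0.5, 1.0, 1.5])
        _, grad = L.focal_loss_with_grad(pred, truth, cfg)
        h = 1e-7
        for _ in range(8):
            t, i, j = rng.integers(0, 3, 3)
            bumped = pred.copy()
            bumped[t, i, j] += h
            fd = (L.focal_loss(bumped, truth, cfg)
                  - L.focal_loss(pred, truth, cfg)) / h
            assert grad[0, t, i, j] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestSupervisedLoss:
    def test_rho_endpoints(self):
        rng = np.random.default_rng(5)
        pred = random_probs(3, (4, 4), rng)
        truth = rng.integers(0, 3, (4, 4))
        d = L.dice_loss(pred, truth)
        f = L.focal_loss(pred, truth, L.LossConfig(rho=0.0))
        assert L.supervised_loss(pred, truth, L.LossConfig(rho=0.0)) == pytest.approx(d)
        assert L.supervised_loss(pred, truth, L.LossConfig(rho=1.0)) == pytest.approx(f)

    def test_default_rho_combination(self):
        rng = np.random.default_rng(6)
        pred = random_probs(2, (3, 3), rng)
        truth = rng.integers(0, 2, (3, 3))
        cfg = L.LossConfig(rho=0.75)
        expected = 0.25 * L.dice_loss(pred, truth) + 0.75 * L.focal_loss(pred, truth, cfg)
        assert L.supervised_loss(pred, truth, cfg) == pytest.approx(expected)

    def test_linear_in_rho(self):
        rng = np.random.default_rng(8)
        pred = random_probs(2, (4, 4), rng)
        truth = rng.integers(0, 2, (4, 4))
        v = {rho: L.supervised_loss(pred, truth, L.LossConfig(rho=rho))
             for rho in (0.0, 0.5, 1.0)}
        assert v[0.5] == pytest.approx((v[0.0] + v[1.0]) / 2)

    def test_invariant_to_pixel_permutation(self):
        rng = np.random.default_rng(9)
        pred = random_probs(3, (1, 16), rng)
        truth = rng.integers(0, 3, (1, 16))
        perm = rng.permutation(16)
        cfg = L.LossConfig()
        assert L.supervised_loss(pred[:, :, perm], truth[:, perm], cfg) == \
            pytest.approx(L.supervised_loss(pred, truth, cfg))


class TestConsistencyLoss:
    def test_identical_maps_zero_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = random_probs(2, (4, 4), rng)
        b = random_probs(2, (4, 4), rng)
        assert L.consistency_loss(a, a) == 0.0
        assert L.consistency_loss(a, b) == pytest.approx(L.consistency_loss(b, a))

    def test_constant_offset_closed_form(self):
        a = np.full((2, 3, 3), 0.5)
        d = 0.07
        assert L.consistency_loss(a, a + d) == pytest.approx(d ** 2)

    def test_matches_brute_force_mse(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.random((2, 2, 2))
            b = rng.random((2, 2, 2))
            brute = float(np.mean([(x - y) ** 2 for x, y in
                                   zip(a.ravel(), b.ravel())]))
            assert L.consistency_loss(a, b) == pytest.approx(brute)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.consistency_loss(np.zeros((2, 2, 2)), np.zeros((2, 3, 3)))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        t = rng.random((2, 3, 3))
        s = rng.random((2, 3, 3))
        _, grad = L.consistency_loss_with_grad(t, s)
        h = 1e-7
        bumped = s.copy()
        bumped[1, 2, 1] += h
        fd = (L.consistency_loss(t, bumped) - L.consistency_loss(t, s)) / h
        assert grad[1, 2, 1] == pytest.approx(fd, rel=1e-5)


class TestLambdaSchedule:
    def test_ramp_start_middle_end(self):
        cfg = L.LossConfig(lambda_max=1.0, ramp_length=100)
        assert L.lambda_schedule(0, cfg) == pytest.approx(np.exp(-5.0))
        assert L.lambda_schedule(50, cfg) == pytest.approx(np.exp(-1.25))
        assert L.lambda_schedule(100, cfg) == 1.0
        assert L.lambda_schedule(5000, cfg) == 1.0

    def test_monotone_nondecreasing(self):
        cfg = L.LossConfig(lambda_max=0.7, ramp_length=37)
        vals = [L.lambda_schedule(s, cfg) for s in range(80)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert max(vals) == pytest.approx(0.7)

    def test_bad_ramp_rejected(self):
        with pytest.raises(ValueError):
            L.lambda_schedule(0, L.LossConfig(ramp_length=0))


class TestTotalLossAndBeta:
    @pytest.mark.parametrize("sup,con,lam,expected", [
        (0.4, 0.1, 0.5, 0.45), (0.4, 0.1, 0.0, 0.4), (0.4, 0.0, 1.0, 0.4)])
    def test_total_loss(self, sup, con, lam, expected):
        assert L.total_loss(sup, con, lam) == pytest.approx(expected)

    def test_beta_inverse_frequency_mean_one_and_ordering(self, small_volume):
        from stseg.synthetic import volume_records
        recs = volume_records(small_volume, labeled_only=True)
        beta = L.beta_inverse_frequency(recs, 3)
        assert beta.mean() == pytest.approx(1.0)
        counts = np.zeros(3)
        for r in recs:
            lab = r.label[r.label != IGNORE_LABEL]
            counts += np.bincount(lab, minlength=3)
        # rarer classes get larger weights
        assert np.argmax(beta) == np.argmin(counts)
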