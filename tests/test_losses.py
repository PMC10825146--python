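"""Closed forms and invariants of every objective term."""

import numpy as np
import pytest
from scipy.stats import nbinom, poisson

import autotransop as at
from autotransop.autodiff import Tensor, softplus

LN2 = np.log(2.0)


class TestPriorLoss:
    def test_half_scores_give_two_log_half(self):
        v = np.full(4, 0.5)
        assert at.prior_loss(v, v) == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_perfect_discrimination_approaches_zero_from_below(self):
        delta = 1e-9
        val = at.prior_loss(np.array([1 - delta]), np.array([delta]))
        assert -1e-6 < val < 0

    def test_worked_batch(self):
        # oracle: ln 0.9 + ln 0.8
        val = at.prior_loss(np.array([0.9]), np.array([0.2]))
        assert val == pytest.approx(np.log(0.9) + np.log(0.8), abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_scores_outside_open_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            at.prior_loss(np.array([bad]), np.array([0.5]))


class TestMILoss:
    def test_zero_scores_give_zero_terms(self):
        D = np.zeros((3, 3))
        mask = np.zeros((3, 3))
        mask[0, 1] = mask[1, 0] = 1
        L, Ep, Eq = at.mi_loss(D, mask)
        assert (L, Ep, Eq) == (pytest.approx(0.0), pytest.approx(0.0), pytest.approx(0.0))

    def test_perfect_discriminator_limit(self):
        big = 60.0
        mask = np.zeros((3, 3))
        mask[0, 1] = mask[1, 0] = 1
        D = np.where(mask > 0, big, -big)
        L, Ep, Eq = at.mi_loss(D, mask)
        assert Ep == pytest.approx(LN2, abs=1e-6)
        assert Eq == pytest.approx(-LN2, abs=1e-6)
        assert L == pytest.approx(-2 * LN2, abs=1e-5)

    def test_three_by_three_toy_matches_elementwise_oracle(self):
        D = np.array([[0.0, 1.0, -0.5], [1.0, 0.0, 2.0], [-0.5, 2.0, 0.0]])
        mask = np.zeros((3, 3))
        mask[0, 1] = mask[1, 0] = 1
        # oracle: direct elementwise evaluation over the mask
        sp = lambda x: np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)  # softplus
        ep_terms = [LN2 - sp(-D[0, 1]), LN2 - sp(-D[1, 0])]
        neg = [(i, j) for i in range(3) for j in range(3)
               if i != j and mask[i, j] == 0]
        eq_terms = [sp(-D[i, j]) + D[i, j] - LN2 for i, j in neg]
        L, Ep, Eq = at.mi_loss(D, mask)
        assert Ep == pytest.approx(np.mean(ep_terms), abs=1e-12)
        assert Eq == pytest.approx(np.mean(eq_terms), abs=1e-12)
        assert L == pytest.approx(-(np.mean(ep_terms) - np.mean(eq_terms)), abs=1e-12)

    def test_degenerate_masks_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            at.mi_loss(D, np.zeros((2, 2)))  # no positives
        with pytest.raises(ValueError):
            at.mi_loss(D, 1 - np.eye(2))  # no off-diagonal negatives

    def test_invariant_under_sample_relabeling(self, rng):
        n = 5
        D = rng.normal(size=(n, n))
        D = (D + D.T) / 2
        mask = np.zeros((n, n))
        mask[0, 3] = mask[3, 0] = mask[1, 4] = mask[4, 1] = 1
        perm = rng.permutation(n)
        got = at.mi_loss(D[np.ix_(perm, perm)], mask[np.ix_(perm, perm)])
        want = at.mi_loss(D, mask)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestAlignment:
    def test_identical_pair(self):
        Z = np.array([[1.0, 2.0], [1.0, 2.0]])
        d, c = at.pair_alignment_losses(Z, [(0, 1)])
        assert d == pytest.approx(0.0, abs=1e-5)
        assert c == pytest.approx(1.0)

    def test_orthogonal_unit_vectors(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        d, c = at.pair_alignment_losses(Z, [(0, 1)])
        assert d == pytest.approx(np.sqrt(2), abs=1e-6)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_worked_pair(self):
        Z = np.array([[1.0, 0.0], [0.0, 2.0]])
        d, c = at.pair_alignment_losses(Z, [(0, 1)])
        assert d == pytest.approx(np.sqrt(5), abs=1e-6)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_squared_distance_flag(self):
        Z = np.array([[1.0, 0.0], [0.0, 2.0]])
        d2, _ = at.pair_alignment_losses(Z, [(0, 1)], squared=True)
        assert d2 == pytest.approx(5.0)

    def test_zero_norm_vector_rejected(self):
        Z = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            at.pair_alignment_losses(Z, [(0, 1)])

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            at.pair_alignment_losses(np.ones((2, 2)), [])


class TestReconMSE:
    def test_exact_reconstruction_is_zero(self, rng):
        X = rng.normal(size=(3, 4))
        assert at.recon_loss_mse(X, X.copy()) == 0.0

    def test_single_sample_residuals(self):
        assert at.recon_loss_mse(np.array([[1.0, -1.0]]), np.zeros((1, 2))) == 2.0

    def test_two_by_three_toy(self):
        X = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        Xh = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 0.0]])
        # oracle: ((0+1+4) + (1+0+0)) / 2
        assert at.recon_loss_mse(X, Xh) == pytest.approx(3.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            at.recon_loss_mse(np.ones((2, 2)), np.ones((2, 3)))

    def test_nonnegative_property(self, rng):
        for _ in range(20):
            X, Y = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
            v = at.recon_loss_mse(X, Y)
            assert v >= 0
            assert (v == 0) == np.array_equal(X, Y)


class TestReconNB:
    def test_matches_scipy_pmf(self):
        mu, th = 2.0, 4.0
        for k in (0, 1, 5, 17):
            got = at.recon_loss_nb(np.array([[k]]), np.array([[mu]]), np.array([[th]]))
            want = -np.log(nbinom.pmf(k, th, th / (th + mu)))
            assert got == pytest.approx(want, abs=1e-10)

    def test_pmf_normalizes_over_truncated_support(self):
        mu, th = 2.0, 1.5
        ks = np.arange(0, 400)
        lls = [-at.recon_loss_nb(np.array([[k]]), np.array([[mu]]), np.array([[th]]))
               for k in ks]
        assert np.exp(lls).sum() >= 1 - 1e-6

    def test_poisson_limit_at_large_dispersion(self):
        got = at.recon_loss_nb(np.array([[1.0]]), np.array([[2.0]]), np.array([[1e6]]))
        want = -np.log(poisson.pmf(1, 2.0))
        assert got == pytest.approx(want, abs=1e-3)

    def test_nll_minimized_at_mu_equal_k(self):
        k = 7
        grid = np.linspace(0.5, 20, 200)
        nlls = [at.recon_loss_nb(np.array([[k]]), np.array([[m]]), np.array([[3.0]]))
                for m in grid]
        assert abs(grid[int(np.argmin(nlls))] - k) < 0.2

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            at.recon_loss_nb(np.array([[1.5]]), np.array([[1.0]]), np.array([[1.0]]))


class TestClassifierEntropy:
    def test_certain_and_uniform(self):
        assert at.classifier_entropy(np.array([[1.0, 0.0]]) + 1e-300, [0]) == pytest.approx(0.0, abs=1e-9)
        assert at.classifier_entropy(np.array([[0.5, 0.5]]), [0]) == pytest.approx(LN2)

    def test_worked_batch(self):
        probs = np.array([[0.8, 0.2], [0.7, 0.3]])
        val = at.classifier_entropy(probs, [0, 1])
        assert val == pytest.approx(-(np.log(0.8) + np.log(0.3)) / 2, abs=1e-12)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            at.classifier_entropy(np.array([[0.5, 0.5]]), [2])


def _unit_parts(**overrides):
    parts = at.LossBreakdown(L_recon=1, L_distance=1, L_cosine=1, L_MI=1, L_prior=1,
                             entropy=(1.0,), entropy_adverse=1.0,
                             L2_encoder=(1.0, 1.0), L2_decoder=(1.0, 1.0),
                             L2_classifier=(1.0,), L2_trained_effect=1.0)
    for k, v in overrides.items():
        setattr(parts, k, v)
    return parts


class TestTotalLoss:
    def test_recon_only(self):
        parts = _unit_parts(L_recon=3.5)
        w = at.LossWeights(recon=1, distance=0, mi=0, prior=0, cosine=0,
                           enc=(0, 0), dec=(0, 0), l2_class=(0,), classifier=(0,))
        assert at.total_loss(parts, w, "v1") == pytest.approx(3.5)

    def test_linear_in_each_weight(self):
        parts = _unit_parts(L_MI=2.0)
        w1 = at.LossWeights(mi=1.0)
        w2 = at.LossWeights(mi=2.0)
        assert at.total_loss(parts, w2, "v1") - at.total_loss(parts, w1, "v1") \
            == pytest.approx(parts.L_MI)

    def test_worked_all_ones_v1(self):
        # recon+distance+MI+prior+2*enc+2*dec+1*classL2+1*entropy-cosine = 9
        assert at.total_loss(_unit_parts(), at.LossWeights(), "v1") == pytest.approx(9.0)

    def test_v2_minus_v1_relation(self):
        parts = _unit_parts(entropy_adverse=0.7, L2_trained_effect=0.2)
        w = at.LossWeights(adverse=2.0, trained_effect=3.0)
        diff = at.total_loss(parts, w, "v2") - at.total_loss(parts, w, "v1")
        assert diff == pytest.approx(-2.0 * 0.7 + 3.0 * 0.2)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            at.total_loss(_unit_parts(), at.LossWeights(recon=-1.0), "v1")


class TestAutodiffEngine:
    """Spot-check gradients of the engine against finite differences."""

    @pytest.mark.parametrize("op", ["elu", "sigmoid", "softplus", "tanh", "lgamma"])
    def test_elementwise_gradients(self, op, rng):
        x = rng.uniform(0.5, 2.0, size=5)
        t = Tensor(x, requires_grad=True)
        getattr(t, op)().sum().backward()
        eps = 1e-6
        for i in range(5):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (getattr(Tensor(xp), op)().sum().item()
                  - getattr(Tensor(xm), op)().sum().item()) / (2 * eps)
            assert t.grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_matmul_and_broadcast_gradients(self, rng):
        A = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)
        out = ((A @ Tensor(rng.normal(size=(4, 2)))) ** 2).sum() + (A * b).sum()
        out.backward()
        assert A.grad.shape == (3, 4) and b.grad.shape == (4,)

    def test_stable_softplus_no_overflow(self):
        big = np.array([1000.0, -1000.0])
        out = softplus(big)
        assert np.isfinite(out).all()
        assert out[0] == pytest.approx(1000.0)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
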