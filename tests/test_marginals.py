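"""Marginal likelihoods and posterior hypothesis probabilities."""

import numpy as np
import pytest
from scipy import integrate

from maxed.data import DoseData
from maxed.marginals import (
    Block,
    FamilyMarginals,
    HypothesisSpec,
    binomial_likelihood,
    bma_models,
    marginal_likelihood,
    posterior_hypothesis_probs,
    three_dose_hypotheses,
    two_dose_hypotheses,
)
from maxed.priors import IMPriorSpec, restricted_im_density


class TestBinomialLikelihood:
    def test_values(self):
        assert binomial_likelihood(DoseData((0, 0), (1, 1)), (0.1, 0.1)) == pytest.approx(0.81)
        assert binomial_likelihood(DoseData((1, 1), (1, 1)), (1.0, 1.0)) == 1.0
        expected = 0.19371024 * 0.26682793  # C(10,2).1^2.9^8 * C(10,3).3^3.7^7
        assert binomial_likelihood(
            DoseData((2, 3), (10, 10)), (0.1, 0.3)
        ) == pytest.approx(expected, rel=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            binomial_likelihood(DoseData((1, 1), (2, 2)), (0.5,))


class TestMarginalLikelihood:
    def test_null_hypothesis_is_point_evaluation(self, two_dose_family):
        res = marginal_likelihood(DoseData((0, 0), (1, 1)), two_dose_family[0])
        assert res.method == "closed_form"
        assert res.value == pytest.approx(0.81)

    def test_pooled_uniform_closed_form(self):
        m1 = bma_models(2, 0.015)[0]
        res = marginal_likelihood(DoseData((1, 1), (2, 2)), m1)
        assert res.method == "closed_form"
        assert res.value == pytest.approx(4.0 / 30.0, rel=1e-12)
        # independent oracle: 4 * integral of theta^2 (1-theta)^2
        oracle, _ = integrate.quad(lambda t: 4 * t**2 * (1 - t) ** 2, 0, 1)
        assert res.value == pytest.approx(oracle, rel=1e-8)

    def test_pooled_im_quadrature_vs_1d_oracle(self, two_dose_family, spec_tau1):
        # H2: both doses share one rate drawn from the restricted prior
        data = DoseData((3, 3), (10, 10))
        oracle, _ = integrate.quad(
            lambda t: binomial_likelihood(data, (t, t)) * restricted_im_density(t, spec_tau1),
            0.1,
            1.0,
            limit=400,
            epsabs=1e-13,
        )
        # default node count carries ~1e-6 relative error, refinable at will
        got = marginal_likelihood(data, two_dose_family[2]).value
        assert got == pytest.approx(oracle, rel=1e-5)
        fine = marginal_likelihood(data, two_dose_family[2], nodes=1024).value
        assert fine == pytest.approx(oracle, rel=1e-7)

    @pytest.mark.parametrize("x1", [0, 3, 6, 9, 12])
    @pytest.mark.parametrize("x2", [0, 3, 6, 9, 12])
    def test_quadrature_vs_monte_carlo_grid(self, two_dose_family, x1, x2, suite_seed):
        """Deterministic and MC integrations agree across the data lattice."""
        data = DoseData((x1, x2), (12, 12))
        rng = np.random.default_rng((suite_seed, x1, x2))
        for hyp in two_dose_family[1:] + bma_models(2, 0.015)[1:]:
            quad = marginal_likelihood(data, hyp).value
            mc = marginal_likelihood(data, hyp, method="monte_carlo", n_draws=200_000, rng=rng)
            assert abs(quad - mc.value) < 3 * mc.mc_se + 1e-15

    def test_label_swap_symmetry(self, two_dose_family):
        for hyp in (two_dose_family[0], two_dose_family[2], bma_models(2, 0.015)[0]):
            a = marginal_likelihood(DoseData((2, 7), (12, 12)), hyp).value
            b = marginal_likelihood(DoseData((7, 2), (12, 12)), hyp).value
            assert a == pytest.approx(b, rel=1e-12)

    def test_compiled_family_matches_direct(self, family_marginals, two_dose_family, rng):
        for _ in range(10):
            n = tuple(int(v) for v in rng.integers(1, 25, 2))
            x = tuple(int(rng.integers(0, ni + 1)) for ni in n)
            data = DoseData(x, n)
            direct = [marginal_likelihood(data, h).value for h in two_dose_family]
            np.testing.assert_allclose(family_marginals.marginals(data), direct, rtol=1e-10)


class TestPosteriors:
    def test_normalization_and_prior_recovery(self, two_dose_family):
        post = posterior_hypothesis_probs(
            DoseData((1, 6), (12, 12)), two_dose_family, [0.25] * 4
        )
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        no_data = posterior_hypothesis_probs(
            DoseData((0, 0), (0, 0)), two_dose_family, [0.25] * 4
        )
        np.testing.assert_allclose(no_data, 0.25, atol=1e-12)

    def test_identical_marginals_give_uniform_posterior(self):
        h0 = HypothesisSpec("A", (Block((0, 1), "point"),), 0.2)
        h1 = HypothesisSpec("B", (Block((0, 1), "point"),), 0.2)
        post = posterior_hypothesis_probs(DoseData((1, 2), (5, 5)), [h0, h1], [0.5, 0.5])
        np.testing.assert_allclose(post, 0.5)

    def test_matches_monte_carlo_normalization(self, two_dose_family, suite_seed):
        """Posteriors agree with brute-force normalization of MC marginals."""
        data = DoseData((1, 6), (12, 12))
        rng = np.random.default_rng(suite_seed)
        mc = np.array(
            [
                marginal_likelihood(data, h, method="monte_carlo", n_draws=1_000_000, rng=rng).value
                for h in two_dose_family
            ]
        )
        post = posterior_hypothesis_probs(data, two_dose_family, [0.25] * 4)
        np.testing.assert_allclose(post, mc / mc.sum(), atol=0.005)


class TestEvidenceAccumulation:
    def test_null_evidence_grows_with_sample_size(self, family_marginals, suite_seed):
        """Average p(H0|x) under true-null data is non-decreasing in n.

        This is the nonlocal-prior property the design relies on: evidence
        for a true null accumulates rather than plateauing.
        """
        rng = np.random.default_rng(suite_seed)
        checkpoints = (24, 34, 44, 54)
        sums = np.zeros(len(checkpoints))
        for _ in range(200):
            x = [0, 0]
            n = [0, 0]
            k = 0
            for total in range(1, 55):
                arm = int(rng.random() < 0.5)
                n[arm] += 1
                x[arm] += int(rng.random() < 0.1)
                if total == checkpoints[k]:
                    post = family_marginals.posteriors(DoseData(tuple(x), tuple(n)), [0.25] * 4)
                    sums[k] += post[0]
                    k += 1
        avg = sums / 200
        assert np.all(np.diff(avg) >= -1e-12), avg


class TestThreeDoseFamily:
    def test_structure_and_normalization(self):
        hyps = three_dose_hypotheses(0.1, 0.06, 0.015)
        assert [h.label for h in hyps] == [f"H{i}" for i in range(8)]
        data = DoseData((1, 2, 3), (8, 8, 8))
        post = posterior_hypothesis_probs(data, hyps, [1 / 8] * 8, nodes=64)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        assert (post > 0).all()

    def test_invalid_partitions_rejected(self):
        with pytest.raises(ValueError):
            HypothesisSpec("bad", (Block((1,), "point"), Block((0,), "point")), 0.1)
        with pytest.raises(ValueError):
            HypothesisSpec("bad", (Block((0,), "im", "prev", 0.05),), 0.1)
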