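"""Joint BHT design: interim rules, H2/H3 splitting, futility-only variant."""

import numpy as np
import pytest

from maxed.bht import BHTConfig, BHTDesign, InterimDecision, bht_b_config, bht_interim, bht_split
from maxed.data import DoseData
from maxed.marginals import marginal_likelihood


@pytest.fixture(scope="module")
def runner():
    return BHTDesign().make_runner()


@pytest.fixture(scope="module")
def futility_runner():
    return BHTDesign(BHTConfig(mode="futility_only"), tox=None).make_runner()


class TestInterim:
    def test_burn_in_always_continues(self):
        dec = bht_interim(DoseData((0, 11), (11, 12)), BHTConfig())
        assert dec.action == "continue" and dec.posterior is None

    def test_null_data_concludes_null(self, runner):
        dec = runner.evaluate(DoseData((0, 0), (12, 12)))
        assert dec.action == "stop" and dec.conclusion == "H0"
        assert dec.posterior["H0"] == max(dec.posterior.values())

    def test_threshold_rule_and_refinement(self, runner):
        # strong balanced responses: merged H2* wins and refines to H2
        dec = runner.evaluate(DoseData((8, 8), (12, 12)))
        assert dec.action == "stop" and dec.conclusion in ("H2", "H3")
        assert dec.conclusion == runner.split(DoseData((8, 8), (12, 12)))

    def test_inconclusive_at_maximum(self, runner):
        # find a state at total n = 54 where no posterior clears the bar
        for x1 in range(10):
            for x2 in range(10):
                data = DoseData((x1, x2), (27, 27))
                post = runner.merged_posteriors(data)
                if max(post.values()) <= 0.65:
                    dec = runner.evaluate(data)
                    assert dec.action == "stop" and dec.conclusion == "inconclusive"
                    return
        pytest.fail("no inconclusive state found at the maximum sample size")

    def test_at_most_one_posterior_can_stop(self, runner, rng):
        for _ in range(25):
            n = tuple(int(v) for v in rng.integers(12, 28, 2))
            x = tuple(int(rng.integers(0, ni + 1)) for ni in n)
            post = runner.merged_posteriors(DoseData(x, n))
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(v > 0.65 for v in post.values()) <= 1


class TestSplit:
    def test_ratio_rule_strictness(self, family_marginals):
        cfg = BHTConfig()
        runner = BHTDesign(cfg).make_runner()
        data = DoseData((5, 5), (12, 12))
        # inject marginals so the H2/H3 ratio is exactly at, above, below Pb
        key = data.key()
        for ratio, expected in [(1.3, "H2"), (1.2, "H3"), (1.1, "H3")]:
            runner.family._cache[key] = np.array([0.1, 0.1, ratio, 1.0])
            assert runner.split(data) == expected

    def test_zero_h3_marginal_defaults_to_equality(self):
        runner = BHTDesign().make_runner()
        data = DoseData((1, 1), (2, 2))
        runner.family._cache[data.key()] = np.array([0.1, 0.1, 0.5, 0.0])
        assert runner.split(data) == "H2"

    def test_quadrature_and_monte_carlo_agree_on_call(self, two_dose_family, suite_seed):
        data = DoseData((8, 8), (12, 12))
        cfg = BHTConfig()
        rng = np.random.default_rng(suite_seed)
        mc = [
            marginal_likelihood(data, h, method="monte_carlo", n_draws=1_000_000, rng=rng).value
            for h in two_dose_family[2:]
        ]
        mc_call = "H2" if mc[0] / mc[1] > cfg.Pb else "H3"
        assert bht_split(data, cfg) == mc_call


class TestPriorsVariant:
    def test_bht_b_downweights_merged_hypothesis(self, runner):
        data = DoseData((8, 8), (12, 12))
        post_a = runner.merged_posteriors(data)
        post_b = BHTDesign(bht_b_config()).make_runner().merged_posteriors(data)
        assert post_b["H2*"] < post_a["H2*"]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BHTConfig(Pa=0.4)
        with pytest.raises(ValueError):
            BHTConfig(prior_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            InterimDecision("continue", conclusion="H0")


class TestFutilityOnly:
    def test_overwhelming_null_terminates(self, futility_runner):
        dec = futility_runner.evaluate(DoseData((0, 0), (17, 17)), {"closed": {}})
        assert dec.posterior["H0"] > 0.848
        assert dec.action == "stop" and dec.conclusion == "H0"

    def test_high_dose_evidence_closes_lower_arm(self, futility_runner):
        # find a state where only the high dose looks active
        for x2 in range(4, 13):
            data = DoseData((0, x2), (13, 13))
            post = futility_runner.merged_posteriors(data)
            if post["H1"] > 0.848:
                dec = futility_runner.evaluate(data, {"closed": {}})
                assert dec.action == "close_arm" and dec.close == (0,)
                # once closed, the same state just continues
                dec2 = futility_runner.evaluate(data, {"closed": {0: "rule"}})
                assert dec2.action == "continue"
                return
        pytest.fail("no arm-closure state found")

    def test_no_efficacy_stopping_before_cap(self, futility_runner):
        # strong positive data must NOT stop the futility-only variant early
        data = DoseData((10, 10), (13, 13))
        post = futility_runner.merged_posteriors(data)
        assert post["H2*"] > 0.848
        assert futility_runner.evaluate(data, {"closed": {}}).action == "continue"

    def test_final_claims_at_half(self, futility_runner):
        dec = futility_runner.final(DoseData((30, 31), (45, 45)))
        assert dec.conclusion in ("H2", "H3")
        dec = futility_runner.final(DoseData((2, 3), (45, 45)))
        assert dec.conclusion == "H0"
        # balanced middling data leaves every posterior below 1/2
        for x in range(5, 12):
            data = DoseData((x, x), (45, 45))
            post = futility_runner.merged_posteriors(data)
            if max(post.values()) <= 0.5:
                assert futility_runner.final(data).conclusion == "inconclusive"
                return
        pytest.fail("no inconclusive end state found")


class TestMonotoneEvidence:
    def test_responding_high_dose_patient_never_raises_null_posterior(self, runner):
        """Appending a responder at the high dose cannot favor the null."""
        for n in (12, 18, 26):
            for x1 in range(0, n + 1, 3):
                for x2 in range(0, n + 1):
                    before = runner.merged_posteriors(DoseData((x1, x2), (n, n)))["H0"]
                    after = runner.merged_posteriors(DoseData((x1, x2 + 1), (n, n + 1)))["H0"]
                    assert after <= before + 1e-9, (n, x1, x2)
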