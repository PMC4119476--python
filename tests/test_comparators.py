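"""Comparator designs: Simon two-stage, independent BHT, BIT."""

import numpy as np
import pytest
from scipy import stats

from maxed.comparators import (
    BITDesign,
    IndepBHTConfig,
    IndepBHTDesign,
    SimonTwoDoseConfig,
    SimonTwoDoseDesign,
    simon_optimal,
    simon_two_dose,
    split_errors,
)
from maxed.data import DoseData, Scenario
from maxed.priors import IMPriorSpec, sample_restricted_im
from maxed.simulate import operating_characteristics


def brute_force_simon(p0, p1, alpha, beta, n_ceiling):
    """Slow, independent enumeration of the optimal two-stage design."""
    best = None
    for n in range(2, n_ceiling + 1):
        for n1 in range(1, n):
            n2 = n - n1
            for r1 in range(0, n1):
                pet0 = stats.binom.cdf(r1, n1, p0)
                for r in range(r1 + 1, n + 1):
                    k = np.arange(r1 + 1, n1 + 1)
                    a = np.sum(stats.binom.pmf(k, n1, p0) * stats.binom.sf(r - k, n2, p0))
                    if a > alpha:
                        continue
                    pw = np.sum(stats.binom.pmf(k, n1, p1) * stats.binom.sf(r - k, n2, p1))
                    if pw < 1 - beta:
                        continue
                    en = n1 + (1 - pet0) * n2
                    if best is None or en < best[0] - 1e-12:
                        best = (en, n1, r1, n, r)
                    break  # larger r only lowers power
    return best


class TestSimonOptimal:
    def test_study_error_split(self):
        a, b = split_errors(0.05, 0.2, 2)
        assert round(a, 4) == 0.0253
        assert round(b, 3) == 0.106
        # inversion: per-dose power compounds back to the overall target
        assert (1 - b) ** 2 == pytest.approx(0.8, rel=1e-12)
        assert split_errors(0.0, 0.3, 3)[0] == 0.0

    def test_study_design_dimensions(self):
        d = simon_optimal(0.1, 0.3, 0.0253, 0.106)
        assert (d.n, d.n1) == (45, 17)
        assert d.alpha <= 0.0253 and d.power >= 0.894
        # printable summary used by the CLI
        assert f"{d.r1}/{d.n1}" in str(d)

    def test_matches_independent_enumeration(self):
        got = simon_optimal(0.1, 0.3, 0.05, 0.2, n_ceiling=40)
        en, n1, r1, n, r = brute_force_simon(0.1, 0.3, 0.05, 0.2, 40)
        assert (got.n1, got.r1, got.n, got.r) == (n1, r1, n, r)
        assert got.en0 == pytest.approx(en, rel=1e-12)

    def test_attained_rates_are_exact_binomials(self):
        d = simon_optimal(0.1, 0.3, 0.05, 0.2)
        k = np.arange(d.r1 + 1, d.n1 + 1)
        alpha = np.sum(
            stats.binom.pmf(k, d.n1, 0.1) * stats.binom.sf(d.r - k, d.n - d.n1, 0.1)
        )
        assert d.alpha == pytest.approx(alpha, rel=1e-12)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            simon_optimal(0.1, 0.12, 0.01, 0.01, n_ceiling=30)


class TestSimonTwoDose:
    def test_conclusion_mapping(self):
        assert simon_two_dose((True, True), (0.0, 0.0), 0.05) == "H0"
        assert simon_two_dose((True, False), (0.1, 0.4), 0.05) == "H1"
        assert simon_two_dose((False, False), (0.40, 0.42), 0.05) == "H2"
        assert simon_two_dose((False, False), (0.30, 0.42), 0.05) == "H3"
        assert simon_two_dose((False, True), (0.4, 0.1), 0.05) == "inconclusive"

    def test_simulated_null_rejection_matches_exact_probability(self, suite_seed):
        """Internal consistency: simulated P(both arms reject) at the null
        equals (1 - attained alpha)^2 within Monte-Carlo error."""
        d = simon_optimal(0.1, 0.3, 0.0253, 0.106)
        design = SimonTwoDoseDesign(SimonTwoDoseConfig(d, 0.05))
        oc = operating_characteristics(design, Scenario((0.1, 0.1)), 400, suite_seed)
        exact = (1 - d.alpha) ** 2
        se = np.sqrt(exact * (1 - exact) / 400)
        assert abs(oc.probs["H0"] - exact) < 3 * se
        # per-arm sample size matches the design's expected value
        assert np.mean(oc.avg_arm_n) == pytest.approx(d.en0, abs=3 * 8 / np.sqrt(400))


class TestIndepBHT:
    def test_arm_decision_ignores_other_arm(self):
        runner = IndepBHTDesign().make_runner()
        assert runner.arm_posterior_null(2, 12) == runner.arm_posterior_null(2, 12)
        # the per-arm decision is a function of that arm's counts only:
        # arm 1 at 0/12 is closed futile whatever arm 2 shows
        s1, s2 = {"closed": {}}, {"closed": {}}
        runner.evaluate(DoseData((0, 6), (12, 12)), s1)
        runner.evaluate(DoseData((0, 0), (12, 5)), s2)
        assert s1["closed"][0] == "futile" == s2["closed"][0]

    def test_conclusion_mapping(self):
        runner = IndepBHTDesign().make_runner()
        data = DoseData((0, 0), (12, 12))
        mk = lambda s1, s2: {"closed": {0: s1, 1: s2}}  # noqa: E731
        assert runner.final(data, mk("futile", "futile")).conclusion == "H0"
        assert runner.final(data, mk("futile", "effective")).conclusion == "H1"
        assert runner.final(data, mk("effective", "futile")).conclusion == "inconclusive"
        assert runner.final(data, mk("unresolved", "futile")).conclusion == "inconclusive"
        got = runner.final(DoseData((8, 8), (12, 12)), mk("effective", "effective"))
        assert got.conclusion in ("H2", "H3")

    def test_diff_exceedance_matches_monte_carlo(self, suite_seed):
        """Deterministic grid split probability vs importance-sampling MC."""
        cfg = IndepBHTConfig()
        runner = IndepBHTDesign(cfg).make_runner()
        data = DoseData((5, 8), (12, 12))
        got = runner.diff_exceedance(data)
        rng = np.random.default_rng(suite_seed)
        spec = IMPriorSpec(cfg.theta0, cfg.tau1)
        # self-normalized importance sampling with the prior as proposal
        th1 = sample_restricted_im(spec, 400_000, rng)
        th2 = sample_restricted_im(spec, 400_000, rng)
        w = (
            th1 ** data.x[0] * (1 - th1) ** (data.n[0] - data.x[0])
            * th2 ** data.x[1] * (1 - th2) ** (data.n[1] - data.x[1])
        )
        mc = float(np.sum(w * (th2 - th1 > cfg.diff)) / np.sum(w))
        assert got == pytest.approx(mc, abs=3e-3)

    def test_flat_prior_variant_differs(self):
        data = DoseData((5, 8), (12, 12))
        nl = IndepBHTDesign().make_runner().diff_exceedance(data)
        fl = IndepBHTDesign(IndepBHTConfig(split_prior="flat")).make_runner().diff_exceedance(data)
        assert nl != fl and 0 < fl < 1


class TestBIT:
    def test_extreme_data_stops_for_promise(self):
        runner = BITDesign().make_runner(7)
        dec = runner.evaluate(DoseData((12, 12), (12, 12)), {"closed": {}})
        assert dec.action == "stop" and dec.conclusion in ("H2", "H3")
        assert dec.posterior["p1"] > 0.99

    def test_null_data_concludes_null(self):
        runner = BITDesign().make_runner(7)
        dec = runner.evaluate(DoseData((0, 0), (12, 12)), {"closed": {}})
        assert dec.action == "stop" and dec.conclusion == "H0"
        p = dec.posterior
        assert p["p2"] + p["p3"] > 0.65 and p["p2"] - p["p3"] <= 0.4

    def test_ordered_data_has_no_equality_mass(self):
        runner = BITDesign().make_runner(7)
        _, _, _, eq = runner.summaries(DoseData((1, 11), (12, 12)))
        assert eq < 0.01

    def test_summaries_deterministic_per_state(self):
        a = BITDesign().make_runner(7).summaries(DoseData((3, 5), (12, 12)))
        b = BITDesign().make_runner(7).summaries(DoseData((3, 5), (12, 12)))
        assert a == b
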