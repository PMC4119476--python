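"""Joint Bayesian hypothesis-testing (BHT) design.

Two doses, continuous monitoring.  Four hypotheses about the response
rates (neither dose promising / only the high dose / both equal / both but
ordered) receive prior probabilities; after a burn-in the posterior
probabilities of H0, H1 and the merged "both promising" hypothesis
H2* = H2 u H3 are evaluated after every patient, and the trial stops as
soon as one exceeds the threshold Pa (or the maximum sample size is
reached, in which case the same thresholds decide between a conclusion and
an inconclusive trial).  An H2* stop is refined to H2 when the marginal
likelihood ratio p(x|H2)/p(x|H3) exceeds Pb, and to H3 otherwise.

Two prior configurations matter in practice: equal mass 1/4 on each of
H0..H3 ("BHT-A") and mass 1/3 on H0, H1 and H2* with H2* split evenly
("BHT-B").

A futility-only variant supports comparison with designs that never stop
early for efficacy: the trial terminates only when p(H0|x) is very high,
the lower arm is closed when p(H1|x) is very high, each arm enrolls to a
per-arm maximum, and conclusions are claimed at the end at a lower
posterior bar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .data import DoseData
from .marginals import FamilyMarginals, single_arm_hypotheses, two_dose_hypotheses
from .toxicity import ToxConfig

__all__ = ["BHTConfig", "InterimDecision", "BHTDesign", "bht_interim", "bht_split"]


@dataclass(frozen=True)
class InterimDecision:
    action: str                      # "continue" | "stop" | "close_arm"
    conclusion: str | None = None    # set iff action == "stop"
    posterior: dict | None = None    # snapshot of the monitored probabilities
    close: tuple[int, ...] = ()      # arms to close when action == "close_arm"

    def __post_init__(self) -> None:
        if (self.action == "stop") != (self.conclusion is not None):
            raise ValueError("conclusion must be set exactly when stopping")


@dataclass(frozen=True)
class BHTConfig:
    theta0: float = 0.1
    theta_star: float = 0.3
    tau1: float = 0.06
    tau2: float = 0.015
    prior_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    Pa: float = 0.65
    Pb: float = 1.2
    n_min: int = 24
    N_max: int = 54
    mode: str = "full"               # "full" | "futility_only"
    # futility-only variant parameters
    futility_stop: float = 0.848
    final_claim: float = 0.5
    futility_split: float = 1.37
    per_arm_max: int = 45
    nodes: int = 128

    def __post_init__(self) -> None:
        if not self.Pa > 0.5:
            raise ValueError("Pa must exceed 0.5 (at most one hypothesis can stop)")
        if not self.Pb > 0:
            raise ValueError("Pb must be positive")
        if self.n_min > self.N_max:
            raise ValueError("n_min cannot exceed N_max")
        if abs(sum(self.prior_probs) - 1.0) > 1e-9:
            raise ValueError("prior probabilities must sum to 1")
        if self.mode not in ("full", "futility_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


def bht_b_config(**overrides) -> BHTConfig:
    """The BHT-B prior configuration: 1/3 on H0, H1, H2*; H2* split evenly."""
    cfg = BHTConfig(prior_probs=(1 / 3, 1 / 3, 1 / 6, 1 / 6))
    return replace(cfg, **overrides) if overrides else cfg


class BHTDesign:
    """Stateless description of a BHT design; per-run state lives in runners."""

    n_doses = 2

    def __init__(self, cfg: BHTConfig = BHTConfig(), tox: ToxConfig | None = ToxConfig()):
        self.cfg = cfg
        self.tox = tox
        if cfg.mode == "futility_only":
            self.name = "bht-futility"
        elif max(cfg.prior_probs) - min(cfg.prior_probs) < 1e-12:
            self.name = "bht-a"
        else:
            self.name = "bht-b"

    @property
    def burn_in(self) -> int:
        return self.cfg.n_min

    @property
    def total_cap(self) -> int:
        if self.cfg.mode == "futility_only":
            return self.n_doses * self.cfg.per_arm_max
        return self.cfg.N_max

    @property
    def per_arm_cap(self) -> int | None:
        return self.cfg.per_arm_max if self.cfg.mode == "futility_only" else None

    def make_runner(self, mc_seed: int = 0) -> "BHTRunner":
        return BHTRunner(self)


class BHTRunner:
    """Cached interim evaluator for one simulation run (or one real trial)."""

    def __init__(self, design: BHTDesign):
        self.design = design
        cfg = design.cfg
        self.family = FamilyMarginals(
            two_dose_hypotheses(cfg.theta0, cfg.tau1, cfg.tau2), nodes=cfg.nodes
        )
        self.single = FamilyMarginals(
            single_arm_hypotheses(cfg.theta0, cfg.tau1), nodes=cfg.nodes
        )

    # -- posterior summaries -------------------------------------------------

    def merged_posteriors(self, data: DoseData) -> dict[str, float]:
        """p(H0|x), p(H1|x) and the merged p(H2*|x)."""
        cfg = self.design.cfg
        post = self.family.posteriors(data, cfg.prior_probs)
        return {
            "H0": float(post[0]),
            "H1": float(post[1]),
            "H2*": float(post[2] + post[3]),
        }

    def split(self, data: DoseData) -> str:
        """Refine an H2* conclusion: H2 iff p(x|H2)/p(x|H3) > Pb (strict)."""
        cfg = self.design.cfg
        cut = cfg.futility_split if cfg.mode == "futility_only" else cfg.Pb
        m = self.family.marginals(data)
        if m[3] == 0.0:
            return "H2"
        return "H2" if m[2] / m[3] > cut else "H3"

    # -- interim logic -------------------------------------------------------

    def evaluate(self, data: DoseData, state: dict | None = None) -> InterimDecision:
        cfg = self.design.cfg
        closed = state["closed"] if state is not None else {}
        if cfg.mode == "futility_only":
            return self._evaluate_futility(data, closed)
        if 1 in closed:
            return self._evaluate_single_arm(data)
        if data.total_n < cfg.n_min:
            return InterimDecision("continue")
        post = self.merged_posteriors(data)
        label = max(post, key=post.get)
        if post[label] > cfg.Pa:
            conclusion = self.split(data) if label == "H2*" else label
            return InterimDecision("stop", conclusion, post)
        if data.total_n >= cfg.N_max:
            return InterimDecision("stop", "inconclusive", post)
        return InterimDecision("continue", posterior=post)

    def _evaluate_single_arm(self, data: DoseData) -> InterimDecision:
        # High arm closed for toxicity: the trial continues as a single-arm
        # evaluation of the low dose with the same null/alternative priors.
        # A null conclusion maps to H0; a promising low dose maps to H2 (the
        # low dose is the effective dose the trial can still recommend).
        cfg = self.design.cfg
        if data.total_n < cfg.n_min:
            return InterimDecision("continue")
        d1 = DoseData((data.x[0],), (data.n[0],))
        post = self.single.posteriors(d1, (0.5, 0.5))
        snap = {"H0": float(post[0]), "H2": float(post[1])}
        if post[0] > cfg.Pa:
            return InterimDecision("stop", "H0", snap)
        if post[1] > cfg.Pa:
            return InterimDecision("stop", "H2", snap)
        if data.total_n >= cfg.N_max:
            return InterimDecision("stop", "inconclusive", snap)
        return InterimDecision("continue", posterior=snap)

    def _evaluate_futility(self, data: DoseData, closed: dict) -> InterimDecision:
        cfg = self.design.cfg
        if data.total_n < cfg.n_min:
            return InterimDecision("continue")
        post = self.merged_posteriors(data)
        if post["H0"] > cfg.futility_stop:
            return InterimDecision("stop", "H0", post)
        if 0 not in closed and post["H1"] > cfg.futility_stop:
            return InterimDecision("close_arm", posterior=post, close=(0,))
        return InterimDecision("continue", posterior=post)

    def final(self, data: DoseData, state: dict | None = None) -> InterimDecision:
        """End-of-enrollment claim for the futility-only variant."""
        cfg = self.design.cfg
        post = self.merged_posteriors(data)
        if post["H0"] > cfg.final_claim:
            return InterimDecision("stop", "H0", post)
        if post["H1"] > cfg.final_claim:
            return InterimDecision("stop", "H1", post)
        if post["H2*"] > cfg.final_claim:
            return InterimDecision("stop", self.split(data), post)
        return InterimDecision("stop", "inconclusive", post)


# -- convenience one-shot API ------------------------------------------------

def bht_interim(data: DoseData, cfg: BHTConfig) -> InterimDecision:
    """Interim decision for observed trial data under a BHT configuration."""
    return BHTDesign(cfg).make_runner().evaluate(data)


def bht_split(data: DoseData, cfg: BHTConfig) -> str:
    """H2-vs-H3 refinement after an H2* stop."""
    return BHTDesign(cfg).make_runner().split(data)
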