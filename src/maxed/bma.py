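"""Bayesian model-averaging (BMA) design.

Two models for the two dose-specific response rates: M1 pools them
(theta1 = theta2 ~ Uniform(0,1)); M2 orders them strictly, with
theta1 ~ Uniform(0,1) and theta2 | theta1 following a restricted
inverse-moment prior anchored at theta1.  Interim decisions use three
model-averaged posterior tail probabilities,

    p1 = P(theta1 > theta*-delta, theta2 > theta*-delta | data)
    p2 = P(theta1 < theta0+delta, theta2 > theta*-delta | data)
    p3 = P(theta1 < theta0+delta, theta2 < theta0+delta | data),

each computed under both models and averaged with the posterior model
probabilities.  The trial stops when p1 > Pe (both doses promising; H2 if
the posterior odds of M1 exceed Pg, else H3) or when p2 + p3 > Pf (H0 if
p2 - p3 <= Pk, else H1), or at the maximum sample size.

Under M1 every event collapses to a one-dimensional beta-posterior tail.
Under M2 the posterior on the ordered triangle is evaluated on a fixed
product grid, keeping interim decisions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .bht import InterimDecision
from .data import DoseData
from .marginals import FamilyMarginals, bma_models
from .toxicity import ToxConfig

__all__ = [
    "BMAConfig",
    "TailProbs",
    "BMADesign",
    "bma_model_posteriors",
    "bma_tail_probs",
    "bma_interim",
]


@dataclass(frozen=True)
class BMAConfig:
    theta0: float = 0.1
    theta_star: float = 0.3
    tau2: float = 0.015
    delta: float = 0.1
    Pe: float = 0.7
    Pf: float = 0.65
    Pg: float = 1.3
    Pk: float = 0.02
    n_min: int = 24
    N_max: int = 54
    prior_probs: tuple[float, float] = (0.5, 0.5)
    grid: int = 2000          # per-axis resolution of the M2 posterior grid
    nodes: int = 128

    def __post_init__(self) -> None:
        if not 0 < self.delta < self.theta_star - self.theta0:
            raise ValueError("need 0 < delta < theta_star - theta0")
        for name in ("Pe", "Pf"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.Pg > 0:
            raise ValueError("Pg must be positive")
        if not -1 < self.Pk < 1:
            raise ValueError("Pk must lie in (-1, 1)")
        if abs(sum(self.prior_probs) - 1.0) > 1e-9:
            raise ValueError("prior model probabilities must sum to 1")


@dataclass(frozen=True)
class TailProbs:
    p1: float
    p2: float
    p3: float

    @property
    def low(self) -> float:
        """p2 + p3, the evidence that the low dose is not promising."""
        return self.p2 + self.p3


class BMADesign:
    name = "bma"
    n_doses = 2

    def __init__(self, cfg: BMAConfig = BMAConfig(), tox: ToxConfig | None = ToxConfig()):
        self.cfg = cfg
        self.tox = tox

    @property
    def burn_in(self) -> int:
        return self.cfg.n_min

    @property
    def total_cap(self) -> int:
        return self.cfg.N_max

    per_arm_cap: int | None = None

    def make_runner(self, mc_seed: int = 0) -> "BMARunner":
        return BMARunner(self)


class BMARunner:
    def __init__(self, design: BMADesign):
        self.design = design
        cfg = design.cfg
        self.family = FamilyMarginals(bma_models(2, cfg.tau2), nodes=cfg.nodes)
        self._tails: dict[tuple, TailProbs] = {}
        # Midpoint grid on (0,1)^2; the ordered-prior weight matrix depends
        # only on the configuration, so it is built once.  Log space: the
        # conditional normalizer of pi_rI(theta2; theta1) underflows as
        # theta1 -> 1 although the ratio density/normalizer stays finite.
        g = (np.arange(cfg.grid) + 0.5) / cfg.grid
        self._g = g
        diff = g[None, :] - g[:, None]              # theta2 - theta1
        tau = cfg.tau2
        with np.errstate(divide="ignore", invalid="ignore"):
            log_dens = np.log(tau) - 3.0 * np.log(diff) - tau / diff**2
        log_z = np.log(0.5) - tau / (1.0 - g) ** 2  # per-theta1 normalizer
        self._log_prior = np.where(diff > 0.0, log_dens - log_z[:, None], -np.inf)

    def model_posteriors(self, data: DoseData) -> tuple[float, float]:
        post = self.family.posteriors(data, self.design.cfg.prior_probs)
        return float(post[0]), float(post[1])

    def _m1_tails(self, data: DoseData) -> TailProbs:
        cfg = self.design.cfg
        a = sum(data.x) + 1.0
        b = sum(data.n) - sum(data.x) + 1.0
        lo = cfg.theta0 + cfg.delta
        hi = cfg.theta_star - cfg.delta
        cdf = lambda t: special.betainc(a, b, t)  # noqa: E731
        p1 = 1.0 - cdf(hi)
        p2 = max(0.0, cdf(lo) - cdf(hi))  # empty when lo <= hi
        p3 = cdf(lo)
        return TailProbs(p1, p2, p3)

    def _m2_tails(self, data: DoseData) -> TailProbs:
        cfg = self.design.cfg
        g = self._g
        ll1 = data.x[0] * np.log(g) + (data.n[0] - data.x[0]) * np.log1p(-g)
        ll2 = data.x[1] * np.log(g) + (data.n[1] - data.x[1]) * np.log1p(-g)
        logW = self._log_prior + ll1[:, None] + ll2[None, :]
        W = np.exp(logW - logW.max())
        total = W.sum()
        lo = g < cfg.theta0 + cfg.delta          # mask on each axis
        hi = g > cfg.theta_star - cfg.delta
        p1 = W[np.ix_(hi, hi)].sum() / total
        p2 = W[np.ix_(lo, hi)].sum() / total
        p3 = W[np.ix_(lo, lo)].sum() / total
        return TailProbs(float(p1), float(p2), float(p3))

    def tail_probs(self, data: DoseData) -> TailProbs:
        key = data.key()
        out = self._tails.get(key)
        if out is None:
            w1, w2 = self.model_posteriors(data)
            t1 = self._m1_tails(data)
            t2 = self._m2_tails(data)
            out = TailProbs(
                w1 * t1.p1 + w2 * t2.p1,
                w1 * t1.p2 + w2 * t2.p2,
                w1 * t1.p3 + w2 * t2.p3,
            )
            self._tails[key] = out
        return out

    def decide(self, tails: TailProbs, model_odds: float, at_cap: bool) -> InterimDecision:
        """Pure stopping rule given the tail probabilities and p(M1|x)/p(M2|x)."""
        cfg = self.design.cfg
        snap = {"p1": tails.p1, "p2": tails.p2, "p3": tails.p3, "odds": model_odds}
        if tails.p1 > cfg.Pe:
            conclusion = "H2" if model_odds > cfg.Pg else "H3"
            return InterimDecision("stop", conclusion, snap)
        if tails.low > cfg.Pf:
            conclusion = "H0" if tails.p2 - tails.p3 <= cfg.Pk else "H1"
            return InterimDecision("stop", conclusion, snap)
        if at_cap:
            return InterimDecision("stop", "inconclusive", snap)
        return InterimDecision("continue", posterior=snap)

    def evaluate(self, data: DoseData, state: dict | None = None) -> InterimDecision:
        cfg = self.design.cfg
        closed = state["closed"] if state is not None else {}
        if data.total_n < cfg.n_min:
            return InterimDecision("continue")
        if 1 in closed:
            return self._evaluate_single_arm(data)
        tails = self.tail_probs(data)
        w1, w2 = self.model_posteriors(data)
        odds = np.inf if w2 == 0.0 else w1 / w2
        return self.decide(tails, odds, at_cap=data.total_n >= cfg.N_max)

    def _evaluate_single_arm(self, data: DoseData) -> InterimDecision:
        # High arm closed for toxicity: monitor the low dose alone under its
        # Uniform(0,1) prior; a promising low dose maps to H2.
        cfg = self.design.cfg
        a = data.x[0] + 1.0
        b = data.n[0] - data.x[0] + 1.0
        p_hi = 1.0 - special.betainc(a, b, cfg.theta_star - cfg.delta)
        p_lo = special.betainc(a, b, cfg.theta0 + cfg.delta)
        snap = {"p1": float(p_hi), "p3": float(p_lo)}
        if p_hi > cfg.Pe:
            return InterimDecision("stop", "H2", snap)
        if p_lo > cfg.Pf:
            return InterimDecision("stop", "H0", snap)
        if data.total_n >= cfg.N_max:
            return InterimDecision("stop", "inconclusive", snap)
        return InterimDecision("continue", posterior=snap)

    def final(self, data: DoseData, state: dict | None = None) -> InterimDecision:
        return self.evaluate(data, state)


# -- convenience one-shot API ------------------------------------------------

def bma_model_posteriors(data: DoseData, cfg: BMAConfig) -> tuple[float, float]:
    """(p(M1|x), p(M2|x)): closed beta form for M1, quadrature for M2."""
    return BMADesign(cfg).make_runner().model_posteriors(data)


def bma_tail_probs(data: DoseData, cfg: BMAConfig) -> TailProbs:
    """Model-averaged tail probabilities (p1, p2, p3)."""
    return BMADesign(cfg).make_runner().tail_probs(data)


def bma_interim(data: DoseData, cfg: BMAConfig) -> InterimDecision:
    """Interim decision for observed trial data under a BMA configuration."""
    return BMADesign(cfg).make_runner().evaluate(data)
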