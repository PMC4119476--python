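"""Benchmark designs: independent per-arm BHT, BIT, and Simon two-stage.

* Independent BHT runs a single-arm nonlocal-prior hypothesis test on each
  dose separately (null rate vs. restricted inverse-moment alternative),
  stopping each arm for futility or efficacy at a per-arm threshold.
* BIT monitors the same three tail probabilities as the model-averaging
  design but computes them from independent Uniform(0,1)/beta posteriors
  passed through the precision-weighted isotonic projection.
* The Simon optimal two-stage design is the classical single-arm design
  (n1, r1, n, r) minimizing the expected sample size under the null
  subject to exact binomial error bounds, applied independently per dose
  with an overall error split across doses, and extended with an
  observed-rate rule to pick between equal and ordered response rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .bht import InterimDecision
from .data import DoseData
from .marginals import FamilyMarginals, single_arm_hypotheses
from .priors import IMPriorSpec, restricted_im_density
from .toxicity import ToxConfig, pava_rows

__all__ = [
    "IndepBHTConfig",
    "IndepBHTDesign",
    "BITConfig",
    "BITDesign",
    "SimonDesign",
    "simon_optimal",
    "split_errors",
    "simon_two_dose",
    "SimonTwoDoseConfig",
    "SimonTwoDoseDesign",
]


# ---------------------------------------------------------------------------
# Simon optimal two-stage design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimonDesign:
    """A two-stage design: stop after n1 if X1 <= r1; reject at n if X <= r."""

    n1: int
    r1: int
    n: int
    r: int
    alpha: float       # attained P(accept drug | p0)
    power: float       # attained P(accept drug | p1)
    pet0: float        # P(early termination | p0)
    en0: float         # expected sample size under p0

    def __str__(self) -> str:
        return (
            f"Simon optimal: r1/n1 = {self.r1}/{self.n1}, r/n = {self.r}/{self.n}; "
            f"alpha = {self.alpha:.4f}, power = {self.power:.4f}, "
            f"EN(p0) = {self.en0:.2f}, PET(p0) = {self.pet0:.4f}"
        )


def simon_optimal(
    p0: float, p1: float, alpha: float, beta: float, n_ceiling: int = 100
) -> SimonDesign:
    """Exhaustive search for the Simon *optimal* two-stage design.

    All designs with total size up to ``n_ceiling`` are enumerated with
    exact binomial attained error rates; among those with attained type I
    error <= ``alpha`` and power >= ``1 - beta``, the design minimizing the
    expected sample size under ``p0`` is returned (ties broken by smaller
    n, then smaller n1).
    """
    if not p0 < p1:
        raise ValueError("need p0 < p1")
    best: SimonDesign | None = None
    for n in range(2, n_ceiling + 1):
        for n1 in range(1, n):
            n2 = n - n1
            k = np.arange(n1 + 1)
            pmf0 = stats.binom.pmf(k, n1, p0)
            pmf1 = stats.binom.pmf(k, n1, p1)
            cdf0 = np.cumsum(pmf0)
            # sf[j] = P(X2 > j); j may be negative (prob 1) or >= n2 (prob 0)
            r_grid = np.arange(n)                     # candidate final bounds r
            j = r_grid[None, :] - k[:, None]          # needed X2 exceedance per k
            sf0 = np.where(j < 0, 1.0, stats.binom.sf(np.clip(j, 0, n2), n2, p0))
            sf1 = np.where(j < 0, 1.0, stats.binom.sf(np.clip(j, 0, n2), n2, p1))
            acc0 = pmf0[:, None] * sf0                # P(X1=k, X1+X2 > r | p0)
            acc1 = pmf1[:, None] * sf1
            # suffix sums over k > r1 for every r1 simultaneously
            tail0 = np.cumsum(acc0[::-1], axis=0)[::-1]   # tail0[k] = sum_{k'>=k}
            tail1 = np.cumsum(acc1[::-1], axis=0)[::-1]
            for r1 in range(0, n1):
                a_r = tail0[r1 + 1]                   # attained alpha per r
                ok = np.flatnonzero((a_r <= alpha) & (r_grid > r1))
                if ok.size == 0:
                    continue
                r = int(ok[0])                        # smallest r keeps max power
                pw = float(tail1[r1 + 1][r])
                if pw < 1.0 - beta:
                    continue
                pet0 = float(cdf0[r1])
                en0 = n1 + (1.0 - pet0) * n2
                cand = SimonDesign(n1, r1, n, r, float(a_r[r]), pw, pet0, en0)
                if (
                    best is None
                    or cand.en0 < best.en0 - 1e-12
                    or (abs(cand.en0 - best.en0) <= 1e-12 and (cand.n, cand.n1) < (best.n, best.n1))
                ):
                    best = cand
    if best is None:
        raise ValueError(f"no feasible two-stage design with n <= {n_ceiling}")
    return best


def split_errors(overall_alpha: float, overall_beta: float, J: int = 2) -> tuple[float, float]:
    """Per-dose error rates controlling overall errors across J independent arms."""
    if J < 2:
        raise ValueError("J must be at least 2")
    a = 1.0 - (1.0 - overall_alpha) ** (1.0 / J)
    b = 1.0 - (1.0 - overall_beta) ** (1.0 / J)
    return a, b


@dataclass(frozen=True)
class SimonTwoDoseConfig:
    design: SimonDesign
    delta: float = 0.05

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")


def simon_two_dose(
    rejected: tuple[bool, bool], observed_rates: tuple[float, float], delta: float
) -> str:
    """Trial conclusion from per-arm Simon outcomes.

    "Rejected" means the dose was *not* found promising.  Both rejected ->
    H0; only the lower -> H1; neither -> H2 when the observed rates are
    within delta (RR1 >= RR2 - delta), else H3; only the higher ->
    inconclusive.
    """
    r1, r2 = rejected
    if r1 and r2:
        return "H0"
    if r1 and not r2:
        return "H1"
    if not r1 and not r2:
        rr1, rr2 = observed_rates
        return "H2" if rr1 >= rr2 - delta else "H3"
    return "inconclusive"


class SimonTwoDoseDesign:
    """Two independent Simon two-stage arms with an observed-rate H2/H3 split."""

    name = "simon"
    n_doses = 2
    burn_in = 0

    def __init__(self, cfg: SimonTwoDoseConfig, tox: ToxConfig | None = None):
        self.cfg = cfg
        self.tox = tox

    @property
    def total_cap(self) -> int:
        return 2 * self.cfg.design.n

    @property
    def per_arm_cap(self) -> int:
        return self.cfg.design.n

    def make_runner(self, mc_seed: int = 0) -> "SimonTwoDoseRunner":
        return SimonTwoDoseRunner(self)


class SimonTwoDoseRunner:
    def __init__(self, design: SimonTwoDoseDesign):
        self.design = design

    def evaluate(self, data: DoseData, state: dict) -> InterimDecision:
        d = self.design.cfg.design
        closed = state["closed"]
        close: list[int] = []
        for arm in range(2):
            if arm in closed:
                continue
            if data.n[arm] == d.n1 and data.x[arm] <= d.r1:
                closed[arm] = "rejected"      # stage-1 futility stop
                close.append(arm)
            elif data.n[arm] == d.n:
                closed[arm] = "rejected" if data.x[arm] <= d.r else "accepted"
                close.append(arm)
        if all(arm in closed for arm in range(2)):
            return self.final(data, state)
        if close:
            return InterimDecision("close_arm", close=tuple(close))
        return InterimDecision("continue")

    def final(self, data: DoseData, state: dict) -> InterimDecision:
        closed = state["closed"]
        if any(closed.get(arm) == "toxic" for arm in range(2)):
            return InterimDecision("stop", "inconclusive")
        rejected = tuple(closed.get(arm) == "rejected" for arm in range(2))
        rates = tuple(data.x[i] / data.n[i] if data.n[i] else 0.0 for i in range(2))
        return InterimDecision(
            "stop", simon_two_dose(rejected, rates, self.design.cfg.delta)
        )


# ---------------------------------------------------------------------------
# Independent per-arm BHT design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndepBHTConfig:
    theta0: float = 0.1
    tau1: float = 0.06
    Pa_star: float = 0.7      # per-arm stop threshold (futility and efficacy)
    Pd: float = 0.11          # H2/H3 split: H2 iff P(theta2-theta1 > diff) <= Pd
    diff: float = 0.1
    n_min_arm: int = 12
    n_max_arm: int = 27
    split_prior: str = "nonlocal"   # posteriors for the split: "nonlocal" | "flat"
    nodes: int = 128

    def __post_init__(self) -> None:
        if not self.Pa_star > 0.5:
            raise ValueError("Pa_star must exceed 0.5")
        if self.split_prior not in ("nonlocal", "flat"):
            raise ValueError(f"unknown split_prior {self.split_prior!r}")


class IndepBHTDesign:
    name = "indep-bht"
    n_doses = 2

    def __init__(
        self,
        cfg: IndepBHTConfig = IndepBHTConfig(),
        tox: ToxConfig | None = ToxConfig(rule="independent"),
    ):
        self.cfg = cfg
        self.tox = tox

    @property
    def burn_in(self) -> int:
        return 0  # per-arm burn-in is enforced inside evaluate

    @property
    def total_cap(self) -> int:
        return 2 * self.cfg.n_max_arm

    @property
    def per_arm_cap(self) -> int:
        return self.cfg.n_max_arm

    def make_runner(self, mc_seed: int = 0) -> "IndepBHTRunner":
        return IndepBHTRunner(self)


class IndepBHTRunner:
    def __init__(self, design: IndepBHTDesign):
        self.design = design
        cfg = design.cfg
        self.single = FamilyMarginals(
            single_arm_hypotheses(cfg.theta0, cfg.tau1), nodes=cfg.nodes
        )
        self._split_cache: dict[tuple, float] = {}

    def arm_posterior_null(self, x: int, n: int) -> float:
        """p(H0i | arm data) with equal prior odds on {H0i, H1i}."""
        post = self.single.posteriors(DoseData((x,), (n,)), (0.5, 0.5))
        return float(post[0])

    def diff_exceedance(self, data: DoseData) -> float:
        """P(theta2 - theta1 > diff | x) under independent arm posteriors."""
        key = data.key()
        out = self._split_cache.get(key)
        if out is None:
            cfg = self.design.cfg
            grid = 4000
            if cfg.split_prior == "nonlocal":
                lo = cfg.theta0
                g = lo + (np.arange(grid) + 0.5) * (1.0 - lo) / grid
                prior = restricted_im_density(g, IMPriorSpec(cfg.theta0, cfg.tau1))
            else:
                g = (np.arange(grid) + 0.5) / grid
                prior = np.ones(grid)
            dens = []
            for arm in range(2):
                d = prior * g ** data.x[arm] * (1.0 - g) ** (data.n[arm] - data.x[arm])
                dens.append(d / d.sum())
            cdf2 = np.cumsum(dens[1])
            # P(theta2 > t) at t = theta1 + diff, interpolated on the grid CDF
            sf2 = 1.0 - np.interp(g + cfg.diff, g, cdf2, left=0.0, right=1.0)
            out = float(np.sum(dens[0] * sf2))
            self._split_cache[key] = out
        return out

    def evaluate(self, data: DoseData, state: dict) -> InterimDecision:
        cfg = self.design.cfg
        closed = state["closed"]
        close: list[int] = []
        for arm in range(2):
            if arm in closed or data.n[arm] < cfg.n_min_arm:
                continue
            p0 = self.arm_posterior_null(data.x[arm], data.n[arm])
            if p0 > cfg.Pa_star:
                closed[arm] = "futile"
                close.append(arm)
            elif 1.0 - p0 > cfg.Pa_star:
                closed[arm] = "effective"
                close.append(arm)
            elif data.n[arm] >= cfg.n_max_arm:
                closed[arm] = "unresolved"
                close.append(arm)
        if all(arm in closed for arm in range(2)):
            return self.final(data, state)
        if close:
            return InterimDecision("close_arm", close=tuple(close))
        return InterimDecision("continue")

    def final(self, data: DoseData, state: dict) -> InterimDecision:
        cfg = self.design.cfg
        closed = state["closed"]
        status = [closed.get(arm, "unresolved") for arm in range(2)]
        if status == ["futile", "futile"]:
            return InterimDecision("stop", "H0")
        if status == ["futile", "effective"]:
            return InterimDecision("stop", "H1")
        if status == ["effective", "effective"]:
            conclusion = "H2" if self.diff_exceedance(data) <= cfg.Pd else "H3"
            return InterimDecision("stop", conclusion)
        return InterimDecision("stop", "inconclusive")


# ---------------------------------------------------------------------------
# BIT design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BITConfig:
    theta0: float = 0.1
    theta_star: float = 0.3
    delta: float = 0.1
    Ph: float = 0.65
    Pi: float = 0.65
    Pj: float = 0.4
    n_min: int = 24
    N_max: int = 54
    n_draws: int = 10_000

    def __post_init__(self) -> None:
        for name in ("Ph", "Pi", "Pj"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


class BITDesign:
    name = "bit"
    n_doses = 2

    def __init__(self, cfg: BITConfig = BITConfig(), tox: ToxConfig | None = ToxConfig()):
        self.cfg = cfg
        self.tox = tox

    @property
    def burn_in(self) -> int:
        return self.cfg.n_min

    @property
    def total_cap(self) -> int:
        return self.cfg.N_max

    per_arm_cap: int | None = None

    def make_runner(self, mc_seed: int = 0) -> "BITRunner":
        return BITRunner(self, mc_seed)


class BITRunner:
    """Isotonic-transformation monitor over independent beta posteriors.

    Each interim state (x, n) is evaluated once, with a substream derived
    from the state, so the decision function is deterministic and cached.
    """

    def __init__(self, design: BITDesign, mc_seed: int = 0):
        self.design = design
        self.mc_seed = int(mc_seed)
        self._cache: dict[tuple, tuple[float, float, float, float]] = {}

    def summaries(self, data: DoseData) -> tuple[float, float, float, float]:
        """(p1, p2, p3, equality mass) from projected posterior draws."""
        key = data.key()
        out = self._cache.get(key)
        if out is None:
            cfg = self.design.cfg
            seed = np.random.SeedSequence((self.mc_seed, 11, *data.x, *data.n))
            rng = np.random.Generator(np.random.PCG64(seed))
            a = np.array([x + 1.0 for x in data.x])
            b = np.array([n - x + 1.0 for n, x in zip(data.n, data.x)])
            draws = rng.beta(a, b, size=(cfg.n_draws, 2))
            var = a * b / ((a + b) ** 2 * (a + b + 1.0))
            pooled = draws[:, 0] > draws[:, 1]   # order violated => projection pools
            proj = pava_rows(draws, 1.0 / var)
            lo = cfg.theta0 + cfg.delta
            hi = cfg.theta_star - cfg.delta
            p1 = float(np.mean((proj[:, 0] > hi) & (proj[:, 1] > hi)))
            p2 = float(np.mean((proj[:, 0] < lo) & (proj[:, 1] > hi)))
            p3 = float(np.mean((proj[:, 0] < lo) & (proj[:, 1] < lo)))
            out = (p1, p2, p3, float(pooled.mean()))
            self._cache[key] = out
        return out

    def evaluate(self, data: DoseData, state: dict) -> InterimDecision:
        cfg = self.design.cfg
        if data.total_n < cfg.n_min:
            return InterimDecision("continue")
        closed = state["closed"]
        if 1 in closed:
            return self._evaluate_single_arm(data)
        p1, p2, p3, eq = self.summaries(data)
        snap = {"p1": p1, "p2": p2, "p3": p3, "eq": eq}
        if p1 > cfg.Ph:
            conclusion = "H2" if eq >= 1.0 - eq else "H3"
            return InterimDecision("stop", conclusion, snap)
        if p2 + p3 > cfg.Pi:
            conclusion = "H0" if p2 - p3 <= cfg.Pj else "H1"
            return InterimDecision("stop", conclusion, snap)
        if data.total_n >= cfg.N_max:
            return InterimDecision("stop", "inconclusive", snap)
        return InterimDecision("continue", posterior=snap)

    def _evaluate_single_arm(self, data: DoseData) -> InterimDecision:
        cfg = self.design.cfg
        a = data.x[0] + 1.0
        b = data.n[0] - data.x[0] + 1.0
        p_hi = 1.0 - special.betainc(a, b, cfg.theta_star - cfg.delta)
        p_lo = special.betainc(a, b, cfg.theta0 + cfg.delta)
        snap = {"p1": float(p_hi), "p3": float(p_lo)}
        if p_hi > cfg.Ph:
            return InterimDecision("stop", "H2", snap)
        if p_lo > cfg.Pi:
            return InterimDecision("stop", "H0", snap)
        if data.total_n >= cfg.N_max:
            return InterimDecision("stop", "inconclusive", snap)
        return InterimDecision("continue", posterior=snap)

    def final(self, data: DoseData, state: dict) -> InterimDecision:
        return self.evaluate(data, state)
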