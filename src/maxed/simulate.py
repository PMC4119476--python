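"""Discrete-event simulation of trials and operating characteristics.

The engine enrolls one patient at a time: the patient is randomized with
equal probability among the open arms, response and toxicity are drawn
independently from the scenario's true rates, toxicity is checked after
every patient from the first, and the design's efficacy rule is checked
after every patient once its burn-in is reached.  Arm closures (for
toxicity or by design rule) redirect later patients to the remaining open
arms.  A trial ends when the design stops it, when toxicity terminates it,
or when no arm can enroll further, at which point the design draws its
final conclusion.

Randomness discipline: `operating_characteristics` spawns one independent
substream per replicate from the master seed, and each replicate splits
assignment, response and toxicity into separate streams.  Monte-Carlo
decision functions (toxicity exceedance, BIT summaries) use substreams
derived from a separate ``mc_seed`` and the interim state, making every
design decision a fixed deterministic function of the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DoseData, Scenario
from .toxicity import ToxicityMonitor

__all__ = ["TrialResult", "OCTable", "simulate_trial", "operating_characteristics"]

CONCLUSIONS = ("H0", "H1", "H2", "H3", "inconclusive", "toxicity")


@dataclass(frozen=True)
class TrialResult:
    conclusion: str                  # one of CONCLUSIONS
    data: DoseData
    stop_reason: str                 # "efficacy_rule" | "toxicity" | "exhausted"
    n_looks: int

    @property
    def total_n(self) -> int:
        return self.data.total_n

    def __post_init__(self) -> None:
        if self.conclusion not in CONCLUSIONS:
            raise ValueError(f"unknown conclusion {self.conclusion!r}")


@dataclass
class OCTable:
    """Operating characteristics of one design under one scenario."""

    design: str
    scenario: str
    n_reps: int
    seed: int
    probs: dict[str, float]          # P(H0), P(H1), P(H2), P(H3), P(H2*)
    pct_inconclusive: float
    pct_toxicity: float
    avg_total_n: float
    avg_arm_n: tuple[float, ...]

    @classmethod
    def from_results(
        cls, results: list[TrialResult], design: str, scenario: str, seed: int
    ) -> "OCTable":
        n = len(results)
        counts = {c: 0 for c in CONCLUSIONS}
        for r in results:
            counts[r.conclusion] += 1
        probs = {c: counts[c] / n for c in ("H0", "H1", "H2", "H3")}
        probs["H2*"] = probs["H2"] + probs["H3"]
        arms = np.array([r.data.n for r in results], dtype=float)
        return cls(
            design=design,
            scenario=scenario,
            n_reps=n,
            seed=seed,
            probs=probs,
            pct_inconclusive=counts["inconclusive"] / n,
            pct_toxicity=counts["toxicity"] / n,
            avg_total_n=float(arms.sum(axis=1).mean()),
            avg_arm_n=tuple(float(v) for v in arms.mean(axis=0)),
        )

    def to_series(self) -> pd.Series:
        row = {
            "design": self.design,
            "scenario": self.scenario,
            "P(H0)": self.probs["H0"],
            "P(H1)": self.probs["H1"],
            "P(H2)": self.probs["H2"],
            "P(H3)": self.probs["H3"],
            "P(H2*)": self.probs["H2*"],
            "avg ss": self.avg_total_n,
            "% inconclusive": self.pct_inconclusive,
            "% toxicity stop": self.pct_toxicity,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }
        for i, v in enumerate(self.avg_arm_n, start=1):
            row[f"avg ss {i}"] = v
        return pd.Series(row)

    def check_partition(self, tol: float = 1e-12) -> bool:
        total = (
            sum(self.probs[c] for c in ("H0", "H1", "H2", "H3"))
            + self.pct_inconclusive
            + self.pct_toxicity
        )
        return abs(total - 1.0) <= tol


def _open_arms(design, data: DoseData, closed: dict) -> list[int]:
    cap = design.per_arm_cap
    out = []
    for arm in range(design.n_doses):
        if arm in closed:
            continue
        if cap is not None and data.n[arm] >= cap:
            continue
        out.append(arm)
    return out


def simulate_trial(
    runner,
    scenario: Scenario,
    seed_seq: np.random.SeedSequence,
    tox_monitor: ToxicityMonitor | None = None,
) -> TrialResult:
    """Simulate one trial with a design runner (see ``Design.make_runner``)."""
    design = runner.design
    if scenario.n_doses != design.n_doses:
        raise ValueError("scenario and design dose counts differ")
    s_assign, s_resp, s_tox = [
        np.random.Generator(np.random.PCG64(s)) for s in seed_seq.spawn(3)
    ]
    data = DoseData((0,) * design.n_doses, (0,) * design.n_doses)
    state: dict = {"closed": {}}
    looks = 0
    while True:
        open_arms = _open_arms(design, data, state["closed"])
        if not open_arms or data.total_n >= design.total_cap:
            dec = runner.final(data, state)
            return TrialResult(dec.conclusion, data, "exhausted", looks)
        arm = open_arms[s_assign.integers(len(open_arms))] if len(open_arms) > 1 else open_arms[0]
        response = s_resp.random() < scenario.response[arm]
        toxicity = s_tox.random() < scenario.toxicity[arm]
        data = data.add(arm, response, toxicity)
        if tox_monitor is not None:
            action, doses = tox_monitor.action(data)
            if action == "terminate":
                return TrialResult("toxicity", data, "toxicity", looks)
            if action == "close":
                for d in doses:
                    state["closed"].setdefault(d, "toxic")
        looks += 1
        dec = runner.evaluate(data, state)
        if dec.action == "stop":
            return TrialResult(dec.conclusion, data, "efficacy_rule", looks)
        if dec.action == "close_arm":
            for d in dec.close:
                state["closed"].setdefault(d, "rule")


def operating_characteristics(
    design,
    scenario: Scenario,
    n_reps: int,
    seed: int,
    mc_seed: int | None = None,
) -> OCTable:
    """Aggregate ``n_reps`` independent simulated trials into an OC table."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mc_seed = seed if mc_seed is None else mc_seed
    runner = design.make_runner(mc_seed)
    monitor = ToxicityMonitor(design.tox, mc_seed) if design.tox is not None else None
    master = np.random.SeedSequence(seed)
    results = [
        simulate_trial(runner, scenario, child, monitor)
        for child in master.spawn(n_reps)
    ]
    return OCTable.from_results(results, design.name, scenario.label, seed)
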