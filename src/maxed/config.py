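"""Run configuration: design registry, YAML parsing, validation.

Every decision threshold of the study designs has exactly one definition (the
design config dataclass defaults); YAML files and CLI flags only override
them.  Every override is validated by the dataclass invariants before any
simulation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .bht import BHTConfig, BHTDesign, bht_b_config
from .bma import BMAConfig, BMADesign
from .comparators import (
    BITConfig,
    BITDesign,
    IndepBHTConfig,
    IndepBHTDesign,
    SimonTwoDoseConfig,
    SimonTwoDoseDesign,
    simon_optimal,
)
from .data import Scenario
from .toxicity import ToxConfig

__all__ = ["DESIGN_NAMES", "build_design", "RunConfig", "load_run_config"]

_SIMON_DELTAS = {"simon-i": 0.05, "simon-ii": 0.03, "simon-iii": 0.07}

DESIGN_NAMES = (
    "bht-a",
    "bht-b",
    "bht-futility",
    "bma",
    "bit",
    "indep-bht",
    "simon-i",
    "simon-ii",
    "simon-iii",
)


def _tox_config(tox: dict | None, rule: str = "isotonic") -> ToxConfig | None:
    if tox is None:
        return ToxConfig(rule=rule)
    if tox.get("enabled", True) is False:
        return None
    kwargs = {k: v for k, v in tox.items() if k != "enabled"}
    if "priors" in kwargs:
        kwargs["priors"] = tuple(tuple(p) for p in kwargs["priors"])
    kwargs.setdefault("rule", rule)
    return ToxConfig(**kwargs)


def build_design(name: str, overrides: dict | None = None, tox: dict | None = None):
    """Instantiate a design by CLI name with optional threshold overrides."""
    overrides = dict(overrides or {})
    if name == "bht-a":
        return BHTDesign(BHTConfig(**overrides), _tox_config(tox))
    if name == "bht-b":
        return BHTDesign(bht_b_config(**overrides), _tox_config(tox))
    if name == "bht-futility":
        overrides.setdefault("mode", "futility_only")
        # the futility-only comparison switches off toxicity monitoring
        return BHTDesign(BHTConfig(**overrides), _tox_config(tox or {"enabled": False}))
    if name == "bma":
        return BMADesign(BMAConfig(**overrides), _tox_config(tox))
    if name == "bit":
        return BITDesign(BITConfig(**overrides), _tox_config(tox))
    if name == "indep-bht":
        return IndepBHTDesign(
            IndepBHTConfig(**overrides), _tox_config(tox, rule="independent")
        )
    if name in _SIMON_DELTAS:
        p0 = overrides.pop("p0", 0.1)
        p1 = overrides.pop("p1", 0.3)
        alpha = overrides.pop("alpha", 0.0253)
        beta = overrides.pop("beta", 0.106)
        delta = overrides.pop("delta", _SIMON_DELTAS[name])
        if overrides:
            raise ValueError(f"unknown Simon overrides: {sorted(overrides)}")
        design = SimonTwoDoseDesign(
            SimonTwoDoseConfig(simon_optimal(p0, p1, alpha, beta), delta),
            _tox_config(tox or {"enabled": False}, rule="independent"),
        )
        design.name = name
        return design
    raise ValueError(f"unknown design {name!r}; known: {', '.join(DESIGN_NAMES)}")


@dataclass
class RunConfig:
    designs: list          # instantiated design objects
    scenarios: list[Scenario]
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.designs:
            raise ValueError("at least one design required")
        if not self.scenarios:
            raise ValueError("at least one scenario required")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    tox = raw.get("toxicity")
    designs = []
    for entry in raw.get("designs", []):
        if isinstance(entry, str):
            entry = {"name": entry}
        designs.append(build_design(entry["name"], entry.get("overrides"), tox))
    scenarios = [
        Scenario(
            tuple(s["response"]),
            tuple(s.get("toxicity", ())),
            s.get("label", ""),
        )
        for s in raw.get("scenarios", [])
    ]
    return RunConfig(
        designs=designs,
        scenarios=scenarios,
        n_reps=int(raw.get("n_reps", 1000)),
        seed=int(raw.get("seed", 0)),
    )


def config_dict(design) -> dict:
    """Flat JSON-friendly dump of a design's configuration (for manifests)."""
    out = {"name": design.name}
    cfg = design.cfg
    out.update(dataclasses.asdict(cfg) if dataclasses.is_dataclass(cfg) else dict(cfg))
    if getattr(design, "tox", None) is not None:
        out["toxicity"] = dataclasses.asdict(design.tox)
    return out
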