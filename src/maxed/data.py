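"""Core containers: per-dose trial data and simulation scenarios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DoseData", "Scenario"]


@dataclass(frozen=True)
class DoseData:
    """Per-dose sufficient statistics: responses, patients, toxicities.

    Doses are indexed from lowest to highest.  ``x[i]`` responses out of
    ``n[i]`` patients at dose i, with ``tox[i]`` dose-limiting toxicities.
    """

    x: tuple[int, ...]
    n: tuple[int, ...]
    tox: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", tuple(int(v) for v in self.x))
        object.__setattr__(self, "n", tuple(int(v) for v in self.n))
        tox = self.tox if self.tox else (0,) * len(self.x)
        object.__setattr__(self, "tox", tuple(int(v) for v in tox))
        if not (len(self.x) == len(self.n) == len(self.tox)):
            raise ValueError("x, n, tox must have equal length")
        if len(self.x) not in (1, 2, 3):
            raise ValueError("designs support 1-3 dose levels")
        for xi, ni, ti in zip(self.x, self.n, self.tox):
            if not 0 <= xi <= ni:
                raise ValueError(f"need 0 <= x <= n per dose, got x={xi}, n={ni}")
            if not 0 <= ti <= ni:
                raise ValueError(f"need 0 <= tox <= n per dose, got tox={ti}, n={ni}")

    @property
    def n_doses(self) -> int:
        return len(self.x)

    @property
    def total_n(self) -> int:
        return sum(self.n)

    def add(self, dose: int, response: bool, toxicity: bool = False) -> "DoseData":
        """Return a new DoseData with one more patient at ``dose``."""
        x = list(self.x)
        n = list(self.n)
        t = list(self.tox)
        x[dose] += int(response)
        n[dose] += 1
        t[dose] += int(toxicity)
        return DoseData(tuple(x), tuple(n), tuple(t))

    def key(self) -> tuple:
        """Hashable sufficient-statistic key for caching."""
        return (self.x, self.n)


@dataclass(frozen=True)
class Scenario:
    """True per-dose response and toxicity probabilities for simulation."""

    response: tuple[float, ...]
    toxicity: tuple[float, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "response", tuple(float(v) for v in self.response))
        tox = self.toxicity if self.toxicity else (0.0,) * len(self.response)
        object.__setattr__(self, "toxicity", tuple(float(v) for v in tox))
        if len(self.response) != len(self.toxicity):
            raise ValueError("response and toxicity must have equal length")
        arr = np.array(self.response + self.toxicity)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.label:
            lab = " & ".join(f"{r:g}" for r in self.response)
            object.__setattr__(self, "label", lab)

    @property
    def n_doses(self) -> int:
        return len(self.response)
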