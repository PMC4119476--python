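"""Order-constrained toxicity monitoring.

Toxicity probabilities are assumed non-decreasing in dose.  Each dose gets
an independent beta prior; after every patient the unconstrained beta
posteriors are sampled jointly, and each draw vector is mapped to the
ordered cone by the weighted least-squares isotonic projection
(pool-adjacent-violators), with weights equal to the unconstrained
posterior precisions.  A dose is declared toxic when the posterior
probability that its *constrained* toxicity rate exceeds the limit p_bar
passes the threshold Pc; the trial is terminated when every dose is toxic
and the highest dose arms are closed when only they are toxic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DoseData

__all__ = [
    "ToxConfig",
    "weighted_pava",
    "pava_rows",
    "tox_posterior_exceedance",
    "tox_action",
    "ToxicityMonitor",
    "elicit_toxicity_priors",
]


@dataclass(frozen=True)
class ToxConfig:
    """Toxicity-monitoring parameters.

    ``priors`` holds one (a, b) beta prior per dose; the defaults encode
    the borrowed phase I experience for the two studied dose levels (see
    :func:`elicit_toxicity_priors`).  ``rule`` selects the order-constrained
    ("isotonic") monitor or fully independent per-arm monitoring
    ("independent"), the latter used by the independent comparator design.
    """

    priors: tuple[tuple[float, float], ...] = ((0.5, 16.5), (0.5, 8.5))
    p_bar: float = 0.3
    Pc: float = 0.8
    n_draws: int = 10_000
    rule: str = "isotonic"

    def __post_init__(self) -> None:
        for a, b in self.priors:
            if a <= 0 or b <= 0:
                raise ValueError("beta prior parameters must be positive")
        if not 0 < self.p_bar < 1 or not 0 < self.Pc < 1:
            raise ValueError("p_bar and Pc must lie in (0, 1)")
        if self.rule not in ("isotonic", "independent"):
            raise ValueError(f"unknown rule {self.rule!r}")


def weighted_pava(values, weights) -> np.ndarray:
    """Weighted least-squares isotonic projection of a sequence.

    Returns the non-decreasing vector minimizing
    sum_i weights[i] * (out[i] - values[i])**2, by pool-adjacent-violators.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be equal-length 1-D arrays")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    # blocks as (mean, weight, count) stacks merged while out of order
    means: list[float] = []
    wts: list[float] = []
    cnts: list[int] = []
    for vi, wi in zip(v, w):
        means.append(float(vi))
        wts.append(float(wi))
        cnts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), cnts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), cnts.pop()
            wt = w1 + w2
            means.append((w1 * m1 + w2 * m2) / wt)
            wts.append(wt)
            cnts.append(c1 + c2)
    return np.repeat(means, cnts)


def _partitions(j: int) -> list[tuple[tuple[int, ...], ...]]:
    """All contiguous partitions of range(j), e.g. ((0,1),(2,)) for j=3."""
    if j == 1:
        return [((0,),)]
    out = []
    for first_len in range(1, j + 1):
        head = tuple(range(first_len))
        if first_len == j:
            out.append((head,))
        else:
            for rest in _partitions(j - first_len):
                shifted = tuple(tuple(i + first_len for i in blk) for blk in rest)
                out.append((head,) + shifted)
    return out


def pava_rows(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted isotonic projection of a (draws, J) matrix.

    For the small J used here (<= 3) the projection equals the feasible
    contiguous-partition fit with minimal weighted sum of squares, which
    vectorizes across draws; larger J falls back to per-row PAVA.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    W = np.broadcast_to(np.asarray(W, dtype=float), V.shape)
    j = V.shape[1]
    if j == 1:
        return V.copy()
    if j > 3:
        return np.vstack([weighted_pava(v, w) for v, w in zip(V, W)])
    best = None
    best_ss = None
    for part in _partitions(j):
        fit = np.empty_like(V)
        for blk in part:
            blk = list(blk)
            m = (W[:, blk] * V[:, blk]).sum(axis=1) / W[:, blk].sum(axis=1)
            fit[:, blk] = m[:, None]
        feasible = np.all(np.diff(fit, axis=1) >= -1e-15, axis=1)
        ss = (W * (fit - V) ** 2).sum(axis=1)
        ss = np.where(feasible, ss, np.inf)
        if best is None:
            best, best_ss = fit, ss
        else:
            better = ss < best_ss
            best = np.where(better[:, None], fit, best)
            best_ss = np.minimum(ss, best_ss)
    return best


def _posterior_params(data: DoseData, cfg: ToxConfig) -> tuple[np.ndarray, np.ndarray]:
    if len(cfg.priors) != data.n_doses:
        raise ValueError("one beta prior per dose required")
    a = np.array([p[0] + t for p, t in zip(cfg.priors, data.tox)])
    b = np.array([p[1] + n - t for p, n, t in zip(cfg.priors, data.n, data.tox)])
    return a, b


def tox_posterior_exceedance(
    data: DoseData, cfg: ToxConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-dose P(constrained toxicity rate > p_bar | data).

    Monte-Carlo over ``cfg.n_draws`` joint draws of the unconstrained beta
    posteriors, projected draw-by-draw when ``cfg.rule == "isotonic"``.
    Weights are the analytic beta posterior precisions.
    """
    a, b = _posterior_params(data, cfg)
    draws = rng.beta(a, b, size=(cfg.n_draws, data.n_doses))
    if cfg.rule == "isotonic" and data.n_doses > 1:
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        draws = pava_rows(draws, 1.0 / var)
    return (draws > cfg.p_bar).mean(axis=0)


def tox_action(exceedance, cfg: ToxConfig) -> tuple[str, tuple[int, ...]]:
    """Monitoring action from per-dose exceedance probabilities.

    Returns ``("terminate", ())`` when every dose is toxic, ``("close", doses)``
    closing the toxic (higher) doses, or ``("none", ())``.  Under the order
    constraint the toxic set is always a top segment of the doses.
    """
    exc = np.asarray(exceedance, dtype=float)
    toxic = exc > cfg.Pc
    if toxic.all():
        return ("terminate", ())
    if toxic.any():
        doses = tuple(int(i) for i in np.flatnonzero(toxic))
        if cfg.rule == "isotonic" and doses != tuple(range(doses[0], len(exc))):
            raise AssertionError(
                "toxic set is not a top segment despite the order constraint"
            )
        return ("close", doses)
    return ("none", ())


class ToxicityMonitor:
    """Deterministic, cached continuous toxicity monitor.

    The exceedance probabilities depend on the data only through the
    per-dose (toxicity, n) counts, so each state is evaluated once with a
    dedicated substream derived from ``mc_seed`` and the state itself; the
    decision function is then a fixed deterministic map, reproducible
    across replicates and runs.
    """

    def __init__(self, cfg: ToxConfig, mc_seed: int = 0):
        self.cfg = cfg
        self.mc_seed = int(mc_seed)
        self._cache: dict[tuple, np.ndarray] = {}

    def exceedance(self, data: DoseData) -> np.ndarray:
        key = (data.tox, data.n)
        out = self._cache.get(key)
        if out is None:
            seed = np.random.SeedSequence((self.mc_seed, 7, *data.tox, *data.n))
            rng = np.random.Generator(np.random.PCG64(seed))
            out = tox_posterior_exceedance(data, self.cfg, rng)
            self._cache[key] = out
        return out

    def action(self, data: DoseData) -> tuple[str, tuple[int, ...]]:
        return tox_action(self.exceedance(data), self.cfg)


def elicit_toxicity_priors(
    n_per_level: tuple[int, ...] = (3, 3, 3, 3),
    phase2_levels: tuple[int, ...] = (1, 2),
    base: tuple[float, float] = (0.5, 0.5),
    exchange: tuple[int, int] = (3, 5),
) -> list[tuple[float, float]]:
    """Toxicity priors for phase II doses from toxicity-free phase I data.

    Ordering lets a dose borrow from every *higher* phase I level: each
    ``exchange[0]`` toxicity-free patients at one level up count as
    ``exchange[1]`` toxicity-free patients at the level below, applied per
    level distance and rounded to whole pseudo-patients.  Starting from a
    beta ``base`` prior, the pseudo-patients (all toxicity-free) inflate
    only the second beta parameter.

    The defaults encode four phase I levels with three toxicity-free
    patients each and phase II doses at the two middle levels, which yields
    Beta(0.5, 16.5) for the lower and Beta(0.5, 8.5) for the higher dose.
    """
    lo, hi = exchange
    ratio = hi / lo
    out = []
    for level in phase2_levels:
        pseudo = 0
        for j in range(level, len(n_per_level)):
            pseudo += round(n_per_level[j] * ratio ** (j - level))
        out.append((base[0], base[1] + pseudo))
    return out
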