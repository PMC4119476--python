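"""Hypotheses, binomial likelihoods, and marginal likelihoods.

A hypothesis about J ordered dose-specific response rates is encoded as a
contiguous partition of the doses into *blocks* sharing one rate, with one
prior per block:

* ``point``   — the block's rate equals the null rate theta0 exactly;
* ``im``      — the block's rate follows a restricted inverse-moment prior
  anchored either at theta0 or at the previous block's (random) rate;
* ``uniform`` — Uniform(0, 1), used by the model-averaging models.

This covers the two-dose testing family {H0, H1, H2, H3}, its three-dose
extension {H0..H7}, the model-averaging families {M1, M2} / {M1..M4}, and
the single-arm pair {H0i, H1i} used by the independent comparator design.

Marginal likelihoods integrate the binomial likelihood against the chain of
block priors.  The default integrator is deterministic nested
Gauss-Legendre quadrature after an inverse-CDF change of variables per
``im`` block (the prior becomes the uniform measure on (0,1), so the
near-singular peak of the density is absorbed exactly); Monte Carlo over
prior draws is available as a verification mode and reports its standard
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import special

from .data import DoseData
from .priors import _ppf

__all__ = [
    "Block",
    "HypothesisSpec",
    "MarginalResult",
    "binomial_likelihood",
    "marginal_likelihood",
    "posterior_hypothesis_probs",
    "two_dose_hypotheses",
    "three_dose_hypotheses",
    "bma_models",
    "single_arm_hypotheses",
    "FamilyMarginals",
]


@dataclass(frozen=True)
class Block:
    doses: tuple[int, ...]          # contiguous dose indices sharing one rate
    kind: str                       # "point" | "im" | "uniform"
    anchor: str = "theta0"          # for "im": "theta0" or "prev"
    tau: float | None = None        # for "im"

    def __post_init__(self) -> None:
        if self.kind not in ("point", "im", "uniform"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kind == "im":
            if self.anchor not in ("theta0", "prev"):
                raise ValueError(f"unknown anchor {self.anchor!r}")
            if self.tau is None or self.tau <= 0:
                raise ValueError("im block requires tau > 0")


@dataclass(frozen=True)
class HypothesisSpec:
    """One hypothesis (or model-averaging model) over ordered dose rates."""

    label: str
    blocks: tuple[Block, ...]
    theta0: float = 0.0

    def __post_init__(self) -> None:
        covered: list[int] = []
        for i, b in enumerate(self.blocks):
            covered.extend(b.doses)
            if i == 0 and b.kind == "im" and b.anchor == "prev":
                raise ValueError("first block cannot anchor at a previous block")
        if covered != list(range(len(covered))):
            raise ValueError("blocks must form a contiguous low-to-high partition")

    @property
    def n_doses(self) -> int:
        return sum(len(b.doses) for b in self.blocks)

    def key(self) -> tuple:
        return (
            self.label,
            self.theta0,
            tuple((b.doses, b.kind, b.anchor, b.tau) for b in self.blocks),
        )


@dataclass(frozen=True)
class MarginalResult:
    value: float
    method: str          # "closed_form" | "quadrature" | "monte_carlo"
    mc_se: float = 0.0


def binomial_likelihood(data: DoseData, theta: Sequence[float]) -> float:
    """Product of per-dose binomial pmfs, combinatorial coefficients included."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (data.n_doses,):
        raise ValueError(f"theta must have length {data.n_doses}")
    if ((theta < 0) | (theta > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    val = 1.0
    for xi, ni, th in zip(data.x, data.n, theta):
        # 0**0 = 1 convention handles th in {0, 1} with degenerate counts
        val *= comb(ni, xi) * th**xi * (1.0 - th) ** (ni - xi)
    return float(val)


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w  # mapped to (0, 1)


def _block_stats(data: DoseData, block: Block) -> tuple[int, int]:
    sx = sum(data.x[i] for i in block.doses)
    sf = sum(data.n[i] - data.x[i] for i in block.doses)
    return sx, sf


def _binom_coef(data: DoseData) -> float:
    c = 1.0
    for xi, ni in zip(data.x, data.n):
        c *= comb(ni, xi)
    return c


def _quadrature_marginal(data: DoseData, hyp: HypothesisSpec, nodes: int) -> float:
    u, w = _gl_nodes(nodes)
    blocks = hyp.blocks
    theta0 = hyp.theta0

    def rec(idx: int, anchors: np.ndarray) -> np.ndarray:
        if idx == len(blocks):
            return np.ones_like(anchors)
        b = blocks[idx]
        sx, sf = _block_stats(data, b)
        if b.kind == "point":
            lik = theta0**sx * (1.0 - theta0) ** sf
            rest = rec(idx + 1, np.broadcast_to(np.float64(theta0), anchors.shape))
            return lik * rest
        if b.kind == "uniform":
            th = np.broadcast_to(u, anchors.shape + (nodes,))
        else:  # im
            base = anchors if b.anchor == "prev" else np.full_like(anchors, theta0)
            th = _ppf(u, base[..., None], b.tau, 1, 2.0)
        lik = th**sx * (1.0 - th) ** sf
        rest = rec(idx + 1, np.asarray(th))
        return np.sum(w * lik * rest, axis=-1)

    val = rec(0, np.zeros(()))
    return float(val) * _binom_coef(data)


def _mc_marginal(
    data: DoseData, hyp: HypothesisSpec, n_draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    theta0 = hyp.theta0
    lik = np.ones(n_draws)
    prev = np.full(n_draws, theta0)
    for b in hyp.blocks:
        sx, sf = _block_stats(data, b)
        if b.kind == "point":
            th = np.full(n_draws, theta0)
        elif b.kind == "uniform":
            th = rng.random(n_draws)
        else:
            base = prev if b.anchor == "prev" else np.full(n_draws, theta0)
            u = np.clip(rng.random(n_draws), np.finfo(float).tiny, 1 - 1e-16)
            th = np.asarray(_ppf(u, base, b.tau, 1, 2.0))
        lik *= th**sx * (1.0 - th) ** sf
        prev = th
    c = _binom_coef(data)
    est = c * float(lik.mean())
    se = c * float(lik.std(ddof=1) / np.sqrt(n_draws))
    return est, se


def marginal_likelihood(
    data: DoseData,
    hyp: HypothesisSpec,
    method: str = "quadrature",
    nodes: int = 128,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> MarginalResult:
    """Marginal likelihood p(x | hypothesis).

    Closed forms are used where they exist: an all-``point`` hypothesis is a
    pure likelihood evaluation, and a single Uniform(0,1) block shared by all
    doses gives the beta-function form
    C(n1,x1)...C(nJ,xJ) * B(sum x + 1, sum(n-x) + 1).
    """
    if hyp.n_doses != data.n_doses:
        raise ValueError("hypothesis and data dose counts differ")
    if all(b.kind == "point" for b in hyp.blocks):
        th = [hyp.theta0] * data.n_doses
        return MarginalResult(binomial_likelihood(data, th), "closed_form")
    if len(hyp.blocks) == 1 and hyp.blocks[0].kind == "uniform":
        sx = sum(data.x)
        sf = sum(data.n) - sx
        val = _binom_coef(data) * special.beta(sx + 1.0, sf + 1.0)
        return MarginalResult(float(val), "closed_form")
    if method == "quadrature":
        return MarginalResult(_quadrature_marginal(data, hyp, nodes), "quadrature")
    if method == "monte_carlo":
        rng = rng if rng is not None else np.random.default_rng(0)
        est, se = _mc_marginal(data, hyp, n_draws, rng)
        return MarginalResult(est, "monte_carlo", se)
    raise ValueError(f"unknown method {method!r}")


def posterior_hypothesis_probs(
    data: DoseData,
    hyps: Sequence[HypothesisSpec],
    prior_probs: Sequence[float],
    **kwargs,
) -> np.ndarray:
    """Posterior probabilities p(H | x) ∝ p(H) p(x | H), normalized."""
    prior = np.asarray(prior_probs, dtype=float)
    if prior.shape != (len(hyps),):
        raise ValueError("one prior probability per hypothesis required")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior probabilities must sum to 1")
    marg = np.array([marginal_likelihood(data, h, **kwargs).value for h in hyps])
    weighted = prior * marg
    total = weighted.sum()
    if total <= 0.0:
        raise ValueError("all marginal likelihoods vanished; invalid data/hypotheses")
    return weighted / total


# ---------------------------------------------------------------------------
# Standard hypothesis / model families
# ---------------------------------------------------------------------------

def two_dose_hypotheses(theta0: float, tau1: float, tau2: float) -> list[HypothesisSpec]:
    """The two-dose testing family.

    H0: theta1 = theta2 = theta0 (neither dose promising).
    H1: theta1 = theta0, theta2 ~ pi_rI(.; theta0, tau1) (only high promising).
    H2: theta1 = theta2 ~ pi_rI(.; theta0, tau1) (both promising, equal).
    H3: theta1 ~ pi_rI(.; theta0, tau1), theta2 ~ pi_rI(.; theta1, tau2)
        (both promising, high strictly better).
    """
    return [
        HypothesisSpec("H0", (Block((0, 1), "point"),), theta0),
        HypothesisSpec(
            "H1", (Block((0,), "point"), Block((1,), "im", "theta0", tau1)), theta0
        ),
        HypothesisSpec("H2", (Block((0, 1), "im", "theta0", tau1),), theta0),
        HypothesisSpec(
            "H3",
            (Block((0,), "im", "theta0", tau1), Block((1,), "im", "prev", tau2)),
            theta0,
        ),
    ]


def three_dose_hypotheses(theta0: float, tau1: float, tau2: float) -> list[HypothesisSpec]:
    """The eight-hypothesis three-dose extension of the testing family."""
    im0 = lambda d: Block(d, "im", "theta0", tau1)  # noqa: E731
    prev1 = lambda d: Block(d, "im", "prev", tau1)  # noqa: E731
    return [
        HypothesisSpec("H0", (Block((0, 1, 2), "point"),), theta0),
        HypothesisSpec("H1", (Block((0, 1), "point"), im0((2,))), theta0),
        HypothesisSpec("H2", (Block((0,), "point"), im0((1, 2))), theta0),
        HypothesisSpec(
            "H3",
            (Block((0,), "point"), im0((1,)), Block((2,), "im", "prev", tau2)),
            theta0,
        ),
        HypothesisSpec("H4", (im0((0, 1, 2)),), theta0),
        HypothesisSpec("H5", (im0((0,)), prev1((1, 2))), theta0),
        HypothesisSpec("H6", (im0((0, 1)), prev1((2,))), theta0),
        HypothesisSpec("H7", (im0((0,)), prev1((1,)), prev1((2,))), theta0),
    ]


def bma_models(n_doses: int, tau2: float) -> list[HypothesisSpec]:
    """Model-averaging families: {M1, M2} for two doses, {M1..M4} for three.

    The shared lowest block is Uniform(0, 1); each strictly higher block
    follows a restricted inverse-moment prior anchored at the previous
    block's rate, so the rates are strictly ordered under each model beyond
    M1.
    """
    if n_doses == 2:
        return [
            HypothesisSpec("M1", (Block((0, 1), "uniform"),)),
            HypothesisSpec(
                "M2", (Block((0,), "uniform"), Block((1,), "im", "prev", tau2))
            ),
        ]
    if n_doses == 3:
        prev = lambda d: Block(d, "im", "prev", tau2)  # noqa: E731
        return [
            HypothesisSpec("M1", (Block((0, 1, 2), "uniform"),)),
            HypothesisSpec("M2", (Block((0, 1), "uniform"), prev((2,)))),
            HypothesisSpec("M3", (Block((0,), "uniform"), prev((1, 2)))),
            HypothesisSpec("M4", (Block((0,), "uniform"), prev((1,)), prev((2,)))),
        ]
    raise ValueError("model averaging supports 2 or 3 doses")


def single_arm_hypotheses(theta0: float, tau1: float) -> list[HypothesisSpec]:
    """Single-arm pair: H0i (rate = theta0) vs H1i (rate ~ pi_rI(theta0, tau1))."""
    return [
        HypothesisSpec("H0i", (Block((0,), "point"),), theta0),
        HypothesisSpec("H1i", (Block((0,), "im", "theta0", tau1),), theta0),
    ]


class _CompiledHypothesis:
    """Pre-tabulated quadrature for one hypothesis.

    The Gauss-Legendre node positions (after the per-block inverse-CDF
    change of variables) and the tensor-product weights do not depend on
    the data, so they are built once; a marginal likelihood evaluation then
    reduces to a handful of vectorized power operations.
    """

    def __init__(self, hyp: HypothesisSpec, nodes: int):
        self.hyp = hyp
        u, w = _gl_nodes(nodes)
        thetas: list[np.ndarray] = []      # one array per block, common shape
        weights = np.ones(())
        prev = np.float64(hyp.theta0)
        for b in hyp.blocks:
            if b.kind == "point":
                th = np.broadcast_to(np.float64(hyp.theta0), weights.shape)
            elif b.kind == "uniform":
                th = np.broadcast_to(u, weights.shape + (nodes,))
                weights = weights[..., None] * w
            else:
                base = prev if b.anchor == "prev" else np.full_like(np.asarray(prev), hyp.theta0)
                th = np.asarray(_ppf(u, np.asarray(base)[..., None], b.tau, 1, 2.0))
                weights = weights[..., None] * w
            thetas = [np.broadcast_to(t[..., None], th.shape) if t.shape != th.shape else t
                      for t in thetas]
            thetas.append(np.asarray(th))
            prev = th
        shape = weights.shape
        self.weights = weights.ravel()
        self.block_thetas = [
            np.broadcast_to(t[(...,) + (None,) * (len(shape) - t.ndim)], shape).ravel()
            if t.shape != shape else t.ravel()
            for t in thetas
        ]
        self.block_doses = [b.doses for b in hyp.blocks]

    def value(self, data: DoseData) -> float:
        acc = self.weights
        for doses, th in zip(self.block_doses, self.block_thetas):
            sx = sum(data.x[i] for i in doses)
            sf = sum(data.n[i] - data.x[i] for i in doses)
            if sx:
                acc = acc * th**sx
            if sf:
                acc = acc * (1.0 - th) ** sf
        return float(acc.sum()) * _binom_coef(data)


class FamilyMarginals:
    """Cached marginal likelihoods for a fixed hypothesis family.

    Continuous monitoring revisits a small lattice of sufficient statistics
    (x, n) thousands of times across simulated trials; marginals depend on
    the data only through that lattice, so one dictionary lookup replaces
    the quadrature almost always, and cache misses use pre-tabulated
    quadrature nodes.
    """

    def __init__(self, hyps: Sequence[HypothesisSpec], nodes: int = 128):
        self.hyps = list(hyps)
        self.nodes = nodes
        self._compiled = [_CompiledHypothesis(h, nodes) for h in self.hyps]
        self._cache: dict[tuple, np.ndarray] = {}
        self.hits = 0
        self.misses = 0

    def marginals(self, data: DoseData) -> np.ndarray:
        key = data.key()
        out = self._cache.get(key)
        if out is not None:
            self.hits += 1
            return out
        self.misses += 1
        out = np.array([c.value(data) for c in self._compiled])
        self._cache[key] = out
        return out

    def posteriors(self, data: DoseData, prior_probs: Sequence[float]) -> np.ndarray:
        prior = np.asarray(prior_probs, dtype=float)
        weighted = prior * self.marginals(data)
        total = weighted.sum()
        if total <= 0.0:
            raise ValueError("all marginal likelihoods vanished")
        return weighted / total

    @property
    def hit_rate(self) -> float:
        total = self.hits + self.misses
        return self.hits / total if total else 0.0
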