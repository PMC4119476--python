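"""Restricted inverse-moment (nonlocal) prior densities.

The inverse-moment prior is a *nonlocal* alternative prior: its density
vanishes at the null value ``theta'``, so data generated under the null
accumulate evidence against the alternative at an exponential rate instead
of the sublinear rate typical of local alternatives.  The unrestricted
density on the real line is

    pi_I(theta; theta', k, nu, tau)
        = k * tau^(nu/2) / Gamma(nu/(2k))
          * ((theta - theta')^2)^(-(nu+1)/2)
          * exp(-((theta - theta')^2 / tau)^(-k)),

and trial designs use it *restricted* to the interval ``(theta', 1)`` and
renormalized, written ``pi_rI``.

A substitution makes everything analytic: with
``w = ((theta - theta')^2 / tau)^(-k)``, the right half of the density maps
to a Gamma(nu/(2k), 1) distribution in ``w``.  The restriction
``theta' < theta < 1`` becomes the truncation ``w >= w_min`` with
``w_min = ((1 - theta')^2 / tau)^(-k)``, so normalizing constants, CDFs,
quantiles and exact samples all come from the (regularized) incomplete
gamma function.  For the default ``k=1, nu=2`` this reduces to the familiar
closed form ``P(theta' < theta < 1) = 0.5 * exp(-tau * (1 - theta')^-2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "IMPriorSpec",
    "im_density",
    "restricted_normalizer",
    "restricted_im_density",
    "restricted_im_cdf",
    "restricted_im_ppf",
    "im_mode",
    "sample_restricted_im",
]


@dataclass(frozen=True)
class IMPriorSpec:
    """Hyperparameters of an inverse-moment prior restricted to (null_value, 1).

    Parameters
    ----------
    null_value
        The null rate theta' at which the density vanishes; in [0, 1).
    tau
        Scale parameter; larger tau pushes the prior mode away from the null.
    k
        Shape integer (default 1, the value used throughout the designs).
    nu
        Shape parameter (default 2).
    """

    null_value: float
    tau: float
    k: int = 1
    nu: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_value < 1.0:
            raise ValueError(f"null_value must be in [0, 1), got {self.null_value}")
        if not self.tau > 0.0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if not self.nu > 0.0:
            raise ValueError(f"nu must be positive, got {self.nu}")

    @property
    def gamma_shape(self) -> float:
        """Shape nu/(2k) of the Gamma law of w = ((theta-theta')^2/tau)^(-k)."""
        return self.nu / (2.0 * self.k)


def im_density(theta, spec: IMPriorSpec):
    """Unrestricted inverse-moment density pi_I at ``theta``.

    Vectorized over ``theta``.  The value at ``theta == null_value`` is 0
    (continuous extension: the essential singularity of the exponential
    dominates the pole).
    """
    theta = np.asarray(theta, dtype=float)
    d2 = (theta - spec.null_value) ** 2
    const = spec.k * spec.tau ** (spec.nu / 2.0) / special.gamma(spec.gamma_shape)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        out = const * d2 ** (-(spec.nu + 1.0) / 2.0) * np.exp(-((d2 / spec.tau) ** (-spec.k)))
    out = np.where(d2 == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def _w_of(theta, anchor, tau, k):
    return (((theta - anchor) ** 2) / tau) ** (-k)


def restricted_normalizer(spec: IMPriorSpec) -> float:
    """P(null_value < theta < 1) under the unrestricted density.

    Analytic for every (k, nu) through the regularized upper incomplete
    gamma function; equals 0.5*exp(-tau*(1-theta')^-2) for k=1, nu=2.
    """
    w_min = _w_of(1.0, spec.null_value, spec.tau, spec.k)
    return 0.5 * float(special.gammaincc(spec.gamma_shape, w_min))


def restricted_im_density(theta, spec: IMPriorSpec):
    """Density of pi_rI: pi_I truncated to (null_value, 1) and renormalized."""
    theta = np.asarray(theta, dtype=float)
    inside = (theta > spec.null_value) & (theta < 1.0)
    out = np.where(inside, im_density(theta, spec) / restricted_normalizer(spec), 0.0)
    return out if out.ndim else float(out)


def restricted_im_cdf(theta, spec: IMPriorSpec):
    """CDF of pi_rI at ``theta`` (vectorized)."""
    theta = np.asarray(theta, dtype=float)
    a = spec.gamma_shape
    w_min = _w_of(1.0, spec.null_value, spec.tau, spec.k)
    denom = special.gammaincc(a, w_min)
    clipped = np.clip(theta, np.nextafter(spec.null_value, 1.0), 1.0)
    w = _w_of(clipped, spec.null_value, spec.tau, spec.k)
    cdf = special.gammaincc(a, w) / denom
    cdf = np.where(theta <= spec.null_value, 0.0, np.where(theta >= 1.0, 1.0, cdf))
    return cdf if cdf.ndim else float(cdf)


def restricted_im_ppf(u, spec: IMPriorSpec):
    """Quantile function of pi_rI; exact inverse of :func:`restricted_im_cdf`."""
    return _ppf(u, spec.null_value, spec.tau, spec.k, spec.nu)


def _ppf(u, anchor, tau, k, nu):
    """Vectorized quantile of pi_rI with an array-valued anchor.

    Used by the marginal-likelihood integrators, which need quantiles of a
    prior anchored at the *previous* dose's (node-dependent) response rate.
    ``u`` and ``anchor`` broadcast against each other.
    """
    u = np.asarray(u, dtype=float)
    anchor = np.asarray(anchor, dtype=float)
    a = nu / (2.0 * k)
    w_min = (((1.0 - anchor) ** 2) / tau) ** (-k)
    denom = special.gammaincc(a, w_min)
    w = special.gammainccinv(a, u * denom)
    theta = anchor + np.sqrt(tau) * w ** (-1.0 / (2.0 * k))
    return theta if theta.ndim else float(theta)


def im_mode(spec: IMPriorSpec) -> float:
    """Location of the maximum of pi_rI on (null_value, 1).

    Setting d/dtheta log pi_I = 0 gives the offset above the null value in
    closed form: ``(2 k tau^k / (nu+1))^(1/(2k))``, i.e. sqrt(2*tau/(nu+1))
    for k=1.  A warning is raised if the mode falls at or beyond 1, where
    the restricted prior is monotone increasing on its support.
    """
    offset = (2.0 * spec.k * spec.tau**spec.k / (spec.nu + 1.0)) ** (1.0 / (2.0 * spec.k))
    mode = spec.null_value + offset
    if mode >= 1.0:
        warnings.warn(
            f"prior mode {mode:.4f} lies at or beyond 1; tau={spec.tau} is too "
            "large for the support (theta', 1)",
            stacklevel=2,
        )
    return mode


def quadrature_normalizer(spec: IMPriorSpec) -> float:
    """Adaptive-quadrature evaluation of P(null_value < theta < 1).

    Independent check of :func:`restricted_normalizer`; the integrand is
    near-singularly peaked for small tau, so the integral is split at the
    mode.
    """
    offset = (2.0 * spec.k * spec.tau**spec.k / (spec.nu + 1.0)) ** (1.0 / (2.0 * spec.k))
    split = min(spec.null_value + offset, 1.0 - 1e-12)
    lo, _ = integrate.quad(
        lambda t: im_density(t, spec), spec.null_value, split, limit=200, epsabs=1e-10
    )
    hi, _ = integrate.quad(lambda t: im_density(t, spec), split, 1.0, limit=200, epsabs=1e-10)
    return lo + hi


def sample_restricted_im(spec: IMPriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. samples from pi_rI by exact inverse-CDF sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    # u = 0 would map to theta = 1 exactly; keep draws in the open interval.
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).eps)
    return np.asarray(_ppf(u, spec.null_value, spec.tau, spec.k, spec.nu))
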