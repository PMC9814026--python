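"""Hyperparameter priors on the transformed (theta) scale.

Variance-type parameters carry exponential priors on their natural scale
(standard deviation sigma, or Matern practical range rho) — the
penalized-complexity choice for a standard deviation.  Internally every
hyperparameter is a coordinate of an unconstrained vector theta via one of
the transformations

* ``theta = -2 log sigma``   (smooth-term and frailty SDs),
* ``theta = log sigma``      (Matern marginal SD),
* ``theta = log rho``        (Matern practical range),

and the log prior density on the theta scale includes the Jacobian of the
change of variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorSpec",
    "rate_from_median",
    "rate_from_tail",
    "exponential_prior",
    "gaussian_prior",
    "log_prior_theta",
    "dlog_prior_theta",
]

TRANSFORMS = ("minus_two_log_sigma", "log_sigma", "log_range")


@dataclass(frozen=True)
class PriorSpec:
    """One hyperparameter coordinate's prior.

    ``family`` is ``"exponential"`` (rate ``rate`` on the sigma/rho scale)
    or ``"gaussian"`` (mean zero, SD ``rate`` directly on the theta scale).
    """

    family: str
    rate: float
    transformation: str = "minus_two_log_sigma"

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError(f"prior rate must be positive, got {self.rate}")
        if self.family not in ("exponential", "gaussian"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.transformation not in TRANSFORMS:
            raise ValueError(f"unknown transformation {self.transformation!r}")

    # natural-scale value for a given theta coordinate
    def natural(self, theta: float) -> float:
        if self.transformation == "minus_two_log_sigma":
            return float(np.exp(-theta / 2.0))
        return float(np.exp(theta))

    def theta_of(self, natural: float) -> float:
        if self.transformation == "minus_two_log_sigma":
            return float(-2.0 * np.log(natural))
        return float(np.log(natural))


def rate_from_median(median: float) -> float:
    """Exponential rate with the given median: lambda = log(2)/median."""
    if median <= 0:
        raise ValueError("median must be positive")
    return float(np.log(2.0) / median)


def rate_from_tail(quantile: float, tail_prob: float) -> float:
    """Exponential rate with P(X > quantile) = tail_prob."""
    if not 0 < tail_prob < 1:
        raise ValueError("tail probability must lie in (0, 1)")
    if quantile <= 0:
        raise ValueError("quantile must be positive")
    return float(-np.log(tail_prob) / quantile)


def exponential_prior(
    median: float | None = None,
    tail: tuple[float, float] | None = None,
    transformation: str = "minus_two_log_sigma",
) -> PriorSpec:
    """Exponential prior specified through its median or a tail probability."""
    if (median is None) == (tail is None):
        raise ValueError("specify exactly one of median= or tail=(q, p)")
    rate = rate_from_median(median) if median is not None else rate_from_tail(*tail)
    return PriorSpec("exponential", rate, transformation)


def gaussian_prior(sd: float) -> PriorSpec:
    return PriorSpec("gaussian", sd, "log_sigma")


def _log_density_one(spec: PriorSpec, th: float) -> float:
    if spec.family == "gaussian":
        return -0.5 * np.log(2 * np.pi) - np.log(spec.rate) - 0.5 * (th / spec.rate) ** 2
    lam = spec.rate
    if spec.transformation == "minus_two_log_sigma":
        # sigma = e^{-theta/2}, |dsigma/dtheta| = sigma/2
        return np.log(lam / 2.0) - lam * np.exp(-th / 2.0) - th / 2.0
    # log_sigma / log_range: x = e^theta, |dx/dtheta| = x
    return np.log(lam) - lam * np.exp(th) + th


def _dlog_density_one(spec: PriorSpec, th: float) -> float:
    if spec.family == "gaussian":
        return -th / spec.rate**2
    lam = spec.rate
    if spec.transformation == "minus_two_log_sigma":
        return 0.5 * lam * np.exp(-th / 2.0) - 0.5
    return -lam * np.exp(th) + 1.0


def log_prior_theta(specs, theta) -> float:
    """Joint log prior of theta (sum over independent coordinates)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if len(specs) != theta.size:
        raise ValueError("theta length does not match number of prior specs")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite theta")
    return float(sum(_log_density_one(s, t) for s, t in zip(specs, theta)))


def dlog_prior_theta(specs, theta) -> np.ndarray:
    """Gradient of :func:`log_prior_theta` in theta."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    return np.array([_dlog_density_one(s, t) for s, t in zip(specs, theta)])
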