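"""Synthetic survival data emulating the package's two validation designs.

Survival times are drawn by inverse-transform sampling through the
cumulative baseline hazard: with E ~ Exponential(1),

    T = H0^{-1}( E * exp(-eta) ),

exact for piecewise-constant and piecewise-linear baseline hazards (the
cumulative hazard is piecewise linear/quadratic with a closed-form
inverse).  Right censoring selects a fixed fraction of observations
uniformly at random and replaces each selected time t by c ~ Uniform(0, t)
— a random censoring mechanism, so independent censoring holds by
construction.

Two study designs are provided:

* study 1 ("sparse frailties"): n = 60 groups of m observations each,
  i.i.d. frailties xi_i ~ N(0, sigma_xi^2), a standard-normal covariate
  with linear effect beta = 0.2, a simple two-level step baseline and 10%
  censoring.  The estimand of interest is the frailty vector and its SD.
* study 2 ("nonlinear effect"): n independent records, u ~ Uniform(-6, 6),
  eta = gamma(u) = 1.5 [sin(0.8 u) + 1], 10% censoring, with a choice of
  step / oscillating / ramp ("complicated") baselines of increasing
  wiggliness.  The estimand is gamma on the observed u.

The three baseline shapes are package defaults chosen to span the
qualitative regimes (flat, rapidly alternating, mixed ramp/constant); all
are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survdata import SurvivalDataset, dataset_from_frame

__all__ = [
    "BaselineHazard",
    "simple_step_baseline",
    "oscillating_baseline",
    "complicated_baseline",
    "SimulationTruth",
    "sample_survival_times",
    "apply_random_censoring",
    "simulate_study1",
    "simulate_study2",
    "true_gamma",
    "replication_metrics",
]


@dataclass
class BaselineHazard:
    """Piecewise linear-constant hazard with closed-form H0 and inverse.

    Segment i covers [breaks[i], breaks[i+1]) with hazard
    value[i] + slope[i] * (t - breaks[i]); the final segment extends to
    infinity (its slope must be zero or positive with positive value so the
    cumulative hazard is unbounded).
    """

    breaks: np.ndarray
    values: np.ndarray
    slopes: np.ndarray = None

    def __post_init__(self):
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.slopes is None:
            self.slopes = np.zeros_like(self.values)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if len(self.values) != len(self.breaks) or len(self.slopes) != len(self.breaks):
            raise ValueError("breaks, values and slopes must have equal length")
        if self.breaks[0] != 0:
            raise ValueError("first breakpoint must be 0")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breakpoints must be increasing")
        widths = np.diff(self.breaks)
        ends = self.values[:-1] + self.slopes[:-1] * widths
        if np.any(self.values < 0) or np.any(ends < 0):
            raise ValueError("hazard must be nonnegative")
        # cumulative hazard at each breakpoint
        seg = widths * self.values[:-1] + 0.5 * self.slopes[:-1] * widths**2
        self.cum_at_breaks = np.concatenate([[0.0], np.cumsum(seg)])
        if self.values[-1] <= 0 and self.slopes[-1] <= 0:
            raise ValueError("final segment must have positive hazard mass")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(self.breaks, t, side="right") - 1,
                    0, len(self.breaks) - 1)
        return self.values[i] + self.slopes[i] * (t - self.breaks[i])

    def cumulative(self, t):
        """H0(t), continuous and strictly increasing where hazard > 0."""
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(self.breaks, t, side="right") - 1,
                    0, len(self.breaks) - 1)
        dt = t - self.breaks[i]
        return self.cum_at_breaks[i] + self.values[i] * dt + 0.5 * self.slopes[i] * dt**2

    def inverse_cumulative(self, h):
        """H0^{-1}(h): per-segment linear or quadratic closed form."""
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("cumulative hazard must be nonnegative")
        i = np.clip(np.searchsorted(self.cum_at_breaks, h, side="right") - 1,
                    0, len(self.breaks) - 1)
        rem = h - self.cum_at_breaks[i]
        a, b = 0.5 * self.slopes[i], self.values[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            lin = rem / b
            quad = (-b + np.sqrt(b**2 + 4 * a * rem)) / (2 * a)
        dt = np.where(np.abs(a) > 0, quad, lin)
        # segments with zero hazard cannot absorb mass; rem should be ~0 there
        dt = np.where(np.isfinite(dt), dt, 0.0)
        return self.breaks[i] + dt


def simple_step_baseline() -> BaselineHazard:
    """Two-level step: 0.05 on [0, 15), 0.15 afterwards."""
    return BaselineHazard(breaks=[0.0, 15.0], values=[0.05, 0.15])


def oscillating_baseline(horizon: float = 2000.0) -> BaselineHazard:
    """Alternating step 0.05 / 0.25 with period 5 out to the horizon."""
    edges = np.arange(0.0, horizon, 5.0)
    vals = np.where((np.arange(len(edges)) % 2) == 0, 0.05, 0.25)
    vals[-1] = 0.25   # unbounded tail keeps H0 invertible everywhere
    return BaselineHazard(breaks=edges, values=vals)


def complicated_baseline(horizon: float = 2000.0) -> BaselineHazard:
    """Alternating ramps (slope +/-0.04) and constants on length-2 pieces.

    Pattern per period 8: constant 0.01, ramp up to 0.09, constant 0.09,
    ramp down to 0.01; hazard floor 0.01.
    """
    edges = np.arange(0.0, horizon, 2.0)
    n = len(edges)
    vals = np.empty(n)
    slopes = np.zeros(n)
    for j in range(n):
        phase = j % 4
        if phase == 0:
            vals[j] = 0.01
        elif phase == 1:
            vals[j], slopes[j] = 0.01, 0.04
        elif phase == 2:
            vals[j] = 0.09
        else:
            vals[j], slopes[j] = 0.09, -0.04
    vals[-1], slopes[-1] = 0.05, 0.0
    return BaselineHazard(breaks=edges, values=vals, slopes=slopes)


BASELINES = {
    "simple": simple_step_baseline,
    "oscillating": oscillating_baseline,
    "complicated": complicated_baseline,
}


@dataclass
class SimulationTruth:
    seed: int
    censor_rate: float
    true_beta: np.ndarray | None = None
    true_frailties: np.ndarray | None = None
    true_sigma_xi: float | None = None
    true_gamma_values: np.ndarray | None = None
    eta: np.ndarray | None = None
    uncensored_times: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def sample_survival_times(h0: BaselineHazard, eta, seed) -> np.ndarray:
    """Inverse-transform survival times t = H0^{-1}(E exp(-eta))."""
    eta = np.asarray(eta, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    E = rng.exponential(size=eta.shape)
    return h0.inverse_cumulative(E * np.exp(-eta))


def apply_random_censoring(times, rate: float, seed):
    """Censor a uniformly random round(rate*N) subset at c ~ Uniform(0, t)."""
    times = np.asarray(times, dtype=float)
    if not 0 <= rate < 1:
        raise ValueError("censoring rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = times.size
    n_cens = int(round(rate * n))
    y = times.copy()
    d = np.ones(n, dtype=int)
    if n_cens:
        sel = rng.choice(n, size=n_cens, replace=False)
        y[sel] = rng.uniform(0.0, times[sel])
        d[sel] = 0
    return y, d


def simulate_study1(m: int = 2, sigma_xi: float = 1.0, seed: int = 0,
                    n_groups: int = 60, beta: float = 0.2,
                    censor_rate: float = 0.1,
                    baseline: BaselineHazard | None = None,
                    group_sizes=None):
    """Sparse-frailty design: n_groups groups of m observations each.

    ``group_sizes`` overrides the constant group size with an explicit
    per-group vector (varying-group-size variant).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = (np.full(n_groups, m, dtype=int) if group_sizes is None
             else np.asarray(group_sizes, dtype=int))
    N = int(sizes.sum())
    groups = np.repeat(np.arange(n_groups), sizes)
    xi = rng.normal(0.0, sigma_xi, size=n_groups) if sigma_xi > 0 else np.zeros(n_groups)
    x = rng.normal(size=N)
    eta = beta * x + xi[groups]
    h0 = baseline or simple_step_baseline()
    t = sample_survival_times(h0, eta, rng)
    y, d = apply_random_censoring(t, censor_rate, rng)
    df = pd.DataFrame({"group": groups, "time": y, "status": d, "x": x})
    data = dataset_from_frame(df)
    truth = SimulationTruth(
        seed=seed, censor_rate=censor_rate, true_beta=np.array([beta]),
        true_frailties=xi, true_sigma_xi=sigma_xi, eta=eta,
        uncensored_times=t,
    )
    return data, truth


def true_gamma(u):
    """The sinusoidal nonlinear effect gamma(u) = 1.5 [sin(0.8 u) + 1]."""
    return 1.5 * (np.sin(0.8 * np.asarray(u, dtype=float)) + 1.0)


def simulate_study2(baseline: str = "simple", seed: int = 0, n: int = 1000,
                    censor_rate: float = 0.1):
    """Nonlinear-effect design: n independent records, u ~ Uniform(-6, 6)."""
    if baseline not in BASELINES:
        raise ValueError(
            f"unknown baseline {baseline!r}; choose from {sorted(BASELINES)}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-6.0, 6.0, size=n)
    eta = true_gamma(u)
    h0 = BASELINES[baseline]()
    t = sample_survival_times(h0, eta, rng)
    y, d = apply_random_censoring(t, censor_rate, rng)
    df = pd.DataFrame({"group": np.arange(n), "time": y, "status": d, "u": u})
    data = dataset_from_frame(df)
    truth = SimulationTruth(
        seed=seed, censor_rate=censor_rate, true_gamma_values=eta,
        eta=eta, uncensored_times=t,
    )
    return data, truth


def replication_metrics(estimates, truths, intervals=None):
    """Posterior-mean MSE and credible-interval coverage across estimands."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths have different shapes")
    mse = float(np.mean((estimates - truths) ** 2))
    coverage = None
    if intervals is not None:
        lo, hi = np.asarray(intervals[0], float), np.asarray(intervals[1], float)
        if lo.shape != truths.shape or hi.shape != truths.shape:
            raise ValueError("interval arrays do not match truths")
        coverage = float(np.mean((truths >= lo) & (truths <= hi)))
    return mse, coverage
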