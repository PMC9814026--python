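"""Log partial likelihood of the Cox model and its derivatives in W.

For events e with risk sets R_e (Breslow ties),

    l(eta) = sum_e [ eta_e - log sum_{k in R_e} exp(eta_k) ].

Evaluation sorts the observations by time once and sweeps a reverse
cumulative sum of exp(eta) (stabilized by subtracting the running maximum),
so cost is O(N log N) rather than O(N^2).

Derivatives are taken with respect to the latent vector W through the
linear map eta = X W:

    grad = X' g,          g_i = d_i - exp(eta_i) * sum_{e: i in R_e} 1/S_e,
    hess = -X' [ sum_e ( diag(p_e) - p_e p_e' ) ] X,   p_e = w 1_{R_e} / S_e,

accumulated with reverse cumulative sums of w x and w x x', so the dense
dim(W) x dim(W) Hessian costs O(N dim(W)^2).  l is concave in eta and
invariant to adding a constant to eta (no global intercept is estimable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survdata import RiskSetIndex

__all__ = [
    "CoxPartialLikelihood",
    "PredictorState",
    "LikelihoodDerivatives",
    "log_partial_likelihood",
    "delta_from_eta",
    "derivatives",
]


@dataclass
class PredictorState:
    """eta and its differenced form Delta_ij = eta_ref - eta_ij."""

    eta: np.ndarray
    delta: np.ndarray
    reference_index: int


@dataclass
class LikelihoodDerivatives:
    value: float
    gradient: np.ndarray
    hessian: np.ndarray   # d^2 l / dW dW' (negative semidefinite)


def delta_from_eta(eta, reference_index: int = 0) -> PredictorState:
    """Differenced predictors relative to a reference observation.

    The likelihood depends on eta only through these differences, so every
    result is invariant to the choice of reference.
    """
    eta = np.asarray(eta, dtype=float)
    if not 0 <= reference_index < eta.size:
        raise IndexError(f"reference index {reference_index} out of range")
    delta = eta[reference_index] - eta
    return PredictorState(eta=eta, delta=delta, reference_index=reference_index)


class CoxPartialLikelihood:
    """Breslow-ties log partial likelihood bound to a risk-set index."""

    def __init__(self, risk: RiskSetIndex):
        self.risk = risk
        n = risk.n
        # scatter: events whose risk span starts at sorted position p
        self._start_counts = np.bincount(risk.risk_start, minlength=n)
        self._event_mask_sorted = risk.sorted_events == 1

    # -- value --------------------------------------------------------------

    def _sorted_quantities(self, eta):
        """Common pieces on the time-sorted array.

        Returns (eta_sorted, w, S, logS) where w = exp(eta - m) and
        S[e] = sum_{k in R_e} w_k for each event e.
        """
        eta = np.asarray(eta, dtype=float)
        if eta.size != self.risk.n:
            raise ValueError("eta length does not match dataset")
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite eta")
        es = eta[self.risk.order]
        m = es.max()
        w = np.exp(es - m)
        rev = np.cumsum(w[::-1])[::-1]      # rev[p] = sum_{k >= p} w_k
        S = rev[self.risk.risk_start]
        if S.size and S.min() <= 0.0:       # eta spread beyond exp range
            raise FloatingPointError("risk-set sum underflowed: eta too extreme")
        return es, w, S, m

    def value(self, eta) -> float:
        es, _, S, m = self._sorted_quantities(eta)
        return float(np.sum(es[self.risk.event_positions] - m - np.log(S)))

    # -- derivatives in eta ------------------------------------------------

    def grad_eta(self, eta) -> np.ndarray:
        _, w, S, _ = self._sorted_quantities(eta)
        # C[p] = sum over events with risk_start <= p of 1/S_e
        r = np.zeros(self.risk.n)
        np.add.at(r, self.risk.risk_start, 1.0 / S)
        C = np.cumsum(r)
        g_sorted = self._event_mask_sorted.astype(float) - w * C
        g = np.empty_like(g_sorted)
        g[self.risk.order] = g_sorted
        return g

    def hess_eta_dense(self, eta) -> np.ndarray:
        """Dense N x N Hessian of l in eta (for modest N; testing aid)."""
        _, w, S, _ = self._sorted_quantities(eta)
        n = self.risk.n
        H = np.zeros((n, n))
        for e in range(self.risk.n_events):
            span = np.arange(self.risk.risk_start[e], n)
            p = np.zeros(n)
            p[span] = w[span] / S[e]
            H -= np.diag(p) - np.outer(p, p)
        inv = np.empty(n, dtype=int)
        inv[self.risk.order] = np.arange(n)
        return H[np.ix_(inv, inv)]

    def value_grad_hessquad(self, eta, X):
        """(l, X' g, X' H_eta X) with the cumulative-sum sweep.

        ``X`` is the N x d design map from W to eta (input order).
        """
        es, w, S, m = self._sorted_quantities(eta)
        n = self.risk.n
        value = float(np.sum(es[self.risk.event_positions] - m - np.log(S)))

        r = np.zeros(n)
        np.add.at(r, self.risk.risk_start, 1.0 / S)
        C = np.cumsum(r)
        g_sorted = self._event_mask_sorted.astype(float) - w * C
        grad_eta = np.empty(n)
        grad_eta[self.risk.order] = g_sorted
        grad = X.T @ grad_eta

        Xs = X[self.risk.order]
        wx = Xs * w[:, None]
        # reverse cumulative sums of w x and w x x'
        Ux = np.cumsum(wx[::-1], axis=0)[::-1]                     # n x d
        wxx = np.einsum("ni,nj->nij", wx, Xs)
        Uxx = np.cumsum(wxx[::-1], axis=0)[::-1]                   # n x d x d
        starts = self.risk.risk_start
        a = Ux[starts]                                             # e x d
        term1 = np.einsum("e,eij->ij", 1.0 / S, Uxx[starts])
        term2 = np.einsum("e,ei,ej->ij", 1.0 / S**2, a, a)
        hess = -(term1 - term2)
        return value, grad, 0.5 * (hess + hess.T)


def log_partial_likelihood(eta, risk: RiskSetIndex) -> float:
    """l(eta) under the Breslow tie convention."""
    return CoxPartialLikelihood(risk).value(eta)


def derivatives(spec, W, risk: RiskSetIndex) -> LikelihoodDerivatives:
    """l, gradient and dense Hessian of l(eta(W)) with respect to W."""
    X = spec.design_matrix
    eta = spec.eta_from_W(np.asarray(W, dtype=float))
    lik = CoxPartialLikelihood(risk)
    value, grad, hess = lik.value_grad_hessquad(eta, X)
    return LikelihoodDerivatives(value=value, gradient=grad, hessian=hess)
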