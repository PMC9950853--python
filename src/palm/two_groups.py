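"""Beta/uniform two-groups mixture: densities, posteriors and closed-form updates.

Each p-value is modelled as drawn from a null group (uniform on (0,1)) or a
non-null group (Beta(alpha, 1) with 0 < alpha < 1, concentrating mass near 0).
The prior probability of the non-null group may vary per SNP; the intercept-only
fit (:func:`fit_tgm`) is the classic two-groups baseline that uses p-values only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

P_FLOOR = 1e-300
ALPHA_EPS = 1e-6

__all__ = [
    "P_FLOOR",
    "ALPHA_EPS",
    "TGMFit",
    "clip_pvalues",
    "beta_density",
    "log_beta_density",
    "posterior_responsibility",
    "update_alpha",
    "marginal_loglik",
    "fit_tgm",
]


def clip_pvalues(p) -> np.ndarray:
    """Clip p-values into [P_FLOOR, 1] so that log(p) and Beta densities stay finite."""
    p = np.asarray(p, dtype=float)
    return np.clip(p, P_FLOOR, 1.0)


def _check_p(p: np.ndarray) -> None:
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; clip input with clip_pvalues()")


def _check_alpha(alpha: float) -> None:
    if not (0 < alpha < 1 or alpha == 1.0):
        # alpha == 1 (uniform non-null) is allowed for degenerate/testing use
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")


def beta_density(p, alpha: float):
    """Density of Beta(alpha, 1) at p: alpha * p**(alpha - 1)."""
    p = np.asarray(p, dtype=float)
    _check_p(p)
    _check_alpha(alpha)
    out = alpha * p ** (alpha - 1.0)
    return out if out.ndim else float(out)


def log_beta_density(p, alpha: float):
    """log of :func:`beta_density`, safe for p down to P_FLOOR."""
    p = np.asarray(p, dtype=float)
    _check_p(p)
    _check_alpha(alpha)
    out = np.log(alpha) + (alpha - 1.0) * np.log(p)
    return out if out.ndim else float(out)


def posterior_responsibility(p, pi1, alpha: float):
    """Posterior probability that each SNP is non-null.

    q_j1 = pi_j1 * phi(p_j; alpha) / (pi_j0 + pi_j1 * phi(p_j; alpha)),
    computed on the log scale to tolerate extreme p-values and priors.
    """
    p = np.asarray(p, dtype=float)
    pi1 = np.asarray(pi1, dtype=float)
    log_phi = log_beta_density(p, alpha)
    with np.errstate(divide="ignore"):
        logit_prior = np.log(pi1) - np.log1p(-pi1)
    q1 = expit(logit_prior + log_phi)
    return q1 if q1.ndim else float(q1)


def update_alpha(q1, p, prev_alpha: float | None = None) -> float:
    """Closed-form maximizer of the expected complete-data log-likelihood in alpha.

    alpha = -sum(q1) / sum(q1 * log p), clamped into (ALPHA_EPS, 1 - ALPHA_EPS).
    If no posterior mass is assigned to the non-null group the previous alpha is
    returned unchanged (with a warning).
    """
    q1 = np.asarray(q1, dtype=float)
    p = np.asarray(p, dtype=float)
    _check_p(p)
    num = float(q1.sum())
    if num <= 0:
        warnings.warn("update_alpha: no non-null posterior mass; keeping previous alpha")
        return prev_alpha if prev_alpha is not None else 0.5
    denom = float(np.dot(q1, np.log(p)))
    if denom == 0.0:
        # all posterior mass sits at p = 1: the maximizer does not exist
        # (Q increases toward alpha = 1); keep the previous alpha so the
        # uninformative non-null component cannot masquerade as uniform
        return prev_alpha if prev_alpha is not None else 0.5
    return float(np.clip(-num / denom, ALPHA_EPS, 1.0 - ALPHA_EPS))


def marginal_loglik(p, pi1, alpha: float) -> float:
    """Marginal log-likelihood sum_j log[pi_j0 + pi_j1 * phi(p_j; alpha)] (the EM objective)."""
    p = np.asarray(p, dtype=float)
    pi1 = np.asarray(pi1, dtype=float)
    log_phi = log_beta_density(p, alpha)
    with np.errstate(divide="ignore"):
        ll = np.logaddexp(np.log1p(-pi1), np.log(pi1) + log_phi)
    return float(np.sum(ll))


@dataclass
class TGMFit:
    """Result of the intercept-only two-groups fit."""

    pi1: float
    alpha: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(repr=False)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def fit_tgm(
    p,
    tol: float = 1e-8,
    max_iter: int = 1000,
    pi1_init: float = 0.1,
    alpha_init: float = 0.5,
) -> TGMFit:
    """Intercept-only two-groups EM on p-values alone (the TGM baseline).

    Alternates the posterior E-step with the closed-form M-step
    (pi1 <- mean(q1), alpha <- update_alpha) until the relative log-likelihood
    improvement drops below ``tol``.
    """
    p = clip_pvalues(p)
    if p.size < 2:
        raise ValueError("need at least two p-values")
    pi1, alpha = float(pi1_init), float(alpha_init)
    trace = [marginal_loglik(p, np.full(p.shape, pi1), alpha)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q1 = posterior_responsibility(p, np.full(p.shape, pi1), alpha)
        alpha = update_alpha(q1, p, prev_alpha=alpha)
        pi1 = float(np.clip(q1.mean(), 1e-12, 1 - 1e-12))
        trace.append(marginal_loglik(p, np.full(p.shape, pi1), alpha))
        if abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    return TGMFit(pi1=pi1, alpha=alpha, converged=converged, n_iter=it,
                  loglik_trace=np.asarray(trace))
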