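"""Functional-gradient EM: alternate posterior E-steps with one-tree boosting M-steps.

Each iteration (i) computes the posterior non-null responsibilities under the
current prior and alpha, (ii) updates alpha in closed form, (iii) fits one
regression tree to the Q-function's first/second derivatives and appends it to
the ensemble with shrinkage nu. The number of trees is the model's capacity
control and is chosen by K-fold cross-validation on held-out marginal
log-likelihood, after which the model is refit on all data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .trees import (
    TreeEnsembleModel,
    compute_grad_hess,
    fit_tree,
    predict_tree,
    presort_features,
)
from .two_groups import (
    clip_pvalues,
    fit_tgm,
    marginal_loglik,
    posterior_responsibility,
    update_alpha,
)

__all__ = ["PALMConfig", "FitTrace", "em_boost_fit", "select_num_trees_cv", "fit"]


@dataclass
class PALMConfig:
    """Hyper-parameters of a PALM fit.

    depth=1 gives an additive model in the annotations ("PALM-D1"); depth=2
    allows pairwise interactions ("PALM-D2").
    """

    depth: int = 1
    nu: float = 0.1
    cv_folds: int = 5
    max_trees: int = 500
    tau: float = 0.1
    seed: int = 0
    min_child_weight: float = 1.0
    reg_lambda: float = 1.0
    cv_patience: int = 50
    em_inner: bool = False  # reserved: inner Newton iterations per E-step (not implemented)

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.nu < 1:
            raise ValueError("shrinkage nu must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.em_inner:
            raise NotImplementedError("inner M-step iterations are reserved, not implemented")


@dataclass
class FitTrace:
    """Per-iteration diagnostics of one EM run (index 0 = before any tree)."""

    loglik: np.ndarray
    alpha: np.ndarray
    val_loglik: np.ndarray | None = None
    selected_T: int | None = None
    cv_curve: np.ndarray | None = field(default=None, repr=False)


def em_boost_fit(p, A, config: PALMConfig, T: int,
                 validation: tuple | None = None,
                 patience: int | None = None):
    """Run the EM for up to T boosting iterations; returns (model, trace).

    ``validation`` is an optional (p_val, A_val) pair; when given, the held-out
    marginal log-likelihood is recorded after every iteration, and ``patience``
    (if set) stops the run early once the best held-out value is that many
    iterations old. The returned model always reflects all iterations run.
    """
    p = clip_pvalues(p)
    A = np.asarray(A, dtype=float)
    if A.shape[0] != p.shape[0]:
        raise ValueError("p and A row counts differ")

    tgm = fit_tgm(p)
    f0 = float(logit(tgm.pi1))
    model = TreeEnsembleModel(f0=f0, nu=config.nu, alpha=tgm.alpha,
                              per_tree_gain=np.zeros((0, A.shape[1])))
    F = np.full(p.shape[0], f0)
    alpha = tgm.alpha
    presorted = presort_features(A) if T > 0 else None

    loglik = [marginal_loglik(p, expit(F), alpha)]
    alphas = [alpha]
    if validation is not None:
        p_val = clip_pvalues(validation[0])
        A_val = np.asarray(validation[1], dtype=float)
        F_val = np.full(p_val.shape[0], f0)
        val_ll = [marginal_loglik(p_val, expit(F_val), alpha)]
        best_val, best_t = val_ll[0], 0

    for t in range(1, T + 1):
        q1 = posterior_responsibility(p, expit(F), alpha)
        alpha = update_alpha(q1, p, prev_alpha=alpha)
        g, h = compute_grad_hess(q1, F)
        tree, gain = fit_tree(A, g, h, config.depth,
                              min_child_weight=config.min_child_weight,
                              reg_lambda=config.reg_lambda, presorted=presorted)
        model.append_tree(tree, gain)
        F += config.nu * predict_tree(tree, A)
        ll = marginal_loglik(p, expit(F), alpha)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {t}")
        loglik.append(ll)
        alphas.append(alpha)
        if validation is not None:
            F_val += config.nu * predict_tree(tree, A_val)
            val_ll.append(marginal_loglik(p_val, expit(F_val), alpha))
            if val_ll[-1] > best_val:
                best_val, best_t = val_ll[-1], t
            if patience is not None and t - best_t >= patience:
                break

    model.alpha = alpha
    trace = FitTrace(loglik=np.asarray(loglik), alpha=np.asarray(alphas),
                     val_loglik=np.asarray(val_ll) if validation is not None else None)
    return model, trace


def _make_folds(M: int, K: int, seed: int) -> list:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    perm = rng.permutation(M)
    return [np.sort(perm[k::K]) for k in range(K)]


def select_num_trees_cv(p, A, config: PALMConfig):
    """Choose the number of trees by K-fold CV on held-out marginal log-likelihood.

    Each fold is fit up to ``config.max_trees`` (with early stopping after
    ``config.cv_patience`` non-improving trees); the fold curves are truncated
    to their common length, averaged, and the argmax taken. Returns
    (T_opt, mean held-out curve).
    """
    p = clip_pvalues(p)
    A = np.asarray(A, dtype=float)
    M = p.shape[0]
    if M < 2 * config.cv_folds:
        raise ValueError("too few SNPs for the requested number of CV folds")
    folds = _make_folds(M, config.cv_folds, config.seed)
    curves = []
    for held_out in folds:
        mask = np.ones(M, dtype=bool)
        mask[held_out] = False
        _, trace = em_boost_fit(
            p[mask], A[mask], config, config.max_trees,
            validation=(p[held_out], A[held_out]),
            patience=config.cv_patience,
        )
        if np.all(~np.isfinite(trace.val_loglik)):
            warnings.warn("degenerate CV fold (non-finite held-out log-likelihood); skipping")
            continue
        curves.append(trace.val_loglik)
    if not curves:
        warnings.warn("all CV folds degenerate; selecting 0 trees")
        return 0, np.zeros(1)
    n = min(len(c) for c in curves)
    mean_curve = np.mean([c[:n] for c in curves], axis=0)
    return int(np.argmax(mean_curve)), mean_curve


def fit(p, A, config: PALMConfig) -> TreeEnsembleModel:
    """Full PALM fit: CV-select the number of trees, then refit on all data."""
    T_opt, _ = select_num_trees_cv(p, A, config)
    model, _ = em_boost_fit(p, A, config, T_opt)
    return model


def fit_with_trace(p, A, config: PALMConfig):
    """Like :func:`fit` but also returns the refit trace (with selected_T and CV curve)."""
    T_opt, curve = select_num_trees_cv(p, A, config)
    model, trace = em_boost_fit(p, A, config, T_opt)
    trace.selected_T = T_opt
    trace.cv_curve = curve
    return model, trace
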