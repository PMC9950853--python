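"""Annotation ranking by ensemble gain importance and pairwise interaction H-statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trees import TreeEnsembleModel, predict_ensemble

__all__ = ["ImportanceReport", "variable_importance", "h_statistic"]


@dataclass
class ImportanceReport:
    importance: np.ndarray          # I_l = (1/T) sum_t I_{t,l}, per-tree gains averaged
    normalized: np.ndarray          # importance / max(importance), for display
    feature_names: list | None = None
    h_pairs: list | None = None     # optional [(l1, l2, H), ...]


def variable_importance(model: TreeEnsembleModel) -> ImportanceReport:
    """Average the per-tree split-gain vectors over trees: I_l = (1/T) sum_t I_{t,l}."""
    if model.per_tree_gain is None or model.n_trees == 0:
        L = model.per_tree_gain.shape[1] if model.per_tree_gain is not None else 0
        imp = np.zeros(L)
    else:
        imp = model.per_tree_gain.mean(axis=0)
    mx = imp.max() if imp.size else 0.0
    normalized = imp / mx if mx > 0 else np.zeros_like(imp)
    return ImportanceReport(importance=imp, normalized=normalized,
                            feature_names=model.feature_names)


def _partial_dependence(model, background, cols, values):
    """Mean prediction over background rows with ``cols`` overridden per grid point."""
    out = np.empty(values.shape[0])
    work = background.copy()
    for i, v in enumerate(values):
        work[:, cols] = v
        out[i] = predict_ensemble(model, work).mean()
    return out


def h_statistic(model: TreeEnsembleModel, A, l1: int, l2: int,
                n_grid: int = 2000, seed: int = 0) -> float:
    """Friedman-Popescu two-variable H^2 for annotations (l1, l2).

    Measures the fraction of the variance of the centered joint partial
    dependence of F on (l1, l2) that is not explained by the sum of the two
    centered one-variable partial dependences. Evaluated over observed
    annotation rows, subsampled to ``n_grid``; rows missing l1 or l2 are
    dropped. Returns a value in [0, 1]; exactly 0 for additive (depth-1)
    ensembles.
    """
    if l1 == l2:
        raise ValueError("l1 and l2 must differ")
    A = np.asarray(A, dtype=float)
    keep = ~(np.isnan(A[:, l1]) | np.isnan(A[:, l2]))
    A = A[keep]
    if A.shape[0] == 0:
        warnings.warn("no rows with both annotations observed; returning 0")
        return 0.0
    if A.shape[0] > n_grid:
        rng = np.random.default_rng(seed)
        A = A[rng.choice(A.shape[0], size=n_grid, replace=False)]

    pd12 = _partial_dependence(model, A, [l1, l2], A[:, [l1, l2]])
    pd1 = _partial_dependence(model, A, [l1], A[:, [l1]])
    pd2 = _partial_dependence(model, A, [l2], A[:, [l2]])
    pd12 -= pd12.mean()
    pd1 -= pd1.mean()
    pd2 -= pd2.mean()

    denom = float(np.sum(pd12 ** 2))
    if denom <= 1e-12 * pd12.shape[0]:  # flat joint PD (features unused) -> no interaction
        warnings.warn("joint partial dependence has (near-)zero variance; returning 0")
        return 0.0
    h2 = float(np.sum((pd12 - pd1 - pd2) ** 2) / denom)
    return min(max(h2, 0.0), 1.0)
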