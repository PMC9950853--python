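"""Depth-limited regression trees fit to (gradient, hessian) data, and the ensemble.

The M-step of the EM algorithm maximizes a second-order approximation of the
Q-function, which is equivalent to one round of gradient boosting with soft
labels: a weighted least-squares tree with sample weights -h_j and pseudo-targets
-g_j/h_j. We work directly with per-node aggregates (sum of g, sum of -h) so the
division by vanishing hessians never happens. Missing annotation values are
handled by sparsity-aware split finding: both routing choices for missing rows
are scored and the winner is stored as the split's default direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "TreeNode",
    "TreeEnsembleModel",
    "compute_grad_hess",
    "fit_tree",
    "predict_tree",
    "predict_ensemble",
]

_GAIN_EPS = 1e-12


@dataclass
class TreeNode:
    """A node of a regression tree.

    Split nodes carry a feature index, threshold and a default direction for
    rows whose split feature is missing; leaves carry a value.
    """

    is_leaf: bool
    value: float = 0.0
    feature: int = -1
    threshold: float = np.nan
    default_left: bool = True
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.value}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "default": "left" if self.default_left else "right",
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "leaf" in d:
            return cls(is_leaf=True, value=float(d["leaf"]))
        return cls(
            is_leaf=False,
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            default_left=d["default"] == "left",
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def compute_grad_hess(q1, F):
    """First/second derivatives of the Q-function at the current ensemble.

    g_j = q_j1 - sigmoid(F_j);  h_j = -sigmoid(F_j) * (1 - sigmoid(F_j)).
    """
    s = expit(np.asarray(F, dtype=float))
    g = np.asarray(q1, dtype=float) - s
    h = -s * (1.0 - s)
    return g, h


def _score(G, W, lam):
    # objective value of an optimally-valued leaf with aggregates (G, W=sum(-h))
    with np.errstate(invalid="ignore", divide="ignore"):
        return G * G / (W + lam)


def presort_features(A) -> np.ndarray:
    """Per-feature argsort of the rows (missing values last), shape (L, M).

    The annotation matrix is fixed across boosting rounds, so the sort is done
    once per fit and node-level sorted orders are derived by boolean gathering.
    """
    return np.argsort(np.asarray(A, dtype=float).T, axis=1)


def _best_split(Asort, order, g, w, lam, min_child_weight):
    """Exact greedy scan over all (feature, threshold, missing-direction) candidates.

    ``Asort``/``order`` are the node's feature values and row indices, sorted per
    feature (missing last), shape (L, n). Returns (gain, feature, threshold,
    default_left) or None when no split improves the objective. Ties break to
    the lowest feature index, then the smallest threshold, then default-left —
    purely for determinism.
    """
    L, n = Asort.shape
    n_pres = n - np.isnan(Asort).sum(axis=1)
    gcum = np.cumsum(g[order], axis=1)
    wcum = np.cumsum(w[order], axis=1)
    Gtot, Wtot = gcum[0, -1], wcum[0, -1]  # node totals (any feature's full sum)
    parent = _score(Gtot, Wtot, lam)

    # aggregates of the missing rows, per feature
    rows = np.arange(L)
    last = np.maximum(n_pres - 1, 0)
    g_pres = np.where(n_pres > 0, gcum[rows, last], 0.0)
    w_pres = np.where(n_pres > 0, wcum[rows, last], 0.0)
    Gmiss, Wmiss = Gtot - g_pres, Wtot - w_pres

    # candidate k: split after sorted position k; needs >=1 present row each side
    # and strictly increasing adjacent present values (threshold = their midpoint)
    ks = np.arange(n)[None, :]
    valid = ks <= n_pres[:, None] - 2
    with np.errstate(invalid="ignore"):
        distinct = np.zeros((L, n), dtype=bool)
        distinct[:, :-1] = Asort[:, 1:] > Asort[:, :-1]
    valid &= distinct

    gains = np.empty((2, L, n))
    for d, (Gm, Wm) in enumerate(((Gmiss[:, None], Wmiss[:, None]), (0.0, 0.0))):
        GL = gcum + Gm  # d=0: missing rows join the left child
        WL = wcum + Wm
        GR, WR = Gtot - GL, Wtot - WL
        ok = valid & (WL >= min_child_weight) & (WR >= min_child_weight)
        gd = _score(GL, WL, lam) + _score(GR, WR, lam) - parent
        gains[d] = np.where(ok, gd, -np.inf)

    best = np.maximum(gains[0], gains[1])
    flat = best.ravel()  # feature-major, ascending threshold within feature
    i = int(np.argmax(flat))
    gain = flat[i]
    if not np.isfinite(gain) or gain <= _GAIN_EPS:
        return None
    feat, k = divmod(i, n)
    threshold = 0.5 * (Asort[feat, k] + Asort[feat, k + 1])
    default_left = gains[0, feat, k] >= gains[1, feat, k]
    return float(gain), int(feat), float(threshold), bool(default_left)


def fit_tree(A, g, h, depth: int, min_child_weight: float = 1.0,
             reg_lambda: float = 1.0, presorted: np.ndarray | None = None):
    """Fit one regression tree to (g, h) data by exact greedy split search.

    Equivalent to a weighted least-squares tree with weights -h and targets
    -g/h; leaf values are the damped Newton steps sum(g)/(sum(-h) + lambda).
    ``presorted`` (from :func:`presort_features`) may be shared across calls on
    the same annotation matrix. Returns the root node and a length-L vector of
    per-feature objective reductions (the gain bookkeeping used for variable
    importance).
    """
    A = np.asarray(A, dtype=float)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h >= 0):
        raise ValueError("hessians must be strictly negative")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    w = -h
    AT = np.ascontiguousarray(A.T)
    if presorted is None:
        presorted = presort_features(A)
    gains = np.zeros(A.shape[1])

    def build(order: np.ndarray, d: int) -> TreeNode:
        # order: (L, n) row indices of this node, sorted per feature, missing last
        n = order.shape[1]
        idx = order[0]
        gn, wn = g[idx], w[idx]
        leaf_value = float(gn.sum() / (wn.sum() + reg_lambda))
        if d == 0 or n < 2:
            return TreeNode(is_leaf=True, value=leaf_value)
        Asort = np.take_along_axis(AT, order, axis=1)
        found = _best_split(Asort, order, g, w, reg_lambda, min_child_weight)
        if found is None:
            return TreeNode(is_leaf=True, value=leaf_value)
        gain, feat, thr, default_left = found
        gains[feat] += gain
        col = A[idx, feat]
        miss = np.isnan(col)
        go_left = np.zeros(A.shape[0], dtype=bool)
        go_left[idx] = np.where(miss, default_left, col < thr)
        in_left = go_left[order]
        n_left = int(in_left[0].sum())
        node = TreeNode(is_leaf=False, feature=feat, threshold=thr,
                        default_left=default_left)
        node.left = build(order[in_left].reshape(order.shape[0], n_left), d - 1)
        node.right = build(order[~in_left].reshape(order.shape[0], n - n_left), d - 1)
        return node

    root = build(presorted, depth)
    return root, gains


def predict_tree(node: TreeNode, A) -> np.ndarray:
    """Evaluate one tree on an M x L annotation matrix (missing -> default direction)."""
    A = np.asarray(A, dtype=float)
    single = A.ndim == 1
    if single:
        A = A[None, :]
    out = np.empty(A.shape[0])

    def walk(nd: TreeNode, idx: np.ndarray) -> None:
        if nd.is_leaf:
            out[idx] = nd.value
            return
        col = A[idx, nd.feature]
        miss = np.isnan(col)
        go_left = np.where(miss, nd.default_left, col < nd.threshold)
        walk(nd.left, idx[go_left])
        walk(nd.right, idx[~go_left])

    walk(node, np.arange(A.shape[0]))
    return float(out[0]) if single else out


@dataclass
class TreeEnsembleModel:
    """Shrunk additive tree ensemble F(A) = f0 + nu * sum_t tree_t(A), plus alpha.

    ``per_tree_gain`` stacks the per-feature objective reductions of each tree
    (row t is nonzero only on features tree t splits on).
    """

    f0: float
    nu: float
    alpha: float
    trees: list = field(default_factory=list)
    per_tree_gain: np.ndarray | None = None  # (T, L)
    feature_names: list | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def append_tree(self, tree: TreeNode, gain: np.ndarray) -> None:
        self.trees.append(tree)
        gain = np.asarray(gain, dtype=float)[None, :]
        if self.per_tree_gain is None:
            self.per_tree_gain = gain
        else:
            self.per_tree_gain = np.vstack([self.per_tree_gain, gain])

    def predict(self, A, n_trees: int | None = None) -> np.ndarray:
        return predict_ensemble(self, A, n_trees)

    def prior(self, A, n_trees: int | None = None) -> np.ndarray:
        """pi_j1 = sigmoid(F(A_j))."""
        return expit(self.predict(A, n_trees))

    def to_dict(self) -> dict:
        return {
            "f0": float(self.f0),
            "nu": float(self.nu),
            "alpha": float(self.alpha),
            "trees": [t.to_dict() for t in self.trees],
            "per_tree_gain": (
                self.per_tree_gain.tolist() if self.per_tree_gain is not None else None
            ),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeEnsembleModel":
        gain = d.get("per_tree_gain")
        return cls(
            f0=float(d["f0"]),
            nu=float(d["nu"]),
            alpha=float(d["alpha"]),
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            per_tree_gain=np.asarray(gain, dtype=float) if gain is not None else None,
            feature_names=d.get("feature_names"),
        )


def predict_ensemble(model: TreeEnsembleModel, A, n_trees: int | None = None) -> np.ndarray:
    """F_j = f0 + nu * sum_{t <= n_trees} tree_t(A_j). n_trees=None uses all trees."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    T = model.n_trees if n_trees is None else n_trees
    if T > model.n_trees:
        raise ValueError(f"n_trees={T} exceeds ensemble size {model.n_trees}")
    F = np.full(A.shape[0], float(model.f0))
    for t in range(T):
        F += model.nu * predict_tree(model.trees[t], A)
    return F
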