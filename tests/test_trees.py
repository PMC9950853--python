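import itertools

import numpy as np
import pytest

from palm.trees import (
    TreeEnsembleModel,
    TreeNode,
    compute_grad_hess,
    fit_tree,
    predict_ensemble,
    predict_tree,
)


def brute_force_stump(A, g, h, lam, mcw):
    """Enumerate every (feature, threshold, missing-direction) depth-1 candidate.

    Independent oracle: objective is the weighted SSE + lambda*leaf^2 with
    weights -h and targets -g/h, evaluated by direct summation. Returns the
    best (objective reduction, feature, threshold, default_left, vl, vr).
    """
    w = -h
    y = -g / h

    def leaf_obj(mask):
        G, W = g[mask].sum(), w[mask].sum()
        v = G / (W + lam)
        return np.sum(w[mask] * (y[mask] - v) ** 2) + lam * v * v, v

    base, _ = leaf_obj(np.ones(len(g), dtype=bool))
    best = None
    for f in range(A.shape[1]):
        col = A[:, f]
        miss = np.isnan(col)
        vals = np.unique(col[~miss])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            for default_left in (True, False):
                left = np.where(miss, default_left, col < thr)
                if w[left].sum() < mcw or w[~left].sum() < mcw:
                    continue
                ol, vl = leaf_obj(left)
                orr, vr = leaf_obj(~left)
                red = base - ol - orr
                cand = (red, f, thr, default_left, vl, vr)
                if best is None or red > best[0] + 1e-12:
                    best = cand
    return best


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("missing", [False, True])
def test_stump_matches_exhaustive_enumeration(seed, missing):
    rng = np.random.default_rng(seed)
    M, L = rng.integers(20, 200), rng.integers(1, 4)
    A = rng.choice(np.round(rng.uniform(-1, 1, 8), 3), size=(M, L))
    if missing:
        A[rng.random((M, L)) < 0.2] = np.nan
    q1 = rng.uniform(0, 1, M)
    F = rng.normal(-1, 1, M)
    g, h = compute_grad_hess(q1, F)
    lam, mcw = 1.0, 0.05
    tree, gains = fit_tree(A, g, h, depth=1, min_child_weight=mcw, reg_lambda=lam)
    oracle = brute_force_stump(A, g, h, lam, mcw)
    if oracle is None or oracle[0] <= 1e-12:
        assert tree.is_leaf
        return
    red, f, thr, dl, vl, vr = oracle
    assert not tree.is_leaf
    assert tree.feature == f
    assert tree.threshold == pytest.approx(thr)
    assert gains[f] == pytest.approx(red, rel=1e-9)
    assert tree.left.value == pytest.approx(vl, rel=1e-9)
    assert tree.right.value == pytest.approx(vr, rel=1e-9)
    if np.isnan(A[:, f]).any():
        assert tree.default_left == dl


def test_grad_hess_values():
    g, h = compute_grad_hess(np.array([1.0]), np.array([0.0]))
    assert g[0] == pytest.approx(0.5)
    assert h[0] == pytest.approx(-0.25)
    g, h = compute_grad_hess(np.array([0.5]), np.array([0.0]))
    assert g[0] == pytest.approx(0.0)
    g, h = compute_grad_hess(np.array([1.0]), np.array([20.0]))
    assert abs(g[0]) < 1e-8 and abs(h[0]) < 1e-8
    assert np.all((h >= -0.25) & (h < 0))


def test_zero_gradient_gives_single_zero_leaf():
    A = np.linspace(-1, 1, 20)[:, None]
    g = np.zeros(20)
    h = np.full(20, -0.25)
    tree, gains = fit_tree(A, g, h, depth=2)
    assert tree.is_leaf
    assert tree.value == pytest.approx(0.0)
    assert np.all(gains == 0)


def test_simple_split_and_missing_default():
    A = np.array([[-1.0], [-1.0], [1.0], [1.0]])
    h = np.full(4, -1.0)
    g = np.array([-1.0, -1.0, 1.0, 1.0])  # targets -g/h = g
    tree, _ = fit_tree(A, g, h, depth=1, min_child_weight=0.0, reg_lambda=0.0)
    assert tree.feature == 0 and -1 < tree.threshold < 1
    assert tree.left.value == pytest.approx(-1.0)
    assert tree.right.value == pytest.approx(1.0)
    # blank the first entry: default direction must join the matching leaf
    A2 = A.copy()
    A2[0, 0] = np.nan
    tree2, _ = fit_tree(A2, g, h, depth=1, min_child_weight=0.0, reg_lambda=0.0)
    assert tree2.default_left
    assert predict_tree(tree2, np.array([np.nan])) == pytest.approx(tree2.left.value)


def test_leaf_values_are_newton_steps(rng):
    # leaf value equals sum(g)/(sum(-h)+lam) over the leaf's rows
    M = 300
    A = rng.uniform(-1, 1, (M, 2))
    g, h = compute_grad_hess(rng.uniform(0, 1, M), rng.normal(0, 1, M))
    lam = 1.0
    tree, _ = fit_tree(A, g, h, depth=2, reg_lambda=lam)
    pred = predict_tree(tree, A)
    for v in np.unique(pred):
        mask = pred == v
        assert v == pytest.approx(g[mask].sum() / ((-h[mask]).sum() + lam), rel=1e-9)


def test_adding_tree_improves_q_approximation(rng):
    # each leaf optimizes the second-order Q locally; any nu in (0,1] helps
    M = 500
    A = rng.uniform(-1, 1, (M, 3))
    q1 = rng.uniform(0, 1, M)
    F = rng.normal(-2, 1, M)
    g, h = compute_grad_hess(q1, F)
    tree, _ = fit_tree(A, g, h, depth=2)
    f = predict_tree(tree, A)
    for nu in (0.05, 0.1, 0.5, 1.0):
        dq = np.sum(g * nu * f + 0.5 * h * (nu * f) ** 2)
        assert dq >= -1e-12


def test_gain_vector_nonnegative_and_sparse(rng):
    M = 400
    A = rng.uniform(-1, 1, (M, 5))
    y = np.where(A[:, 2] > 0, 1.0, 0.0)
    g, h = compute_grad_hess(y, np.zeros(M))
    tree, gains = fit_tree(A, g, h, depth=2)
    assert np.all(gains >= 0)
    used = set()

    def collect(nd):
        if not nd.is_leaf:
            used.add(nd.feature)
            collect(nd.left)
            collect(nd.right)

    collect(tree)
    for l in range(5):
        if l not in used:
            assert gains[l] == 0.0


def test_predict_tree_routing():
    leaf = TreeNode(is_leaf=True, value=0.7)
    assert predict_tree(leaf, np.array([[1.0, 2.0]])) == pytest.approx([0.7])
    split = TreeNode(is_leaf=False, feature=0, threshold=0.0, default_left=False,
                     left=TreeNode(is_leaf=True, value=-1.0),
                     right=TreeNode(is_leaf=True, value=2.0))
    assert predict_tree(split, np.array([-0.5, 9.0])) == pytest.approx(-1.0)
    assert predict_tree(split, np.array([np.nan, 9.0])) == pytest.approx(2.0)


class TestEnsemble:
    def _model(self):
        t1 = TreeNode(is_leaf=True, value=1.0)
        m = TreeEnsembleModel(f0=0.0, nu=0.1, alpha=0.5)
        m.append_tree(t1, np.array([0.0, 0.0]))
        return m

    def test_intercept_only(self):
        m = TreeEnsembleModel(f0=-3.0, nu=0.1, alpha=0.5,
                              per_tree_gain=np.zeros((0, 2)))
        F = predict_ensemble(m, np.zeros((4, 2)))
        np.testing.assert_allclose(F, -3.0)
        np.testing.assert_allclose(m.prior(np.zeros((4, 2))), 1 / (1 + np.e ** 3))

    def test_shrinkage_arithmetic(self):
        F = predict_ensemble(self._model(), np.zeros((3, 2)))
        np.testing.assert_allclose(F, 0.1)

    def test_truncation_identity(self):
        m = self._model()
        np.testing.assert_allclose(predict_ensemble(m, np.zeros((3, 2)), n_trees=0), 0.0)
        with pytest.raises(ValueError):
            predict_ensemble(m, np.zeros((3, 2)), n_trees=5)

    def test_linear_in_tree_predictions(self, rng):
        M = 100
        A = rng.uniform(-1, 1, (M, 3))
        g, h = compute_grad_hess(rng.uniform(0, 1, M), rng.normal(0, 1, M))
        m = TreeEnsembleModel(f0=0.3, nu=0.2, alpha=0.5)
        for _ in range(4):
            t, gain = fit_tree(A, g + rng.normal(0, 0.01, M), h, depth=2)
            m.append_tree(t, gain)
        total = m.f0 + m.nu * sum(predict_tree(t, A) for t in m.trees)
        np.testing.assert_allclose(predict_ensemble(m, A), total, atol=1e-12)

    def test_roundtrip_serialization(self, rng, tmp_path):
        import json

        M = 200
        A = rng.uniform(-1, 1, (M, 4))
        A[rng.random((M, 4)) < 0.1] = np.nan
        g, h = compute_grad_hess(rng.uniform(0, 1, M), rng.normal(-1, 1, M))
        m = TreeEnsembleModel(f0=-2.0, nu=0.1, alpha=0.4)
        for _ in range(3):
            t, gain = fit_tree(A, g, h, depth=2)
            m.append_tree(t, gain)
        d = json.loads(json.dumps(m.to_dict()))
        m2 = TreeEnsembleModel.from_dict(d)
        np.testing.assert_allclose(predict_ensemble(m2, A), predict_ensemble(m, A),
                                   atol=1e-12)
        np.testing.assert_allclose(m2.per_tree_gain, m.per_tree_gain)

    def test_depth_limit_respected(self, rng):
        M = 500
        A = rng.uniform(-1, 1, (M, 3))
        g, h = compute_grad_hess(rng.uniform(0, 1, M), rng.normal(0, 1, M))
        for d in (1, 2, 3):
            t, _ = fit_tree(A, g, h, depth=d)
            assert t.depth() <= d


def test_deterministic_tie_break_lowest_feature():
    # duplicated feature columns: identical gains must pick the lower index
    A = np.array([[-1.0, -1.0], [-1.0, -1.0], [1.0, 1.0], [1.0, 1.0]])
    g = np.array([-1.0, -1.0, 1.0, 1.0])
    h = np.full(4, -1.0)
    tree, _ = fit_tree(A, g, h, depth=1, min_child_weight=0.0, reg_lambda=0.0)
    assert tree.feature == 0
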