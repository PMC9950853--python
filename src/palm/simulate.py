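"""Seedable simulation benchmark: annotations, latent status, p-values, missingness.

Five scenario functions map an annotation row to the log-odds of association:

    A: constant -3 (all annotations irrelevant; negative control)
    B: linear,      -3 + 1.5*A1 + 1.5*A2
    C: quadratic,   -4.25 + 2*A1^2 + 2*A2^2 - 2*A1*A2
    D: non-linear,  -4 + 4*sin(pi*A1*A2) + 2*(A3-A4)^2 + A4 + 0.5*A5
    E: piecewise on binary A2: 1 - 6*A1^2 if A2=0, else -1 + 2*A1 - 6*A1^2

Annotations are i.i.d. U(-1,1) (case E's second column is Bernoulli(0.5) in
{0,1}); association status is Bernoulli(sigmoid(F)); null p-values are U(0,1);
non-null p-values come from a two-sided normal tail of z ~ N(mu, 1) with mu
drawn from a configurable normal mixture (default bimodal).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .em import PALMConfig, fit_with_trace
from .inference import bh_procedure, global_fdr_select, local_fdr
from .two_groups import clip_pvalues, fit_tgm, posterior_responsibility

__all__ = [
    "CASE_MIN_FEATURES",
    "BIMODAL",
    "MixtureSpec",
    "SimulatedDataset",
    "ReplicateMetrics",
    "true_F",
    "gen_annotations",
    "gen_status",
    "gen_pvalues",
    "inject_missing",
    "simulate_dataset",
    "evaluate_replicate",
    "run_study",
]

CASE_MIN_FEATURES = {"A": 0, "B": 2, "C": 2, "D": 5, "E": 2}


@dataclass(frozen=True)
class MixtureSpec:
    """Normal mixture for the non-null mean mu; weights must sum to 1."""

    weights: tuple
    means: tuple
    variances: tuple

    def __post_init__(self):
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if not len(self.weights) == len(self.means) == len(self.variances):
            raise ValueError("mixture component lists must have equal length")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        sd = np.sqrt(np.asarray(self.variances))[comp]
        return rng.normal(np.asarray(self.means)[comp], sd)


BIMODAL = MixtureSpec(weights=(0.48, 0.04, 0.48), means=(-2.0, 0.0, 2.0),
                      variances=(1.0, 16.0, 1.0))


def true_F(case: str, A) -> np.ndarray:
    """Evaluate the scenario's log-odds function on annotation rows."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if case not in CASE_MIN_FEATURES:
        raise ValueError(f"unknown case {case!r}")
    need = CASE_MIN_FEATURES[case]
    if A.shape[1] < need:
        raise ValueError(f"case {case} needs at least {need} annotation columns")
    if case == "A":
        return np.full(A.shape[0], -3.0)
    a1 = A[:, 0]
    a2 = A[:, 1]
    if case == "B":
        return -3.0 + 1.5 * a1 + 1.5 * a2
    if case == "C":
        return -4.25 + 2.0 * a1 ** 2 + 2.0 * a2 ** 2 - 2.0 * a1 * a2
    if case == "D":
        a3, a4, a5 = A[:, 2], A[:, 3], A[:, 4]
        return (-4.0 + 4.0 * np.sin(np.pi * a1 * a2)
                + 2.0 * (a3 - a4) ** 2 + a4 + 0.5 * a5)
    if case == "E":
        return np.where(a2 == 0, 1.0 - 6.0 * a1 ** 2,
                        -1.0 + 2.0 * a1 - 6.0 * a1 ** 2)
    raise ValueError(f"unknown case {case!r}")


def gen_annotations(M: int, L: int, case: str, rng) -> np.ndarray:
    """M x L annotation matrix, entries i.i.d. U(-1,1); case E's column 2 is binary."""
    rng = np.random.default_rng(rng)
    if case not in CASE_MIN_FEATURES:
        raise ValueError(f"unknown case {case!r}")
    need = CASE_MIN_FEATURES[case]
    if L < need:
        raise ValueError(f"case {case} needs at least {need} annotation columns, got L={L}")
    A = rng.uniform(-1.0, 1.0, size=(M, L))
    if case == "E":
        A[:, 1] = rng.integers(0, 2, size=M).astype(float)
    return A


def gen_status(pi1, rng) -> np.ndarray:
    """Z_j ~ Bernoulli(pi_j1), independently."""
    rng = np.random.default_rng(rng)
    pi1 = np.asarray(pi1, dtype=float)
    return rng.random(pi1.shape[0]) < pi1


def gen_pvalues(Z, rng, dist: MixtureSpec = BIMODAL):
    """Null p ~ U(0,1); non-null mu ~ dist, z ~ N(mu,1), p = 2*(1 - Phi(|z|)).

    Returns (p, z) with z = NaN on null entries.
    """
    rng = np.random.default_rng(rng)
    Z = np.asarray(Z, dtype=bool)
    M = Z.shape[0]
    p = rng.uniform(0.0, 1.0, size=M)
    z = np.full(M, np.nan)
    n1 = int(Z.sum())
    if n1:
        mu = dist.sample(n1, rng)
        z1 = rng.normal(mu, 1.0)
        z[Z] = z1
        p[Z] = 2.0 * norm.sf(np.abs(z1))
    return clip_pvalues(p), z


def inject_missing(A, mrate: float, rng) -> np.ndarray:
    """Independently blank each entry with probability mrate (returns a copy)."""
    if not 0 <= mrate < 1:
        raise ValueError("mrate must lie in [0, 1)")
    A = np.asarray(A, dtype=float).copy()
    if mrate > 0:
        rng = np.random.default_rng(rng)
        A[rng.random(A.shape) < mrate] = np.nan
    return A


@dataclass
class SimulatedDataset:
    """One simulated replicate: annotations, truth, priors and p-values."""

    A: np.ndarray
    Z: np.ndarray
    pi1_true: np.ndarray
    p: np.ndarray
    z_scores: np.ndarray
    case_id: str
    seed: int
    mrate: float = 0.0


def simulate_dataset(case: str, M: int, L: int, seed: int, mrate: float = 0.0,
                     dist: MixtureSpec = BIMODAL) -> SimulatedDataset:
    """Generate one full replicate; all randomness flows from named substreams of ``seed``."""
    ss = np.random.SeedSequence(seed)
    r_annot, r_status, r_pval, r_miss = ss.spawn(4)
    A = gen_annotations(M, L, case, r_annot)
    pi1 = expit(true_F(case, A))
    Z = gen_status(pi1, r_status)
    p, z = gen_pvalues(Z, r_pval, dist)
    A_obs = inject_missing(A, mrate, r_miss)
    return SimulatedDataset(A=A_obs, Z=Z, pi1_true=pi1, p=p, z_scores=z,
                            case_id=case, seed=seed, mrate=mrate)


@dataclass
class ReplicateMetrics:
    """Empirical false-discovery proportion and power of one rejection set."""

    fdp: float
    power: float
    n_rejected: int
    method: str = ""


def evaluate_replicate(Z, rejected, method: str = "") -> ReplicateMetrics:
    """fdp = #(rejected & null)/max(1, #rejected); power = #(rejected & non-null)/#non-null."""
    Z = np.asarray(Z, dtype=bool)
    rejected = np.asarray(rejected, dtype=bool)
    if Z.shape != rejected.shape:
        raise ValueError("Z and rejected must have equal length")
    n_rej = int(rejected.sum())
    n_true = int(Z.sum())
    fdp = float((rejected & ~Z).sum() / n_rej) if n_rej else 0.0
    power = float((rejected & Z).sum() / n_true) if n_true else np.nan
    return ReplicateMetrics(fdp=fdp, power=power, n_rejected=n_rej, method=method)


def _tgm_reject(p, tau):
    tgmfit = fit_tgm(p)
    pclip = clip_pvalues(p)
    q1 = posterior_responsibility(pclip, np.full(pclip.shape, tgmfit.pi1), tgmfit.alpha)
    rej, _ = global_fdr_select(1.0 - q1, tau)
    return rej


def run_study(cases, M: int, L: int, n_reps: int, methods=("PALM-D1", "PALM-D2", "TGM", "BH"),
              base_seed: int = 1, tau: float = 0.1, mrate: float = 0.0,
              dist: MixtureSpec = BIMODAL, config_kwargs: dict | None = None) -> pd.DataFrame:
    """Run the simulation benchmark; one row per (case, replicate, method).

    Replicate r of every case uses seed base_seed + r, so methods within a
    replicate see identical data. ``config_kwargs`` override PALM defaults
    (e.g. max_trees, cv_folds) to keep desk-scale runs affordable.
    """
    config_kwargs = dict(config_kwargs or {})
    rows = []
    for case in cases:
        for rep in range(n_reps):
            seed = base_seed + rep
            ds = simulate_dataset(case, M, L, seed, mrate=mrate, dist=dist)
            for method in methods:
                t0 = time.perf_counter()
                t_opt, em_monotone = np.nan, True
                if method.startswith("PALM"):
                    depth = int(method.split("-D")[1])
                    cfg = PALMConfig(depth=depth, seed=seed, tau=tau, **config_kwargs)
                    model, trace = fit_with_trace(ds.p, ds.A, cfg)
                    rej, _ = global_fdr_select(local_fdr(model, ds.p, ds.A), tau)
                    t_opt = trace.selected_T
                    ll = trace.loglik
                    em_monotone = bool(np.all(np.diff(ll) >= -1e-8 * (np.abs(ll[:-1]) + 1)))
                elif method == "TGM":
                    rej = _tgm_reject(ds.p, tau)
                elif method == "BH":
                    rej = bh_procedure(ds.p, tau)
                else:
                    raise ValueError(f"unknown method {method!r}")
                met = evaluate_replicate(ds.Z, rej, method)
                rows.append({"case": case, "M": M, "L": L, "mrate": mrate,
                             "method": method, "replicate": rep, "seed": seed,
                             "fdp": met.fdp, "power": met.power,
                             "n_rejected": met.n_rejected, "T_opt": t_opt,
                             "em_monotone": em_monotone,
                             "runtime_s": time.perf_counter() - t0})
    return pd.DataFrame(rows)
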