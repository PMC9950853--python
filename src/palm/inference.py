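"""Local fdr, global FDR control by the direct posterior probability approach, and BH."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .two_groups import clip_pvalues, posterior_responsibility

__all__ = ["PosteriorResult", "local_fdr", "global_fdr_select", "bh_procedure",
           "posterior_result"]


def local_fdr(model, p, A) -> np.ndarray:
    """Per-SNP local fdr = 1 - Pr(Z_j = 1 | p_j, A_j) under the fitted model."""
    p = clip_pvalues(p)
    q1 = posterior_responsibility(p, model.prior(A), model.alpha)
    return 1.0 - q1


def global_fdr_select(lfdr, tau: float):
    """Reject the k SNPs with smallest local fdr whose average stays below tau.

    Sorts the local fdr ascending (stable) and takes the largest prefix whose
    mean is <= tau. A tie group straddling the prefix boundary is included in
    full if doing so keeps the prefix mean <= tau, and excluded in full
    otherwise. Returns (rejected boolean vector, k).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    lfdr = np.asarray(lfdr, dtype=float)
    M = lfdr.shape[0]
    order = np.argsort(lfdr, kind="stable")
    s = lfdr[order]
    prefix_mean = np.cumsum(s) / np.arange(1, M + 1)
    ok = np.nonzero(prefix_mean <= tau)[0]
    k = int(ok[-1] + 1) if ok.size else 0
    if 0 < k < M:
        boundary = s[k - 1]
        if s[k] == boundary:  # tie group straddles the cut
            hi = int(np.searchsorted(s, boundary, side="right"))
            if prefix_mean[hi - 1] <= tau:
                k = hi
            else:
                k = int(np.searchsorted(s, boundary, side="left"))
    rejected = np.zeros(M, dtype=bool)
    rejected[order[:k]] = True
    return rejected, k


def bh_procedure(p, tau: float) -> np.ndarray:
    """Benjamini-Hochberg step-up at level tau; returns a rejection mask."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    M = p.shape[0]
    order = np.argsort(p, kind="stable")
    thresh = tau * np.arange(1, M + 1) / M
    ok = np.nonzero(p[order] <= thresh)[0]
    k = int(ok[-1] + 1) if ok.size else 0
    rejected = np.zeros(M, dtype=bool)
    rejected[order[:k]] = True
    return rejected


@dataclass
class PosteriorResult:
    """Full per-SNP posterior summary at FDR level tau.

    ``cum_fdr`` holds, for each SNP, the running mean of local fdr up to that
    SNP's rank in the ascending local-fdr order (the global Fdr at its rank),
    so results can be re-thresholded without refitting.
    """

    q1: np.ndarray
    local_fdr: np.ndarray
    order: np.ndarray
    cum_fdr: np.ndarray
    rejected: np.ndarray
    k: int
    tau: float


def posterior_result(model, p, A, tau: float) -> PosteriorResult:
    """Compute posteriors, local/global fdr and the rejection set in one pass."""
    lfdr = local_fdr(model, p, A)
    order = np.argsort(lfdr, kind="stable")
    M = lfdr.shape[0]
    prefix_mean = np.cumsum(lfdr[order]) / np.arange(1, M + 1)
    cum_fdr = np.empty(M)
    cum_fdr[order] = prefix_mean
    rejected, k = global_fdr_select(lfdr, tau)
    return PosteriorResult(q1=1.0 - lfdr, local_fdr=lfdr, order=order,
                           cum_fdr=cum_fdr, rejected=rejected, k=k, tau=tau)
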