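"""Score-biased transition matrix and restart propagation.

Each weight block W of the heterogeneous network is first dampened to
``W / (1 + max(W))**2`` (global maximum of the block), then row-normalised
within the block and biased by the target node's initial score:
``entry(u, v) = [X(u, v) / sum_j X(u, j)] * S0(v)``. The four biased blocks
are assembled into the distribution-probability matrix NDPM, and — because
the S0 bias destroys row-stochasticity — every nonzero row of the assembled
matrix is renormalised to sum to 1 by default, giving a proper random walk
with restart.

Scores are then iterated to a fixed point:

    S(t+1) = alpha * NDPM^T @ S(t) + (1 - alpha) * S0

with S0 normalised to sum 1, stopping when the squared L2 norm of the
update falls below ``eps``. The transpose orientation means a node's new
score aggregates the probability mass flowing *in* along edges. With
row-stochastic NDPM the map is a contraction with factor <= alpha, so
convergence is guaranteed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import scipy.sparse as sp

from .config import ConvergenceError, KFPMConfig
from .features import InitialScores
from .io import RankedList
from .network import HeteroNetwork

logger = logging.getLogger("kfpm")


@dataclasses.dataclass
class TransitionMatrix:
    """The assembled NDPM plus the dampened weight blocks it was built
    from. ``row_normalized`` records whether full-row renormalisation was
    applied (the default)."""

    ndpm: sp.csr_matrix
    n_proteins: int
    row_normalized: bool
    ppn: sp.csr_matrix  # dampened WPP
    pdn: sp.csr_matrix  # dampened WPD
    ddn: sp.csr_matrix  # dampened WDD


@dataclasses.dataclass
class PropagationResult:
    """Final converged scores over all N+M nodes plus diagnostics."""

    scores: np.ndarray
    iterations: int
    residual: float           # final squared-norm update
    alpha: float
    eps: float
    residual_history: np.ndarray


def dampen(w: sp.spmatrix, exponent: int = 2) -> sp.csr_matrix:
    """Divide a non-negative block by ``(1 + max(W))**exponent`` where
    ``max(W)`` is the block's global maximum; a zero block maps to itself.
    The zero pattern is preserved."""
    w = w.tocsr()
    mx = w.data.max() if w.nnz else 0.0
    if mx < 0 or (w.nnz and w.data.min() < 0):
        raise ValueError("dampen expects a non-negative matrix")
    return w / ((1.0 + mx) ** exponent)


def _biased_block(x: sp.spmatrix, s0_target: np.ndarray) -> sp.csr_matrix:
    """Row-normalise a dampened block and scale each column by the target
    node's initial score. Zero rows stay zero (no NaN)."""
    x = x.tocsr()
    rs = np.asarray(x.sum(axis=1)).ravel()
    inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
    out = sp.diags(inv) @ x @ sp.diags(np.asarray(s0_target, float))
    out = out.tocsr()
    out.eliminate_zeros()
    return out


def build_ndpm(het: HeteroNetwork, s0: InitialScores,
               config: KFPMConfig | None = None) -> TransitionMatrix:
    """Build the score-biased distribution-probability matrix.

    Block layout matches the network: protein->protein, protein->domain,
    domain->protein (the transposed dampened membership block) and
    domain->domain, each biased by the initial score of the target node.
    """
    cfg = config or KFPMConfig()
    if len(s0.s0) != het.n + het.m or s0.n_proteins != het.n:
        raise ValueError("initial scores do not match network size")
    sp_, sd_ = s0.protein_scores, s0.domain_scores
    ppn = dampen(het.wpp, cfg.dampen_exponent)
    pdn = dampen(het.wpd, cfg.dampen_exponent)
    ddn = dampen(het.wdd, cfg.dampen_exponent)
    blocks = [[_biased_block(ppn, sp_), _biased_block(pdn, sd_)],
              [_biased_block(pdn.T.tocsr(), sp_), _biased_block(ddn, sd_)]]
    ndpm = sp.bmat(blocks, format="csr")
    if cfg.row_renorm:
        rs = np.asarray(ndpm.sum(axis=1)).ravel()
        inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
        ndpm = (sp.diags(inv) @ ndpm).tocsr()
    ndpm.eliminate_zeros()
    return TransitionMatrix(ndpm=ndpm, n_proteins=het.n,
                            row_normalized=cfg.row_renorm,
                            ppn=ppn, pdn=pdn, ddn=ddn)


def propagate(ndpm: TransitionMatrix | sp.spmatrix, s0: InitialScores
              | np.ndarray, alpha: float = 0.5, eps: float = 1e-6,
              max_iter: int = 1000) -> PropagationResult:
    """Iterate the restart propagation to a fixed point.

    The restart vector is S0 normalised to sum 1. Stops when
    ``||S(t+1) - S(t)||^2 < eps``; raises :class:`ConvergenceError`
    (carrying the last residual) if ``max_iter`` rounds do not suffice.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    p = ndpm.ndpm if isinstance(ndpm, TransitionMatrix) else ndpm.tocsr()
    v = s0.s0 if isinstance(s0, InitialScores) else np.asarray(s0, float)
    if p.shape[0] != p.shape[1] or p.shape[0] != len(v):
        raise ValueError("transition matrix and score vector sizes differ")
    total = v.sum()
    if total <= 0:
        raise ValueError("initial scores sum to zero; nothing to propagate")
    restart = v / total
    pt = p.T.tocsr()
    s = restart.copy()
    history = []
    for it in range(1, max_iter + 1):
        s_new = alpha * (pt @ s) + (1.0 - alpha) * restart
        res = float(((s_new - s) ** 2).sum())
        history.append(res)
        s = s_new
        if res < eps:
            logger.debug("propagate: converged in %d iterations "
                         "(residual %.3e)", it, res)
            return PropagationResult(scores=s, iterations=it, residual=res,
                                     alpha=alpha, eps=eps,
                                     residual_history=np.array(history))
    raise ConvergenceError(
        f"propagation did not converge in {max_iter} iterations "
        f"(last squared residual {history[-1]:.3e} >= eps {eps:.3e})",
        residual=history[-1], iterations=max_iter)


def rank(result: PropagationResult, proteins: list[str],
         essential: set[str] | None = None) -> RankedList:
    """Order proteins by final score (descending; ties broken by ID
    ascending). Domain nodes are discarded."""
    n = len(proteins)
    scores = result.scores[:n]
    order = sorted(range(n), key=lambda i: (-scores[i], proteins[i]))
    ids = [proteins[i] for i in order]
    vals = scores[order]
    flags = None
    if essential is not None:
        ess = essential.proteins if hasattr(essential, "proteins") \
            else essential
        flags = np.array([p in ess for p in ids])
    return RankedList(proteins=ids, scores=vals, essential=flags)
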