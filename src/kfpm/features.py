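"""Biological and topological node features and initial scores.

Three biological features are computed per PPI protein:

* orthology: the protein's orthology count divided by the maximum count over
  the network (conserved proteins score near 1);
* co-expression: the sum of Pearson correlations between the protein's
  expression profile and each PPI neighbour's profile;
* subcellular localisation: the sum, over the protein's compartments, of the
  compartment's enrichment ``Eve(i) = N(i) / mean_j N(j)`` where ``N(i)``
  counts PPI proteins annotated to compartment ``i``.

The three columns are fused with CRITIC (Criteria Importance Through
Intercriteria Correlation) weights — each feature's weight is its
contrast (standard deviation) times its conflict (summed ``1 - |r|``
against the other features) — and combined with a topology score into one
initial score per node. Domain nodes inherit the summed scores of their
member proteins, max-normalised over domains.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io import (ExpressionMatrix, OrthologyTable, PPIGraph, SubcellTable)
from .network import HeteroNetwork

logger = logging.getLogger("kfpm")

FEATURE_NAMES = ("orthology", "coexpression", "subcellular")


@dataclasses.dataclass
class CriticWeights:
    """CRITIC weighting diagnostics: final weights, per-feature information
    content C, the feature correlation matrix and column SDs."""

    weights: np.ndarray          # (3,), sums to 1
    information: np.ndarray      # (3,), C_j
    correlation: np.ndarray      # (3, 3)
    sigma: np.ndarray            # (3,)
    uniform_fallback: bool = False


@dataclasses.dataclass
class InitialScores:
    """Initial scores for all N+M nodes, proteins first then domains."""

    s0: np.ndarray
    n_proteins: int
    theta: float

    @property
    def protein_scores(self) -> np.ndarray:
        return self.s0[:self.n_proteins]

    @property
    def domain_scores(self) -> np.ndarray:
        return self.s0[self.n_proteins:]


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------

def orthology_score(tab: OrthologyTable,
                    proteins: Sequence[str]) -> np.ndarray:
    """Max-normalised orthology counts over the given protein order;
    proteins missing from the table score 0."""
    raw = np.array([tab.counts.get(p, 0.0) for p in proteins], dtype=float)
    mx = raw.max(initial=0.0)
    if mx <= 0:
        logger.warning("orthology_score: no positive counts; all scores 0")
        return np.zeros(len(proteins))
    return raw / mx


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation (1/(n-1) convention, sample SDs).

    Defined as 0 when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pcc needs two equal-length vectors, n >= 2")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        return 0.0
    z = ((x - x.mean()) / sx) * ((y - y.mean()) / sy)
    return float(z.sum() / (len(x) - 1))


def _standardised_profiles(expr: ExpressionMatrix,
                           proteins: Sequence[str]) -> np.ndarray:
    """N x L matrix of standardised profiles ((x - mean)/sample SD); zero
    rows for missing or constant profiles so their correlations vanish."""
    z = np.zeros((len(proteins), expr.length))
    for i, p in enumerate(proteins):
        v = expr.profiles.get(p)
        if v is None:
            continue
        s = v.std(ddof=1)
        if s == 0:
            continue
        z[i] = (v - v.mean()) / s
    return z


def expression_score(expr: ExpressionMatrix, g: PPIGraph) -> np.ndarray:
    """Per-protein sum of Pearson correlations with PPI neighbours.

    Pairs where either profile is missing (or constant) contribute 0;
    isolated proteins score 0.
    """
    z = _standardised_profiles(expr, g.proteins)
    out = np.zeros(g.n)
    denom = expr.length - 1
    for i, j in g.edges:
        r = float(z[i] @ z[j]) / denom
        out[i] += r
        out[j] += r
    return out


def subcellular_score(sub: SubcellTable,
                      proteins: Sequence[str]) -> np.ndarray:
    """Sum of compartment enrichments over each protein's localisations.

    Compartment counts are taken over the given (PPI) protein set; the
    enrichment of compartment i is its count divided by the mean count
    across the declared label universe.
    """
    counts = {lab: 0 for lab in sub.universe}
    pset = list(proteins)
    for p in pset:
        for lab in sub.localizations.get(p, ()):
            counts[lab] += 1
    ave = sum(counts.values()) / sub.n_sub
    if ave == 0:
        logger.warning("subcellular_score: no annotated PPI proteins; "
                       "all scores 0")
        return np.zeros(len(pset))
    eve = {lab: c / ave for lab, c in counts.items()}
    return np.array([sum(eve[lab] for lab in sub.localizations.get(p, ()))
                     for p in pset])


# ---------------------------------------------------------------------------
# CRITIC fusion
# ---------------------------------------------------------------------------

def _minmax_columns(f: np.ndarray) -> np.ndarray:
    lo = f.min(axis=0)
    hi = f.max(axis=0)
    span = hi - lo
    out = np.zeros_like(f, dtype=float)
    ok = span > 0
    out[:, ok] = (f[:, ok] - lo[ok]) / span[ok]
    return out


def critic_weights(features: np.ndarray, raw: bool = False) -> CriticWeights:
    """Objective feature weights by contrast and conflict.

    Each column is min-max scaled to [0, 1] first (disable with ``raw``) so
    the three criteria are commensurable; the weight of feature j is
    ``C_j / sum_k C_k`` with ``C_j = sigma_j * sum_i (1 - |r_ij|)``.
    A constant column has sigma 0 and therefore weight 0. If every C is 0
    (e.g. all columns identical) the weights fall back to uniform.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ValueError("critic_weights needs an (N >= 2) x k feature table")
    if not raw:
        f = _minmax_columns(f)
    k = f.shape[1]
    sigma = f.std(axis=0, ddof=1)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if sigma[i] > 0 and sigma[j] > 0:
                r[i, j] = r[j, i] = pcc(f[:, i], f[:, j])
            else:
                r[i, j] = r[j, i] = 0.0
    c = sigma * (1.0 - np.abs(r)).sum(axis=0)
    total = c.sum()
    if total <= 0:
        logger.warning("critic_weights: degenerate feature table; "
                       "falling back to uniform weights")
        return CriticWeights(weights=np.full(k, 1.0 / k), information=c,
                             correlation=r, sigma=sigma,
                             uniform_fallback=True)
    return CriticWeights(weights=c / total, information=c, correlation=r,
                         sigma=sigma)


def bio_score(features: np.ndarray, w: CriticWeights,
              raw: bool = False) -> np.ndarray:
    """Weighted sum of the (min-max scaled, unless ``raw``) feature columns."""
    f = np.asarray(features, dtype=float)
    if not raw:
        f = _minmax_columns(f)
    return f @ w.weights


# ---------------------------------------------------------------------------
# topology and initial scores
# ---------------------------------------------------------------------------

def topology_score(het: HeteroNetwork,
                   on_ppi_only: bool = False) -> np.ndarray:
    """Average shared-neighbour count per protein on the heterogeneous
    network.

    ``TOP(u) = sum_{v in NG(u)} |NG(u) & NG(v)| / |NG(u)|`` with NG the
    unweighted neighbourhood of the assembled adjacency (positive entries
    of NWPD), so both protein and domain neighbours count. Isolated nodes
    score 0. ``on_ppi_only`` restricts NG to the weighted PPI block.
    """
    base = het.wpp if on_ppi_only else het.nwpd
    a = (base > 0).astype(float).tocsr()
    shared = (a @ a).multiply(a)
    deg = np.asarray(a.sum(axis=1)).ravel()
    tot = np.asarray(shared.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        top = np.where(deg > 0, tot / np.where(deg > 0, deg, 1.0), 0.0)
    return top[:het.n]


def initial_scores(bio: np.ndarray, top: np.ndarray, theta: float,
                   wpd: sp.spmatrix) -> InitialScores:
    """Blend biological and topological scores and derive domain scores.

    Protein score: ``theta * BIO + (1 - theta) * TOP``. Each domain sums
    the scores of its member proteins; domain scores are then divided by
    their maximum so the best domain scores 1 (all-zero if no domain has
    positive score).
    """
    if not 0.0 < theta < 1.0:
        # theta = 1 (pure biology) is permitted for boundary analysis only
        if theta != 1.0:
            raise ValueError(f"theta must lie in (0, 1], got {theta}")
    n = len(bio)
    if len(top) != n or wpd.shape[0] != n:
        raise ValueError("bio/top/WPD sizes are inconsistent")
    s0p = theta * np.asarray(bio, float) + (1.0 - theta) * np.asarray(top,
                                                                      float)
    sdom = np.asarray((wpd.T @ s0p)).ravel()
    mx = sdom.max(initial=0.0)
    if mx > 0:
        s0d = sdom / mx
    else:
        logger.warning("initial_scores: all domain scores are 0")
        s0d = np.zeros(wpd.shape[1])
    return InitialScores(s0=np.concatenate([s0p, s0d]), n_proteins=n,
                         theta=theta)


def feature_table(bio_i: np.ndarray, bio_exp: np.ndarray,
                  bio_sub: np.ndarray) -> np.ndarray:
    """Stack the three biological feature vectors into the N x 3 table used
    by CRITIC, in the canonical column order."""
    return np.column_stack([bio_i, bio_exp, bio_sub])
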