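"""Heterogeneous protein-domain network construction.

Three weight blocks are built and assembled into one symmetric adjacency:

* ``WPP`` (N x N): each PPI edge (u, v) is weighted by
  ``|NG(u) & NG(v)|**2 / ((|NG(u)|+1) * (|NG(v)|+1))`` — a squared
  common-neighbour count normalised by the two (degree + 1) terms, so
  edges embedded in dense neighbourhoods score high. Non-edges and the
  diagonal are 0.
* ``WPD`` (N x M): binary protein-domain membership.
* ``WDD`` (M x M): for two distinct non-empty domains,
  ``|N(du) & N(dv)| / (|N(du)| * |N(dv)|)`` where ``N(d)`` is the set of
  PPI proteins carrying domain ``d``.
* ``NWPD``: the (N+M) x (N+M) block matrix ``[[WPP, WPD], [WPD^T, WDD]]``,
  proteins first, then domains.

Domain protein-sets are restricted to PPI nodes throughout so WPD and WDD
stay mutually consistent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .config import KFPMConfig
from .io import DomainAnnotation, PPIGraph


@dataclasses.dataclass
class HeteroNetwork:
    """The assembled heterogeneous network and its blocks.

    All matrices are CSR; node order is ``proteins`` (indices 0..N-1)
    followed by ``domains`` (indices N..N+M-1).
    """

    proteins: list[str]
    domains: list[str]
    wpp: sp.csr_matrix
    wpd: sp.csr_matrix
    wdd: sp.csr_matrix
    nwpd: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def m(self) -> int:
        return len(self.domains)


def build_wpp(g: PPIGraph, exponent: int = 2) -> sp.csr_matrix:
    """Weighted PPI adjacency.

    For adjacent u, v the weight is
    ``c(u,v)**exponent / ((d_u + 1) * (d_v + 1))`` with ``c`` the
    common-neighbour count and ``d`` the PPI degree; 0 elsewhere.
    Isolated nodes simply yield zero rows.
    """
    a = g.adjacency()
    # (A @ A) counts common neighbours for every pair; masking with A keeps
    # only adjacent pairs, which also zeroes the diagonal.
    common = (a @ a).multiply(a).tocoo()
    deg = np.asarray(a.sum(axis=1)).ravel()
    vals = (common.data ** exponent) / (
        (deg[common.row] + 1.0) * (deg[common.col] + 1.0))
    w = sp.coo_matrix((vals, (common.row, common.col)), shape=a.shape)
    return w.tocsr()


def build_wpd(g: PPIGraph, ann: DomainAnnotation) -> sp.csr_matrix:
    """Binary N x M protein-domain membership matrix; annotation entries for
    proteins outside the PPI node set contribute nothing."""
    pidx = g.index
    didx = {d: j for j, d in enumerate(ann.domains)}
    rows, cols = [], []
    for p, d in ann.membership:
        if p in pidx:
            rows.append(pidx[p])
            cols.append(didx[d])
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(g.n, ann.m))


def build_wdd(wpd: sp.csr_matrix,
              sqrt_denominator: bool = False) -> sp.csr_matrix:
    """M x M domain-domain weights from the membership matrix.

    ``WDD(u, v) = shared / (n_u * n_v)`` for distinct domains with
    ``n_u, n_v > 0``, where ``shared`` counts proteins carrying both.
    ``sqrt_denominator`` switches to ``shared / sqrt(n_u * n_v)``
    (the cosine-similarity form). Diagonal is 0.
    """
    b = wpd.tocsc()
    shared = (b.T @ b).tocoo()
    sizes = np.asarray(b.sum(axis=0)).ravel()
    off = shared.row != shared.col
    rows, cols, cnt = shared.row[off], shared.col[off], shared.data[off]
    denom = sizes[rows] * sizes[cols]
    if sqrt_denominator:
        denom = np.sqrt(denom)
    vals = cnt / denom
    m = wpd.shape[1]
    return sp.csr_matrix((vals, (rows, cols)), shape=(m, m))


def assemble_nwpd(wpp: sp.spmatrix, wpd: sp.spmatrix,
                  wdd: sp.spmatrix) -> sp.csr_matrix:
    """Assemble the (N+M) x (N+M) block adjacency
    ``[[WPP, WPD], [WPD^T, WDD]]``."""
    n, m = wpd.shape
    if wpp.shape != (n, n) or wdd.shape != (m, m):
        raise ValueError(
            f"inconsistent block shapes: WPP {wpp.shape}, WPD {wpd.shape}, "
            f"WDD {wdd.shape}")
    return sp.bmat([[wpp, wpd], [wpd.T, wdd]], format="csr")


def build_hetero_network(g: PPIGraph, ann: DomainAnnotation,
                         config: KFPMConfig | None = None) -> HeteroNetwork:
    """Build all blocks and the assembled adjacency in one call."""
    cfg = config or KFPMConfig()
    wpp = build_wpp(g, exponent=cfg.wpp_exponent)
    wpd = build_wpd(g, ann)
    wdd = build_wdd(wpd, sqrt_denominator=cfg.wdd_sqrt_denominator)
    nwpd = assemble_nwpd(wpp, wpd, wdd)
    return HeteroNetwork(proteins=list(g.proteins), domains=list(ann.domains),
                         wpp=wpp, wpd=wpd, wdd=wdd, nwpd=nwpd)


def dump_matrix(mat: sp.spmatrix, path, node_order_path=None,
                labels=None) -> None:
    """Optional MatrixMarket dump for inspection, with a sidecar TSV of node
    labels when given."""
    import scipy.io as sio

    sio.mmwrite(str(path), sp.coo_matrix(mat))
    if node_order_path is not None and labels is not None:
        with open(node_order_path, "w", encoding="utf-8") as fh:
            for k, lab in enumerate(labels):
                fh.write(f"{k}\t{lab}\n")
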