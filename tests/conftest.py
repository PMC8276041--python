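"""Shared fixtures and independent brute-force oracles.

The oracles deliberately recompute every quantity with naive Python loops
over explicit neighbour sets so they share no code path with the package's
sparse-matrix implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from kfpm import PPIGraph, worked_example


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_bundle():
    return worked_example()


@pytest.fixture
def triangle():
    return PPIGraph(proteins=["a", "b", "c"],
                    edges={(0, 1), (0, 2), (1, 2)})


@pytest.fixture
def path3():
    return PPIGraph(proteins=["a", "b", "c"], edges={(0, 1), (1, 2)})


def random_graph(n: int, p: float, rng: np.random.Generator) -> PPIGraph:
    """Erdos-Renyi graph with string node IDs."""
    edges = {(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p}
    return PPIGraph(proteins=[f"n{i:03d}" for i in range(n)], edges=edges)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def naive_wpp(g: PPIGraph, exponent: int = 2) -> np.ndarray:
    nb = g.neighbor_sets()
    w = np.zeros((g.n, g.n))
    for i, j in g.edges:
        c = len(nb[i] & nb[j])
        val = c ** exponent / ((len(nb[i]) + 1) * (len(nb[j]) + 1))
        w[i, j] = w[j, i] = val
    return w


def naive_wdd(domain_members: list[set[int]]) -> np.ndarray:
    m = len(domain_members)
    w = np.zeros((m, m))
    for u in range(m):
        for v in range(m):
            if u == v:
                continue
            nu, nv = domain_members[u], domain_members[v]
            if nu and nv:
                w[u, v] = len(nu & nv) / (len(nu) * len(nv))
    return w


def naive_top(adj: list[set[int]], n_proteins: int) -> np.ndarray:
    """Topology score from explicit heterogeneous neighbour sets."""
    out = np.zeros(n_proteins)
    for u in range(n_proteins):
        if not adj[u]:
            continue
        out[u] = sum(len(adj[u] & adj[v]) for v in adj[u]) / len(adj[u])
    return out


def hetero_adjacency_sets(wpp, wpd, wdd) -> list[set[int]]:
    """Neighbour sets of the assembled network (positive entries only)."""
    n, m = wpd.shape
    wpp = np.asarray(wpp.todense())
    wpd = np.asarray(wpd.todense())
    wdd = np.asarray(wdd.todense())
    adj: list[set[int]] = [set() for _ in range(n + m)]
    for i in range(n):
        for j in range(n):
            if wpp[i, j] > 0:
                adj[i].add(j)
    for i in range(n):
        for j in range(m):
            if wpd[i, j] > 0:
                adj[i].add(n + j)
                adj[n + j].add(i)
    for i in range(m):
        for j in range(m):
            if wdd[i, j] > 0:
                adj[n + i].add(n + j)
    return adj
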