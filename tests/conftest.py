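"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (exhaustive enumeration, plain-loop
formulas) and share no code with the package, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force clique percolation oracle
# ---------------------------------------------------------------------------

def cpm_oracle(g: nx.Graph, k: int) -> set[frozenset]:
    """Clique percolation by exhaustive enumeration + union-find.

    Enumerates every k-node subset, keeps the complete ones, joins cliques
    sharing k-1 nodes, and returns the union of each group as a community.
    Exponential; only usable on tiny graphs.
    """
    nodes = sorted(g.nodes)
    cliques = [
        frozenset(c)
        for c in itertools.combinations(nodes, k)
        if all(g.has_edge(a, b) for a, b in itertools.combinations(c, 2))
    ]
    parent = list(range(len(cliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            parent[find(i)] = find(j)

    groups: dict[int, set] = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    return {frozenset(m) for m in groups.values()}


# ---------------------------------------------------------------------------
# straight-from-formula meta-analysis oracle
# ---------------------------------------------------------------------------

def meta_oracle(ys: list[float], vs: list[float]) -> dict:
    """Fixed-effect summary, Q, I^2, and DerSimonian-Laird tau^2 via plain
    loops, written directly from the defining formulas."""
    ws = [1.0 / v for v in vs]
    sw = sum(ws)
    m = sum(w * y for w, y in zip(ws, ys)) / sw
    v_m = 1.0 / sw
    z = m / math.sqrt(v_m)
    q = sum(w * (y - m) ** 2 for w, y in zip(ws, ys))
    df = len(ys) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = sw - sum(w * w for w in ws) / sw
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return {"M": m, "V_M": v_m, "Z": z, "Q": q, "I2": i2, "tau2": tau2}


# ---------------------------------------------------------------------------
# exhaustive hypergeometric tail oracle
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(background: int, pathway: int, query: int, observed: int) -> float:
    """P(overlap >= observed) by enumerating every C(background, query) draw."""
    universe = range(background)
    in_pathway = set(range(pathway))
    total = 0
    at_least = 0
    for draw in itertools.combinations(universe, query):
        total += 1
        if len(in_pathway.intersection(draw)) >= observed:
            at_least += 1
    return at_least / total


@pytest.fixture
def rng():
    return np.random.default_rng(20140818)
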