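"""Independent reference implementations used as test oracles.

These deliberately use the most literal possible formulations (nested
loops, exhaustive enumeration, textbook formulas) so that agreement with
the package's optimized implementations is meaningful evidence.
"""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


def nested_loop_agreement(rm) -> dict[frozenset, int]:
    """Pairwise agreement counts by direct double loop over students."""
    out = {}
    students = rm.students
    for i, a in enumerate(students):
        for b in students[i + 1:]:
            n = 0
            for q in rm.questions:
                va, vb = rm.choices.at[a, q], rm.choices.at[b, q]
                if pd.notna(va) and pd.notna(vb) and va == vb:
                    n += 1
            out[frozenset((a, b))] = n
    return out


def brute_force_backbone_edges(g: nx.Graph, alpha: float, rule: str = "either-endpoint"):
    """Edge retention by explicit per-node empirical-CDF evaluation."""
    keep = set()
    for u, v in g.edges:
        passes = []
        for a, b in ((u, v), (v, u)):
            ws = np.array([g[a][x]["weight"] for x in g[a]], dtype=float)
            frac = g[a][b]["weight"] / ws.sum()
            pval = float((ws / ws.sum() > frac).sum()) / len(ws)
            passes.append(pval < alpha)
        ok = any(passes) if rule == "either-endpoint" else all(passes)
        if ok:
            keep.add(frozenset((u, v)))
    return keep


def set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth strings."""
    a = [0] * n
    yield list(a)
    while True:
        j = n - 1
        while j > 0 and a[j] == max(a[:j]) + 1:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        for k in range(j + 1, n):
            a[k] = 0
        yield list(a)


def literal_map_equation(g: nx.Graph, assign) -> float:
    """Two-level map equation evaluated term by term from its definition."""
    strength = dict(g.degree(weight="weight"))
    two_w = sum(strength.values())
    p = {n: strength[n] / two_w for n in g.nodes}
    comms = {}
    for n in g.nodes:
        comms.setdefault(assign[n], []).append(n)
    cut = {c: 0.0 for c in comms}
    for u, v, d in g.edges(data=True):
        if assign[u] != assign[v]:
            cut[assign[u]] += d["weight"]
            cut[assign[v]] += d["weight"]
    q_i = {c: cut[c] / two_w for c in comms}
    q = sum(q_i.values())

    def plogp(x):
        return x * math.log2(x) if x > 0 else 0.0

    total = 0.0
    if q > 0:
        total += q * (-sum(plogp(q_i[c] / q) for c in comms))
    for c, nodes in comms.items():
        p_circ = q_i[c] + sum(p[n] for n in nodes)
        if p_circ > 0:
            total += p_circ * (
                -plogp(q_i[c] / p_circ) - sum(plogp(p[n] / p_circ) for n in nodes)
            )
    return total


def random_connected_graph(rng: np.random.Generator, n: int, extra_p: float = 0.3) -> nx.Graph:
    """Random spanning tree plus extra edges, integer weights in [1, 9]."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[int(rng.integers(i))]
        g.add_edge(int(order[i]), int(j), weight=int(rng.integers(1, 10)))
    for u, v in combinations(range(n), 2):
        if not g.has_edge(u, v) and rng.random() < extra_p:
            g.add_edge(u, v, weight=int(rng.integers(1, 10)))
    return g


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> nx.Graph:
    """Erdos-Renyi-style graph (possibly disconnected), weights in [1, 19]."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v, weight=float(rng.integers(1, 20)))
    return g
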