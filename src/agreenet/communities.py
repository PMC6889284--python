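"""Two-level map-equation community detection on weighted undirected graphs.

The map equation scores a partition M by the expected per-step description
length (bits) of a random walk encoded with a two-level codebook::

    L(M) = q * H(Q) + sum_i p_i^circ * H(P^i)

where node visit rates are strength-proportional (p_a = s_a / 2W, no
teleportation — the undirected simplification), q_i is the walk's exit
probability from community i (cut_i / 2W), q = sum_i q_i, H(Q) the entropy
of the normalized exit rates, p_i^circ = q_i + sum_{a in i} p_a, and H(P^i)
the entropy of community i's normalized (exit, member-visit) vector.

``detect_communities`` minimizes L with a greedy two-phase search (local
node moves, then community aggregation, repeated to convergence) restarted
from seeded shuffled node orders, keeping the best trial. Only local moves
that strictly decrease L are accepted, so descent is monotone within a
trial. Weighted Newman-Girvan modularity of the resulting partition is
reported alongside, but never optimized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "Partition",
    "SearchConfig",
    "node_visit_rates",
    "map_equation",
    "modularity",
    "detect_communities",
    "select_normative_groups",
    "compare_partitions",
]


def _plogp(x: float) -> float:
    return x * np.log2(x) if x > 0.0 else 0.0


def node_visit_rates(g: nx.Graph) -> dict:
    """Stationary visit rate of an unbiased random walk on ``g``.

    p[a] = strength(a) / (2 W). Isolated nodes get rate 0 (the walk never
    reaches them); rates sum to 1.
    """
    strength = dict(g.degree(weight="weight"))
    total = sum(strength.values())  # = 2W
    if total <= 0:
        raise ValueError("visit rates undefined: graph has no positive-weight edge")
    return {n: s / total for n, s in strength.items()}


def map_equation(g: nx.Graph, assign: Mapping) -> float:
    """Two-level map-equation description length of a partition, in bits.

    ``assign`` maps every non-isolated node of ``g`` to a community label.
    Communities consisting only of isolated nodes contribute nothing and
    trigger a warning. The one-module limit equals the entropy of the
    visit-rate vector exactly.
    """
    p = node_visit_rates(g)
    two_w = sum(dict(g.degree(weight="weight")).values())
    members: dict = {}
    for n in g.nodes:
        if g.degree(n) == 0:
            continue
        if n not in assign:
            raise ValueError(f"partition does not cover non-isolated node {n!r}")
        members.setdefault(assign[n], []).append(n)
    for n, label in assign.items():
        if label not in members:
            warnings.warn(
                f"community {label!r} contains only isolated nodes; it contributes 0 bits"
            )
            break

    cut = dict.fromkeys(members, 0.0)
    for u, v, d in g.edges(data=True):
        if u == v:
            continue
        if assign[u] != assign[v]:
            cut[assign[u]] += d["weight"]
            cut[assign[v]] += d["weight"]

    q_i = {c: cut[c] / two_w for c in members}
    q = sum(q_i.values())
    # index codebook: entropy of exit rates, weighted by total exit rate
    h_q = -sum(_plogp(q_i[c] / q) for c in members) if q > 0 else 0.0
    length = q * h_q
    # module codebooks: entropy over (exit, member visit rates)
    for c, nodes in members.items():
        p_circ = q_i[c] + sum(p[n] for n in nodes)
        if p_circ <= 0:
            continue
        h = -_plogp(q_i[c] / p_circ) - sum(_plogp(p[n] / p_circ) for n in nodes)
        length += p_circ * h
    return float(length)


def modularity(g: nx.Graph, assign: Mapping) -> float:
    """Weighted Newman-Girvan modularity Q of a partition.

    Q = sum_c [ w_in(c)/W - (s(c) / 2W)^2 ] with w_in(c) the weight inside
    community c, s(c) the summed node strength, W the total edge weight.
    """
    two_w = sum(dict(g.degree(weight="weight")).values())
    if two_w <= 0:
        raise ValueError("modularity undefined on an edgeless graph")
    w = two_w / 2.0
    w_in: dict = {}
    s: dict = {}
    for n in g.nodes:
        if n in assign:
            s[assign[n]] = s.get(assign[n], 0.0) + g.degree(n, weight="weight")
    for u, v, d in g.edges(data=True):
        if assign[u] == assign[v]:
            w_in[assign[u]] = w_in.get(assign[u], 0.0) + d["weight"]
    return float(
        sum(w_in.get(c, 0.0) / w - (s[c] / two_w) ** 2 for c in s)
    )


@dataclass(frozen=True)
class Partition:
    """A hard partition of graph nodes with its quality scores."""

    assign: dict
    map_score: float
    modularity_q: float

    def __post_init__(self) -> None:
        labels = sorted(set(self.assign.values()))
        if labels and labels != list(range(len(labels))):
            raise ValueError("community labels must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.assign.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assign.values():
            out[c] = out.get(c, 0) + 1
        return out

    def members(self, label: int) -> list:
        return [n for n, c in self.assign.items() if c == label]

    def to_frame(self) -> pd.DataFrame:
        sizes = self.sizes()
        return pd.DataFrame(
            {
                "student_id": list(self.assign),
                "community": list(self.assign.values()),
                "community_size": [sizes[c] for c in self.assign.values()],
            }
        )


@dataclass(frozen=True)
class SearchConfig:
    """Search policy for :func:`detect_communities`.

    n_trials seeded restarts with shuffled node orders; the trial with
    minimal description length wins, ties to the first found. ``tolerance``
    is the minimum improvement (bits) to accept a local move.
    """

    n_trials: int = 100
    seed: int = 0
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


class _LevelGraph:
    """Flat arrays for one aggregation level of the search."""

    __slots__ = ("n", "adj", "self_loop", "strength", "two_w")

    def __init__(self, n: int, edges: list[tuple[int, int, float]]):
        self.n = n
        self.adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        self.self_loop = [0.0] * n
        self.strength = [0.0] * n
        for u, v, w in edges:
            if u == v:
                self.self_loop[u] += w
                self.strength[u] += 2.0 * w
            else:
                self.adj[u].append((v, w))
                self.adj[v].append((u, w))
                self.strength[u] += w
                self.strength[v] += w
        self.two_w = sum(self.strength)


def _optimize_level(lg: _LevelGraph, order: np.ndarray, tol: float) -> list[int]:
    """Greedy local moves minimizing the partition part of L; one level."""
    n, two_w = lg.n, lg.two_w
    comm = list(range(n))
    s_c = list(lg.strength)                       # summed strength per community
    win_c = list(lg.self_loop)                    # internal weight per community
    sum_q = sum((s_c[c] - 2.0 * win_c[c]) / two_w for c in range(n))

    def q_of(c: int) -> float:
        return (s_c[c] - 2.0 * win_c[c]) / two_w

    def term(qc: float, pc: float) -> float:
        return -2.0 * _plogp(qc) + _plogp(qc + pc)

    improved = True
    while improved:
        improved = False
        for a in order:
            a = int(a)
            c_old = comm[a]
            # links from a to each neighboring community (self-loop excluded)
            k: dict[int, float] = {}
            for b, w in lg.adj[a]:
                k[comm[b]] = k.get(comm[b], 0.0) + w
            s_a, sl_a = lg.strength[a], lg.self_loop[a]
            k_old = k.get(c_old, 0.0)

            q_old_before = q_of(c_old)
            # community state with a removed from c_old
            s_old_r = s_c[c_old] - s_a
            win_old_r = win_c[c_old] - k_old - sl_a
            q_old_after = (s_old_r - 2.0 * win_old_r) / two_w
            base_removed = term(q_old_after, s_old_r / two_w)
            base_current = term(q_old_before, s_c[c_old] / two_w)

            best_c, best_delta = c_old, 0.0
            for c_new, k_new in k.items():
                if c_new == c_old:
                    continue
                q_new_before = q_of(c_new)
                s_new_a = s_c[c_new] + s_a
                win_new_a = win_c[c_new] + k_new + sl_a
                q_new_after = (s_new_a - 2.0 * win_new_a) / two_w
                new_sum_q = sum_q - q_old_before - q_new_before + q_old_after + q_new_after
                delta = (
                    _plogp(new_sum_q) - _plogp(sum_q)
                    + base_removed - base_current
                    + term(q_new_after, s_new_a / two_w)
                    - term(q_new_before, s_c[c_new] / two_w)
                )
                if delta < best_delta - 1e-15:
                    best_c, best_delta = c_new, delta
            if best_c != c_old and -best_delta > tol:
                k_new = k[best_c]
                sum_q += (
                    -q_of(c_old) - q_of(best_c)
                )
                s_c[c_old] -= s_a
                win_c[c_old] -= k_old + sl_a
                s_c[best_c] += s_a
                win_c[best_c] += k_new + sl_a
                sum_q += q_of(c_old) + q_of(best_c)
                comm[a] = best_c
                improved = True
    return comm


def _search_trial(
    lg: _LevelGraph, rng: np.random.Generator, tol: float
) -> list[int]:
    """One restart: local moves + aggregation until convergence."""
    mapping = list(range(lg.n))  # original node -> current community label
    level = lg
    while True:
        order = rng.permutation(level.n)
        comm = _optimize_level(level, order, tol)
        labels = sorted(set(comm))
        relabel = {c: i for i, c in enumerate(labels)}
        comm = [relabel[c] for c in comm]
        mapping = [comm[mapping[a]] for a in range(lg.n)]
        n_next = len(labels)
        if n_next == level.n:
            return mapping
        # aggregate communities into supernodes
        agg: dict[tuple[int, int], float] = {}
        for u in range(level.n):
            cu = comm[u]
            if level.self_loop[u]:
                key = (cu, cu)
                agg[key] = agg.get(key, 0.0) + level.self_loop[u]
            for v, w in level.adj[u]:
                if u < v:
                    cu2, cv = sorted((cu, comm[v]))
                    agg[(cu2, cv)] = agg.get((cu2, cv), 0.0) + w
        level = _LevelGraph(n_next, [(u, v, w) for (u, v), w in agg.items()])


def detect_communities(g: nx.Graph, cfg: SearchConfig = SearchConfig()) -> Partition:
    """Find the minimal-description-length partition of ``g``.

    Isolated nodes become singleton communities (they carry no walk flow
    and are excluded from the objective). Deterministic for fixed
    (graph, config): restart r uses a child RNG seeded from cfg.seed.
    """
    active = [n for n in g.nodes if g.degree(n) > 0]
    if not active:
        raise ValueError("community detection requires at least one edge")
    idx = {n: i for i, n in enumerate(active)}
    edges = [(idx[u], idx[v], float(d["weight"])) for u, v, d in g.edges(data=True)]
    lg = _LevelGraph(len(active), edges)

    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=cfg.n_trials)
    best_assign: list[int] | None = None
    best_l = np.inf
    for s in seeds:
        mapping = _search_trial(lg, np.random.default_rng(int(s)), cfg.tolerance)
        assign = {n: mapping[idx[n]] for n in active}
        l = map_equation(g, assign)
        if l < best_l - 1e-12:
            best_l, best_assign = l, mapping
    assert best_assign is not None

    # canonical contiguous labels in node order; isolates appended as singletons
    assign: dict = {}
    relabel: dict[int, int] = {}
    for n in g.nodes:
        if n in idx:
            c = best_assign[idx[n]]
            if c not in relabel:
                relabel[c] = len(relabel)
            assign[n] = relabel[c]
    next_label = len(relabel)
    for n in g.nodes:
        if n not in idx:
            assign[n] = next_label
            next_label += 1
    return Partition(
        assign=assign,
        map_score=best_l,
        modularity_q=modularity(g, assign),
    )


def select_normative_groups(part: Partition, min_size: int = 10) -> list[int]:
    """Labels of communities with >= min_size members, largest first."""
    sizes = part.sizes()
    big = [c for c, n in sizes.items() if n >= min_size]
    return sorted(big, key=lambda c: (-sizes[c], c))


def compare_partitions(p1: Partition | Mapping, p2: Partition | Mapping) -> dict[str, float]:
    """Adjusted Rand index and normalized mutual information of two partitions."""
    a1 = p1.assign if isinstance(p1, Partition) else dict(p1)
    a2 = p2.assign if isinstance(p2, Partition) else dict(p2)
    if set(a1) != set(a2):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a1, key=str)
    x = [a1[n] for n in nodes]
    y = [a2[n] for n in nodes]
    return {
        "ari": float(adjusted_rand_score(x, y)),
        "nmi": float(normalized_mutual_info_score(x, y)),
    }
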