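"""Student agreement networks and their statistical backbone.

The response matrix is encoded as a bipartite students x (question, option)
incidence matrix M; its one-mode projection A = M M^T counts, for each
student pair, the questions on which the two chose the same option. The
backbone step keeps only edges whose weight is significant against a
node-local null: each endpoint ranks the edge's fractional weight
w_ij / strength(i) within the empirical distribution of its own incident
fractional weights, a locally adaptive, parameter-free sparsification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ResponseMatrix

__all__ = [
    "BipartiteIncidence",
    "BackboneConfig",
    "build_bipartite",
    "project_agreement",
    "edge_significance",
    "lans_backbone",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class BipartiteIncidence:
    """Binary students x (question, option) indicator matrix.

    ``matrix`` rows follow ``students``; columns follow ``columns``, the
    full list of (question_id, option) pairs in question-major order.
    A missing response leaves the whole option block of that question zero.
    """

    matrix: np.ndarray
    students: tuple[str, ...]
    columns: tuple[tuple[str, str], ...]

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def build_bipartite(rm: ResponseMatrix) -> BipartiteIncidence:
    """Encode a response matrix as a binary bipartite incidence matrix."""
    columns = [(q, opt) for q in rm.questions for opt in rm.options[q]]
    col_index = {pair: k for k, pair in enumerate(columns)}
    m = np.zeros((rm.n_students, len(columns)), dtype=np.int64)
    values = rm.choices.to_numpy(dtype=object)
    for i in range(rm.n_students):
        for j, q in enumerate(rm.questions):
            v = values[i, j]
            if pd.isna(v):
                continue
            m[i, col_index[(q, v)]] = 1
    return BipartiteIncidence(
        matrix=m, students=tuple(rm.students), columns=tuple(columns)
    )


def project_agreement(m: BipartiteIncidence) -> nx.Graph:
    """Project the bipartite incidence onto the weighted student network.

    Edge weight between students i and j is the number of questions on
    which both answered and chose the same option, i.e. (M M^T)[i, j];
    the diagonal is discarded. Zero-agreement pairs are non-edges.
    Every student is a node, so students agreeing with nobody stay in the
    graph as isolates.
    """
    if len(m.students) < 2:
        raise ValueError("agreement projection requires at least 2 students")
    a = m.matrix @ m.matrix.T
    g = nx.Graph(n_questions=len({q for q, _ in m.columns}))
    g.add_nodes_from(m.students)
    n = len(m.students)
    for i in range(n):
        for j in range(i + 1, n):
            w = int(a[i, j])
            if w > 0:
                g.add_edge(m.students[i], m.students[j], weight=w)
    return g


def edge_significance(g: nx.Graph) -> dict[tuple[str, str], float]:
    """Per-endpoint significance of every edge weight.

    For endpoint i of edge (i, j) the fractional weight is
    ``w_ij / strength(i)``. Its p-value is the fraction of i's incident
    edges whose fractional weight is strictly greater — one minus the
    empirical CDF (<= convention) over i's incident fractional weights.
    Ties therefore share a p-value, and a node's maximal edges get 0.

    Returns a dict keyed by the *directed* pair (i, j): the significance
    of edge {i, j} as judged from endpoint i.
    """
    if g.number_of_edges() == 0:
        raise ValueError("edge significance requires at least one edge")
    pvals: dict[tuple[str, str], float] = {}
    for node in g.nodes:
        nbrs = g[node]
        if not nbrs:
            continue  # isolates have no incident edges, nothing to emit
        weights = np.array([d["weight"] for d in nbrs.values()], dtype=float)
        strength = weights.sum()
        frac = weights / strength
        deg = len(weights)
        for (other, d), f in zip(nbrs.items(), frac):
            pvals[(node, other)] = float((frac > f).sum()) / deg
    return pvals


@dataclass(frozen=True)
class BackboneConfig:
    """Sparsification parameters.

    alpha : significance level; an endpoint passes when its p-value < alpha.
    rule  : 'either-endpoint' keeps an edge if at least one endpoint passes
            (the default); 'both-endpoints' requires both.
    """

    alpha: float = 0.01
    rule: str = "either-endpoint"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rule not in ("either-endpoint", "both-endpoints"):
            raise ValueError(f"unknown retention rule {self.rule!r}")


def lans_backbone(g: nx.Graph, cfg: BackboneConfig = BackboneConfig()) -> nx.Graph:
    """Extract the locally adaptive significance backbone of ``g``.

    All nodes are retained (isolates allowed); retained edges keep their
    original weights and carry ``pvalue_u`` / ``pvalue_v`` attributes (the
    significance at each endpoint, in node order of the edge tuple).
    """
    pvals = edge_significance(g)
    bb = nx.Graph(**g.graph)
    bb.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        pu, pv = pvals[(u, v)], pvals[(v, u)]
        if cfg.rule == "either-endpoint":
            keep = pu < cfg.alpha or pv < cfg.alpha
        else:
            keep = pu < cfg.alpha and pv < cfg.alpha
        if keep:
            bb.add_edge(u, v, weight=d["weight"], pvalue_u=pu, pvalue_v=pv)
    return bb


def write_edge_list(
    g: nx.Graph, backbone: nx.Graph, path: str | Path, nodes_path: str | Path | None = None
) -> None:
    """Write the full weighted edge list with significances and retention flags.

    The node list goes to ``nodes_path`` (default: path with '.nodes.csv')
    so isolated students survive serialization.
    """
    pvals = edge_significance(g)
    rows = [
        {
            "source": u,
            "target": v,
            "weight": d["weight"],
            "pvalue_src": pvals[(u, v)],
            "pvalue_tgt": pvals[(v, u)],
            "retained": backbone.has_edge(u, v),
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "pvalue_src", "pvalue_tgt", "retained"]).to_csv(path, index=False)
    if nodes_path is None:
        nodes_path = Path(path).with_suffix(".nodes.csv")
    pd.DataFrame({"student_id": list(g.nodes)}).to_csv(nodes_path, index=False)


def read_edge_list(path: str | Path, nodes_path: str | Path | None = None) -> tuple[nx.Graph, nx.Graph]:
    """Read back (full graph, backbone) from an edge-list CSV pair."""
    if nodes_path is None:
        nodes_path = Path(path).with_suffix(".nodes.csv")
    nodes = pd.read_csv(nodes_path, dtype=str)["student_id"].tolist()
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    g, bb = nx.Graph(), nx.Graph()
    g.add_nodes_from(nodes)
    bb.add_nodes_from(nodes)
    for r in df.itertuples():
        g.add_edge(r.source, r.target, weight=int(r.weight))
        if r.retained:
            bb.add_edge(
                r.source, r.target, weight=int(r.weight),
                pvalue_u=float(r.pvalue_src), pvalue_v=float(r.pvalue_tgt),
            )
    return g, bb
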