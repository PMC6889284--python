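"""Unit and property tests for the map equation, modularity and the search."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import (
    literal_map_equation,
    random_connected_graph,
    set_partitions,
)
from agreenet.communities import (
    Partition,
    SearchConfig,
    compare_partitions,
    detect_communities,
    map_equation,
    modularity,
    node_visit_rates,
    select_normative_groups,
)


def _two_cliques(w_bridge=1):
    g = nx.Graph()
    for group in (("a1", "a2", "a3"), ("b1", "b2", "b3")):
        for i, u in enumerate(group):
            for v in group[i + 1:]:
                g.add_edge(u, v, weight=5)
    g.add_edge("a1", "b1", weight=w_bridge)
    return g


def test_visit_rates_sum_to_one_and_isolates_zero():
    g = _two_cliques()
    g.add_node("iso")
    p = node_visit_rates(g)
    assert sum(p.values()) == pytest.approx(1.0)
    assert p["iso"] == 0.0
    with pytest.raises(ValueError):
        node_visit_rates(nx.Graph([("a", "b", {"weight": 0})]))


def test_one_module_equals_visit_rate_entropy():
    g = _two_cliques()
    p = node_visit_rates(g)
    h = -sum(v * math.log2(v) for v in p.values() if v > 0)
    assert map_equation(g, {n: 0 for n in g.nodes}) == pytest.approx(h, abs=1e-12)


@given(st.integers(0, 29))
def test_map_equation_matches_literal_formula(case):
    rng = np.random.default_rng(5000 + case)
    g = random_connected_graph(rng, int(rng.integers(3, 10)))
    labels = rng.integers(0, 3, size=g.number_of_nodes())
    assign = {n: int(labels[i]) for i, n in enumerate(g.nodes)}
    assert map_equation(g, assign) == pytest.approx(
        literal_map_equation(g, assign), abs=1e-12
    )


def test_map_equation_requires_coverage_and_warns_on_isolated_community():
    g = _two_cliques()
    with pytest.raises(ValueError, match="does not cover"):
        map_equation(g, {"a1": 0})
    g.add_node("iso")
    assign = {n: 0 for n in g.nodes if n != "iso"}
    assign["iso"] = 1
    with pytest.warns(UserWarning, match="only isolated nodes"):
        map_equation(g, assign)


@given(st.integers(0, 29))
def test_modularity_matches_networkx(case):
    rng = np.random.default_rng(6000 + case)
    g = random_connected_graph(rng, int(rng.integers(3, 10)))
    labels = rng.integers(0, 3, size=g.number_of_nodes())
    assign = {n: int(labels[i]) for i, n in enumerate(g.nodes)}
    comms = {}
    for n, c in assign.items():
        comms.setdefault(c, set()).add(n)
    ref = nx.algorithms.community.modularity(g, list(comms.values()), weight="weight")
    assert modularity(g, assign) == pytest.approx(ref, abs=1e-12)


def test_detect_separates_two_cliques():
    g = _two_cliques()
    part = detect_communities(g, SearchConfig(10, 0))
    assert part.n_communities == 2
    assert len({part.assign[n] for n in ("a1", "a2", "a3")}) == 1
    assert part.assign["a1"] != part.assign["b1"]
    # modularity is reported for the same partition
    assert part.modularity_q == pytest.approx(modularity(g, part.assign))


def test_detect_is_deterministic_and_isolates_are_singletons():
    g = _two_cliques()
    g.add_node("iso1")
    g.add_node("iso2")
    p1 = detect_communities(g, SearchConfig(10, 7))
    p2 = detect_communities(g, SearchConfig(10, 7))
    assert p1.assign == p2.assign and p1.map_score == p2.map_score
    assert p1.assign["iso1"] != p1.assign["iso2"]
    sizes = p1.sizes()
    assert sizes[p1.assign["iso1"]] == 1


def test_detect_requires_an_edge():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    with pytest.raises(ValueError, match="at least one edge"):
        detect_communities(g)


@given(st.integers(0, 14))
def test_detect_attains_exhaustive_minimum_small(case):
    rng = np.random.default_rng(7000 + case)
    n = int(rng.integers(3, 8))
    g = random_connected_graph(rng, n)
    nodes = list(g.nodes)
    best = min(
        literal_map_equation(g, dict(zip(nodes, rgs))) for rgs in set_partitions(n)
    )
    part = detect_communities(g, SearchConfig(20, case))
    assert part.map_score == pytest.approx(best, abs=1e-9)


def test_partition_labels_must_be_contiguous():
    with pytest.raises(ValueError, match="contiguous"):
        Partition(assign={"a": 0, "b": 2}, map_score=0.0, modularity_q=0.0)


def test_select_normative_groups_sorted_by_size():
    part = Partition(
        assign={f"s{i}": (0 if i < 12 else 1 if i < 22 else 2) for i in range(25)},
        map_score=0.0,
        modularity_q=0.0,
    )
    assert select_normative_groups(part, 10) == [0, 1]
    assert select_normative_groups(part, 3) == [0, 1, 2]


def test_compare_partitions_invariances():
    a = {f"s{i}": i % 3 for i in range(30)}
    relabeled = {s: (c + 1) % 3 for s, c in a.items()}
    res = compare_partitions(a, relabeled)
    assert res["ari"] == pytest.approx(1.0)
    assert res["nmi"] == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    random_labels = {s: int(rng.integers(3)) for s in a}
    assert abs(compare_partitions(a, random_labels)["ari"]) < 0.3
    with pytest.raises(ValueError, match="different node sets"):
        compare_partitions(a, {"x": 0})
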