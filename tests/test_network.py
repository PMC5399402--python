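"""Correlation networks: edge predicate, subnetworks, topology metrics."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scaldnet import (
    OmicsBlock,
    ValidationError,
    build_network,
    edge_table,
    first_neighbors,
    node_metrics,
    refine_members,
    write_graphml,
)
from scaldnet.network import CorrelationNetwork
from conftest import small_dataset


def _tiny_inputs(cluster_profiles, metabolite_profiles):
    """3 observations on days 0/7/14 from one treatment."""
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "treatment": ["control"] * 3,
            "day": [0, 7, 14],
            "replicate": [1, 1, 1],
            "scald": [1, 1, 1],
        }
    )
    cm = pd.DataFrame(
        cluster_profiles, columns=["s1", "s2", "s3"],
    )
    cm.index.name = "cluster_id"
    metab = OmicsBlock(
        "metabolome",
        pd.DataFrame(metabolite_profiles, index=["s1", "s2", "s3"]),
    )
    return cm, metab, meta


def _pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def test_edges_match_direct_pearson_formula():
    cm, metab, meta = _tiny_inputs(
        [[1.0, 2.0, 3.0]],
        {"perfect": [2.0, 4.0, 6.0], "partial": [1.0, 1.0, 2.0], "weak": [3.0, 2.9, 3.2]},
    )
    net = build_network(cm, metab, meta, window=(0, 7, 14))
    g = net.graph
    # x=(1,2,3) vs y=(2,4,6): r=1, weight 0
    assert g.has_edge("cluster_0", "perfect")
    assert g["cluster_0"]["perfect"]["weight"] == pytest.approx(0.0, abs=1e-12)
    # x=(1,2,3) vs y=(1,1,2): r^2 = 0.750, weight 0.250
    assert g.has_edge("cluster_0", "partial")
    assert g["cluster_0"]["partial"]["r2"] == pytest.approx(0.75, abs=1e-12)
    assert g["cluster_0"]["partial"]["weight"] == pytest.approx(0.25, abs=1e-12)
    # r^2 below 0.700: no edge (checked against the direct formula)
    assert _pearson([1, 2, 3], [3.0, 2.9, 3.2]) ** 2 < 0.700
    assert not g.has_edge("cluster_0", "weak")


def test_anticorrelation_qualifies_on_magnitude():
    cm, metab, meta = _tiny_inputs([[1.0, 2.0, 3.0]], {"down": [6.0, 4.0, 2.0]})
    net = build_network(cm, metab, meta, window=(0, 7, 14))
    assert net.graph.has_edge("cluster_0", "down")
    assert net.graph["cluster_0"]["down"]["r"] == pytest.approx(-1.0)


def test_constant_profiles_excluded():
    cm, metab, meta = _tiny_inputs([[1.0, 2.0, 3.0]], {"const": [5.0, 5.0, 5.0]})
    net = build_network(cm, metab, meta, window=(0, 7, 14))
    assert net.excluded == ["const"]
    assert "const" not in net.graph


def test_window_outside_design_rejected():
    cm, metab, meta = _tiny_inputs([[1.0, 2.0, 3.0]], {"m": [1.0, 2.0, 3.0]})
    with pytest.raises(ValidationError):
        build_network(cm, metab, meta, window=(0, 7, 99))


def test_stored_edges_reproducible_from_raw_profiles(planted):
    """Every stored edge r must match recomputation from the profiles."""
    from scaldnet import autoscale, cluster_means, filter_genes, kmeans_summarize, pca_smooth

    expr, metab, meta, _, _ = planted
    expr_f, _ = filter_genes(expr, meta)
    es, ms = autoscale(expr_f), autoscale(metab)
    profiles = es.block.data.T
    km = kmeans_summarize(pca_smooth(profiles.to_numpy(), 10),
                          gene_ids=list(profiles.index), k_init=25, seed=0)
    cm = cluster_means(km, profiles)
    net = build_network(cm, ms.block, meta, window=(0, 7, 14, 28, 61))
    sids = list(meta.loc[meta["day"].isin([0, 7, 14, 28, 61]), "sample_id"])
    assert net.graph.number_of_edges() > 0
    for u, v, d in net.graph.edges(data=True):
        def profile(node):
            if node.startswith("cluster_"):
                return cm.loc[int(node.split("_")[1]), sids].to_numpy()
            return ms.block.data.loc[sids, node].to_numpy()
        r = _pearson(profile(u), profile(v))
        assert d["r"] == pytest.approx(r, abs=1e-10)
        assert d["r2"] == pytest.approx(r * r, abs=1e-10)
        assert d["r2"] >= 0.700


# ---------------------------------------------------------------------------
# subnetworks
# ---------------------------------------------------------------------------

def _net_from_edges(nodes, edges):
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, kind="metabolite")
    for u, v in edges:
        g.add_edge(u, v, r=1.0, r2=1.0, weight=0.0)
    return CorrelationNetwork(graph=g, window_label="toy", window_days=(0,))


def test_first_neighbors_isolated_anchor():
    net = _net_from_edges(["a", "b", "c"], [("b", "c")])
    sub = first_neighbors(net, "a")
    assert list(sub.graph.nodes) == ["a"]
    assert sub.graph.number_of_edges() == 0


def test_first_neighbors_star_and_triangle():
    star = _net_from_edges(["s", "l1", "l2", "l3"], [("s", "l1"), ("s", "l2"), ("s", "l3")])
    sub = first_neighbors(star, "s")
    assert set(sub.graph.nodes) == {"s", "l1", "l2", "l3"}
    tri = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
    sub = first_neighbors(tri, "a")
    assert set(sub.graph.nodes) == {"a", "b", "c"}
    assert sub.graph.number_of_edges() == 3  # induced subgraph keeps b-c


def test_missing_anchor_named_in_error():
    net = _net_from_edges(["a"], [])
    with pytest.raises(ValidationError, match="ghost"):
        first_neighbors(net, "ghost")


# ---------------------------------------------------------------------------
# topology metrics vs brute force
# ---------------------------------------------------------------------------

def _brute_metrics(g):
    A = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    nodes = sorted(g.nodes)
    deg = A.sum(axis=1)
    out = {}
    for i, node in enumerate(nodes):
        nbrs = np.flatnonzero(A[i])
        conn = deg[nbrs].mean() if len(nbrs) else 0.0
        if len(nbrs) < 2:
            cc = 0.0
        else:
            links = sum(
                A[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1:]
            )
            cc = links / (len(nbrs) * (len(nbrs) - 1) / 2)
        out[node] = (deg[i], conn, cc)
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_metrics_match_bruteforce_on_random_graphs(seed):
    g = nx.gnp_random_graph(25, 0.15, seed=seed)
    g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
    nx.set_node_attributes(g, "metabolite", "kind")
    net = CorrelationNetwork(graph=g, window_label="rand", window_days=(0,))
    metrics = node_metrics(net).set_index("node")
    expected = _brute_metrics(g)
    for node, (deg, conn, cc) in expected.items():
        row = metrics.loc[node]
        assert row["degree"] == deg
        assert row["neighborhood_connectivity"] == pytest.approx(conn, abs=1e-12)
        assert row["clustering_coefficient"] == pytest.approx(cc, abs=1e-12)


def test_metrics_hand_worked_examples():
    path = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
    m = node_metrics(path).set_index("node")
    assert m.loc["b", "clustering_coefficient"] == 0.0
    assert m.loc["b", "neighborhood_connectivity"] == 1.0
    star = _net_from_edges(["s", "l1", "l2", "l3"], [("s", "l1"), ("s", "l2"), ("s", "l3")])
    m = node_metrics(star).set_index("node")
    assert m.loc["s", "neighborhood_connectivity"] == 1.0
    for leaf in ("l1", "l2", "l3"):
        assert m.loc[leaf, "neighborhood_connectivity"] == 3.0
    tri = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
    m = node_metrics(tri)
    assert (m["clustering_coefficient"] == 1.0).all()


# ---------------------------------------------------------------------------
# refinement + export
# ---------------------------------------------------------------------------

def test_refine_keeps_correlated_and_drops_noise():
    rng = np.random.default_rng(0)
    trace = pd.Series(np.linspace(1, 8, 12) ** 2, index=[f"s{i}" for i in range(12)])
    data = pd.DataFrame(
        {"tracks": trace.to_numpy() * 3.0 + 1.0, "noise": rng.standard_normal(12)},
        index=trace.index,
    )
    expr = OmicsBlock("transcriptome", data)
    kept = refine_members(["tracks", "noise"], expr, trace)
    assert kept == ["tracks"]


def test_refine_rejects_empty_window():
    expr = OmicsBlock("t", pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "b"]))
    with pytest.raises(ValidationError):
        refine_members(["g"], expr, pd.Series(dtype=float), sample_ids=[])


def test_graphml_round_trip(tmp_path):
    net = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
    path = tmp_path / "net.graphml"
    write_graphml(net, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == {"a", "b", "c"}
    assert back.nodes["b"]["degree"] == 2
    et = edge_table(net)
    assert list(et.columns) == ["source", "target", "r", "r2", "weight"]
    assert len(et) == 2
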