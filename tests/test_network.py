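"""Co-occurrence network construction, filtering and centrality."""

import math

import networkx as nx
import numpy as np
import pytest

from acunet.errors import NumericalError, ParameterError, ValidationError
from acunet.ingest import PrescriptionRecord
from acunet.network import (build_network, cluster_networks,
                            eigenvector_centrality, filter_edges, top_edges)
from conftest import random_records


def rec(pid, case, points):
    return PrescriptionRecord(pid, case, frozenset(points))


def dense_centrality_oracle(net: nx.Graph, weighted=True) -> dict:
    """Max-normalised principal eigenvector via a full symmetric eigensolver,
    restricted to the largest connected component (ties: smallest min node)."""
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    component = sorted(comps[0])
    out = {node: 0.0 for node in net.nodes}
    if len(component) == 1:
        out[component[0]] = 1.0
        return out
    A = nx.to_numpy_array(net, nodelist=component,
                          weight="weight" if weighted else None)
    eigvals, eigvecs = np.linalg.eigh(A)
    v = eigvecs[:, -1]
    v = np.abs(v)  # Perron vector of a connected nonneg matrix is positive
    v = v / v.max()
    for node, value in zip(component, v):
        out[node] = float(value)
    return out


class TestBuildNetwork:
    def test_three_point_prescription_shares_weight(self):
        net = build_network([rec("D01", "case1", {"LI4", "LR3", "ST36"})])
        assert net.number_of_edges() == 3
        for _, _, d in net.edges(data=True):
            assert round(d["weight"], 2) == 0.33
            assert d["weight"] == pytest.approx(1 / 3)

    def test_repeated_pairs_accumulate(self):
        records = [rec("D01", "case1", {"LI4", "ST36"}),
                   rec("D02", "case1", {"LI4", "ST36"})]
        net = build_network(records)
        assert net["LI4"]["ST36"]["weight"] == pytest.approx(2.0)

    def test_singleton_record_contributes_node_only(self):
        net = build_network([rec("D01", "case1", {"ST36"})])
        assert set(net.nodes) == {"ST36"} and net.number_of_edges() == 0

    def test_weight_conservation(self, rng):
        records = random_records(rng, n_records=50)
        net = build_network(records)
        total = sum(d["weight"] for _, _, d in net.edges(data=True))
        contributing = sum(1 for r in records if len(r.acupoints) >= 2)
        assert total == pytest.approx(contributing, abs=1e-9)

    def test_order_independence(self, rng):
        records = random_records(rng, n_records=30)
        a = build_network(records)
        b = build_network(records[::-1])
        assert ({frozenset(e) for e in a.edges}
                == {frozenset(e) for e in b.edges})
        for u, v in a.edges:
            assert a[u][v]["weight"] == pytest.approx(b[u][v]["weight"])

    def test_empty_records_rejected(self):
        with pytest.raises(ParameterError):
            build_network([])


class TestFilterEdges:
    def test_strictly_greater_than_mean(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=1.0)
        net.add_edge("A", "C", weight=2.0)
        net.add_edge("B", "C", weight=3.0)
        kept = filter_edges(net)
        assert set(kept.edges) == {("B", "C")}
        assert "A" not in kept.nodes  # isolated after filtering

    def test_all_equal_weights_remove_everything(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=2.0)
        net.add_edge("B", "C", weight=2.0)
        assert filter_edges(net).number_of_edges() == 0

    def test_matches_independent_filter_pass(self, rng):
        import math

        for _ in range(20):
            records = random_records(rng, n_records=40)
            net = build_network(records)
            kept = filter_edges(net)
            weights = [d["weight"] for _, _, d in net.edges(data=True)]
            mean = math.fsum(weights) / len(weights)
            expected = {tuple(sorted((a, b)))
                        for a, b, d in net.edges(data=True)
                        if d["weight"] > mean}
            assert {tuple(sorted(e)) for e in kept.edges} == expected

    def test_edgeless_network_rejected(self):
        net = nx.Graph()
        net.add_node("A")
        with pytest.raises(ParameterError):
            filter_edges(net)


class TestEigenvectorCentrality:
    def test_symmetric_triangle_all_ones(self):
        net = build_network([rec("D01", "case1", {"LI4", "LR3", "ST36"})])
        cent = eigenvector_centrality(net)
        assert all(v == pytest.approx(1.0) for v in cent.values())

    def test_three_node_path(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=1.0)
        net.add_edge("B", "C", weight=1.0)
        cent = eigenvector_centrality(net)
        assert cent["B"] == pytest.approx(1.0)
        assert cent["A"] == pytest.approx(math.sqrt(0.5), abs=1e-6)
        assert cent["C"] == pytest.approx(math.sqrt(0.5), abs=1e-6)

    def test_matches_dense_eigensolver_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 13))
            p = 0.5
            net = nx.Graph()
            net.add_nodes_from(f"N{i:02d}" for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < p:
                        net.add_edge(f"N{i:02d}", f"N{j:02d}",
                                     weight=float(rng.uniform(0.1, 5.0)))
            if net.number_of_edges() == 0:
                continue
            cent = eigenvector_centrality(net)
            oracle = dense_centrality_oracle(net)
            for node in net.nodes:
                assert cent[node] == pytest.approx(oracle[node], abs=1e-6)

    def test_disconnected_graph_scores_largest_component(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=1.0)
        net.add_edge("B", "C", weight=1.0)
        net.add_edge("X", "Y", weight=9.0)
        cent = eigenvector_centrality(net)
        assert cent["B"] == pytest.approx(1.0)
        assert cent["X"] == 0.0 and cent["Y"] == 0.0

    def test_component_size_tie_goes_to_lexicographic_smallest(self):
        net = nx.Graph()
        net.add_edge("X", "Y", weight=9.0)
        net.add_edge("A", "B", weight=1.0)
        cent = eigenvector_centrality(net)
        assert cent["A"] == pytest.approx(1.0) and cent["X"] == 0.0

    def test_nonconvergence_raises_with_diagnostics(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=1.0)
        net.add_edge("B", "C", weight=2.0)
        with pytest.raises(NumericalError) as excinfo:
            eigenvector_centrality(net, tol=0.0, max_iter=5)
        assert excinfo.value.iterations == 5

    def test_empty_network_rejected(self):
        with pytest.raises(ParameterError):
            eigenvector_centrality(nx.Graph())


class TestTopEdges:
    def test_sorting_and_rounding(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=37.71)
        net.add_edge("A", "C", weight=26.49)
        net.add_edge("B", "C", weight=1.0)
        assert top_edges(net, 2) == [(("A", "B"), 37.7), (("A", "C"), 26.5)]

    def test_ties_break_lexicographically(self):
        net = nx.Graph()
        net.add_edge("B", "C", weight=2.0)
        net.add_edge("A", "D", weight=2.0)
        assert [pair for pair, _ in top_edges(net, 2)] == [("A", "D"), ("B", "C")]

    def test_matches_exhaustive_sort_oracle(self, rng):
        records = random_records(rng, n_records=60)
        net = build_network(records)
        result = top_edges(net, m=net.number_of_edges(), ndigits=None)
        oracle = sorted(
            ((tuple(sorted((a, b))), d["weight"])
             for a, b, d in net.edges(data=True)),
            key=lambda item: (-item[1], item[0]),
        )
        assert result == oracle


class TestClusterNetworks:
    def test_single_cluster_equals_global_pipeline(self, rng):
        records = random_records(rng, n_records=60, n_cases=3)
        assignment = {f"case{i}": "A" for i in range(1, 4)}
        per_cluster = cluster_networks(records, assignment)
        global_net = filter_edges(build_network(records))
        assert set(per_cluster) == {"A"}
        assert set(per_cluster["A"].edges) == set(global_net.edges)

    def test_disjoint_clusters_have_disjoint_nodes(self):
        records = [rec("D1", "case1", {"LI4", "LR3", "ST36"}),
                   rec("D2", "case1", {"LI4", "LR3"}),
                   rec("D1", "case2", {"BL23", "GV3", "GB30"}),
                   rec("D2", "case2", {"BL23", "GV3"})]
        nets = cluster_networks(records, {"case1": "A", "case2": "B"})
        assert set(nets["A"].nodes).isdisjoint(nets["B"].nodes)

    def test_unassigned_case_is_validation_error(self):
        records = [rec("D1", "case1", {"LI4", "LR3"})]
        with pytest.raises(ValidationError, match="case1"):
            cluster_networks(records, {})

    def test_centrality_annotated_per_cluster(self, rng):
        records = random_records(rng, n_records=80, n_cases=4)
        assignment = {"case1": "A", "case2": "A", "case3": "B", "case4": "B"}
        nets = cluster_networks(records, assignment)
        for net in nets.values():
            cent = nx.get_node_attributes(net, "centrality")
            assert cent and max(cent.values()) == pytest.approx(1.0)
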