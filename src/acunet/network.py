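"""Weighted acupoint co-occurrence networks and eigenvector centrality.

Each prescription (one practitioner, one case) carries total co-occurrence
weight 1, shared equally among the C(n, 2) unordered acupoint pairs it
contains (n = prescription size); an edge's weight in the network is the sum
of those shares over all prescriptions. A prescription of a single acupoint
contributes its node but no edge weight. Before the weight-sharing, the sum
of all edge weights therefore equals the number of contributing
prescriptions with n >= 2 — a conservation identity the tests rely on.

The final network keeps only edges strictly heavier than the mean edge
weight. Node importance is eigenvector centrality: the principal (Perron)
eigenvector of the weighted adjacency matrix of the largest connected
component, computed by power iteration from the uniform positive start
vector and rescaled so the most central node scores exactly 1.
"""

from __future__ import annotations

import math
from math import comb
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import NumericalError, ParameterError, ValidationError
from .ingest import PrescriptionRecord

__all__ = [
    "build_network",
    "filter_edges",
    "eigenvector_centrality",
    "cluster_networks",
    "top_edges",
]


def build_network(records: Iterable[PrescriptionRecord]) -> nx.Graph:
    """Accumulate the 1/C(n,2)-weighted co-occurrence graph over all records."""
    records = list(records)
    if not records:
        raise ParameterError("cannot build a network from zero records")
    G = nx.Graph()
    for rec in records:
        points = sorted(rec.acupoints)
        n = len(points)
        G.add_nodes_from(points)
        if n < 2:
            continue
        w = 1.0 / comb(n, 2)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = points[i], points[j]
                if G.has_edge(a, b):
                    G[a][b]["weight"] += w
                else:
                    G.add_edge(a, b, weight=w)
    return G


def filter_edges(net: nx.Graph) -> nx.Graph:
    """Keep edges strictly heavier than the mean edge weight.

    Nodes left without any incident edge are dropped. With all weights equal
    no edge survives (strict inequality), yielding an empty graph.
    """
    if net.number_of_edges() == 0:
        raise ParameterError("cannot filter an edgeless network")
    weights = [d["weight"] for _, _, d in net.edges(data=True)]
    mean = math.fsum(weights) / len(weights)
    out = nx.Graph()
    for a, b, d in net.edges(data=True):
        if d["weight"] > mean:
            out.add_edge(a, b, weight=d["weight"])
    return out


def _largest_component(net: nx.Graph) -> set:
    """Largest connected component; size ties broken by smallest min node."""
    comps = list(nx.connected_components(net))
    return min(comps, key=lambda c: (-len(c), min(c)))


def eigenvector_centrality(net: nx.Graph, tol: float = 1e-10,
                           max_iter: int = 10000,
                           weighted: bool = True) -> dict[str, float]:
    """Max-normalised eigenvector centrality by power iteration.

    Computed on the largest connected component of ``net`` (ties on size go
    to the component containing the lexicographically smallest node); nodes
    outside it score 0. Iteration starts from the uniform positive vector and
    stops when the L2 change between successive normalised iterates falls
    below ``tol``. The iteration matrix is A + cI with c the maximum weighted
    degree: the shift leaves every eigenvector unchanged but makes the Perron
    eigenvalue strictly dominant in magnitude, so convergence also holds on
    bipartite components (where the unshifted spectrum is symmetric and plain
    power iteration oscillates). The result is rescaled so its maximum is
    exactly 1.

    Raises
    ------
    ParameterError
        If the network has no nodes.
    NumericalError
        If convergence is not reached within ``max_iter`` iterations.
    """
    if net.number_of_nodes() == 0:
        raise ParameterError("cannot compute centrality of an empty network")
    component = sorted(_largest_component(net))
    centrality = {node: 0.0 for node in net.nodes}
    if len(component) == 1:
        centrality[component[0]] = 1.0
        return centrality
    A = nx.to_numpy_array(net, nodelist=component,
                          weight="weight" if weighted else None)
    shift = float(A.sum(axis=1).max())
    x = np.full(len(component), 1.0 / np.sqrt(len(component)))
    residual = np.inf
    for _ in range(max_iter):
        y = A @ x + shift * x
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - components here always have an edge
            raise NumericalError("power iteration hit the zero vector")
        y /= norm
        residual = float(np.linalg.norm(y - x))
        x = y
        if residual < tol:
            break
    else:
        raise NumericalError(
            "power iteration did not converge",
            iterations=max_iter, residual=residual,
        )
    x = x / x.max()
    for node, value in zip(component, x):
        centrality[node] = float(value)
    return centrality


def cluster_networks(records: Iterable[PrescriptionRecord],
                     assignment: Mapping[str, str],
                     tol: float = 1e-10,
                     max_iter: int = 10000) -> dict[str, nx.Graph]:
    """Independent filtered networks with centrality, one per case cluster.

    Records are partitioned by the cluster label of their case; the full
    build -> filter -> centrality pipeline runs separately on each partition.
    Centrality is stored as the ``centrality`` node attribute.

    Raises
    ------
    ValidationError
        If some record's case has no cluster label.
    """
    groups: dict[str, list[PrescriptionRecord]] = {}
    for rec in records:
        if rec.case_id not in assignment:
            raise ValidationError(f"case {rec.case_id!r} has no cluster label")
        groups.setdefault(assignment[rec.case_id], []).append(rec)
    out: dict[str, nx.Graph] = {}
    for label in sorted(groups):
        net = filter_edges(build_network(groups[label]))
        cent = eigenvector_centrality(net, tol=tol, max_iter=max_iter)
        nx.set_node_attributes(net, cent, "centrality")
        out[label] = net
    return out


def top_edges(net: nx.Graph, m: int = 30,
              ndigits: int | None = 1) -> list[tuple[tuple[str, str], float]]:
    """The m heaviest edges, ties broken by lexicographic node pair.

    Weights are rounded to ``ndigits`` decimals for reporting (pass ``None``
    for full precision); sorting uses full precision.
    """
    edges = []
    for a, b, d in net.edges(data=True):
        pair = tuple(sorted((a, b)))
        edges.append((pair, d["weight"]))
    edges.sort(key=lambda item: (-item[1], item[0]))
    return [
        (pair, round(w, ndigits) if ndigits is not None else w)
        for pair, w in edges[:m]
    ]
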