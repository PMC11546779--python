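"""Weighted undirected comorbidity co-occurrence networks.

Each patient's deduplicated ICD-10 code set is expanded into the complete
graph over those codes (every pair of co-recorded diagnoses gets a weight-1
edge); summing these per-patient edge lists over the cohort yields a network
whose edge weight counts the number of patients carrying both codes.  The
graph is undirected — discharge lists carry no causal direction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "ComorbidityNetwork",
    "clique_expand",
    "aggregate",
    "density",
    "degrees",
    "write_edge_csv",
    "read_edge_csv",
    "write_node_csv",
    "write_gexf",
]

Edge = tuple[str, str]


def _key(u: str, v: str) -> Edge:
    """Canonical unordered pair (lexicographically sorted)."""
    return (u, v) if u <= v else (v, u)


@dataclass
class ComorbidityNetwork:
    """Undirected weighted graph over ICD-10 codes.

    ``edges`` maps canonical unordered code pairs to positive integer
    weights (number of patients carrying both codes); isolated nodes are
    allowed, self-loops are not.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[Edge, int] = field(default_factory=dict)

    def add_edge(self, u: str, v: str, weight: int = 1) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        self.nodes.update((u, v))
        k = _key(u, v)
        self.edges[k] = self.edges.get(k, 0) + weight

    def weight(self, u: str, v: str) -> int:
        return self.edges.get(_key(u, v), 0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> int:
        return sum(self.edges.values())

    def neighbors(self, u: str) -> list[str]:
        return sorted(v if a == u else a for (a, v) in self.edges if u in (a, v))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), w in sorted(self.edges.items()):
            g.add_edge(u, v, weight=w)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComorbidityNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


def clique_expand(codes: Iterable[str]) -> list[tuple[str, str, int]]:
    """Expand one patient's code set into its complete weight-1 edge list.

    A set of k codes yields exactly k(k-1)/2 edges; singleton or empty sets
    yield none.  Orientation carries no meaning.
    """
    unique = sorted(set(codes))
    return [(u, v, 1) for u, v in combinations(unique, 2)]


def aggregate(patients: Iterable[Iterable[str]]) -> ComorbidityNetwork:
    """Sum per-patient clique expansions into the cohort network.

    weight(u, v) = number of patients whose code set contains both u and v.
    Every recorded code becomes a node, including codes from single-code
    records that contribute no edges.
    """
    net = ComorbidityNetwork()
    for codes in patients:
        unique = sorted(set(codes))
        net.nodes.update(unique)
        for u, v in combinations(unique, 2):
            k = (u, v)
            net.edges[k] = net.edges.get(k, 0) + 1
    return net


def density(n: ComorbidityNetwork) -> float:
    """Simple-graph density 2E / (N(N-1)); edge weights are ignored."""
    if n.n_nodes < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2 * n.n_edges / (n.n_nodes * (n.n_nodes - 1))


def degrees(n: ComorbidityNetwork) -> dict[str, tuple[int, int]]:
    """Per-node (degree, weighted degree); isolated nodes get (0, 0)."""
    out = {u: [0, 0] for u in n.nodes}
    for (u, v), w in n.edges.items():
        out[u][0] += 1
        out[u][1] += w
        out[v][0] += 1
        out[v][1] += w
    return {u: (d, wd) for u, (d, wd) in out.items()}


EDGE_HEADER = ["Source", "Target", "Weight"]


def write_edge_csv(n: ComorbidityNetwork, path, node_path=None) -> None:
    """Write the edge list as ``Source,Target,Weight`` (undirected semantics).

    Isolated nodes are not representable in an edge list, so when
    ``node_path`` is given a companion ``Id,Label`` node file preserving the
    full node set is written alongside.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EDGE_HEADER)
        for (u, v), weight in sorted(n.edges.items()):
            w.writerow([u, v, weight])
    if node_path is not None:
        write_node_csv(n, node_path)


def write_node_csv(n: ComorbidityNetwork, path,
                   attributes: Mapping[str, Mapping[str, object]] | None = None) -> None:
    """Write the node table ``Id,Label[,attribute columns...]``."""
    attributes = attributes or {}
    cols = sorted(attributes)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Id", "Label"] + cols)
        for u in sorted(n.nodes):
            w.writerow([u, u] + [attributes[c].get(u, "") for c in cols])


def read_edge_csv(path, node_path=None) -> ComorbidityNetwork:
    """Read a ``Source,Target,Weight`` edge file (plus optional node file).

    Malformed rows raise with their 1-based line number; duplicate pairs in
    either orientation and self-loops are rejected.
    """
    net = ComorbidityNetwork()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != EDGE_HEADER:
            raise ValueError(f"expected header {','.join(EDGE_HEADER)!r}, got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(row)}")
            u, v, raw_w = row[0].strip(), row[1].strip(), row[2].strip()
            if u == v:
                raise ValueError(f"line {lineno}: self-loop {u!r}")
            try:
                weight = int(raw_w)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad weight {raw_w!r}") from exc
            if weight < 1:
                raise ValueError(f"line {lineno}: weight must be >= 1")
            if _key(u, v) in net.edges:
                raise ValueError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
            net.add_edge(u, v, weight)
    if node_path is not None:
        with open(node_path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader, None)
            for row in reader:
                if row:
                    net.nodes.add(row[0].strip())
    return net


def write_gexf(n: ComorbidityNetwork, path,
               attributes: Mapping[str, Mapping[str, object]] | None = None,
               seed_graph: Optional[nx.Graph] = None) -> None:
    """Export the network as GEXF 1.2 with undirected edges and edge weights.

    ``attributes`` maps attribute name -> {node -> value} (e.g. community id,
    betweenness, render size); an attribute keyed on a node absent from the
    network is an error.
    """
    g = seed_graph if seed_graph is not None else n.to_networkx()
    if attributes:
        for name, mapping in attributes.items():
            unknown = set(mapping) - n.nodes
            if unknown:
                raise ValueError(
                    f"attribute {name!r} refers to unknown node(s) {sorted(unknown)}")
            nx.set_node_attributes(g, dict(mapping), name)
    nx.write_gexf(g, path, version="1.2draft")
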