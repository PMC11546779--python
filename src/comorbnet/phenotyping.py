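"""Community phenotyping of comorbidity networks.

Phenotype clusters are read off the network as modularity communities:
groups of diagnoses whose mutual co-occurrence (edge weight) is heavier than
expected from their overall connectivity.  Communities are found with a
seeded weighted Louvain procedure; bridging diagnoses are ranked by
betweenness centrality; cluster composition is summarised as a node/edge
count table with an inter-cluster connection matrix; and the render
attributes used for network figures (log-scaled node sizes, linearly scaled
edge widths) are computed from those metrics.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network import ComorbidityNetwork, _key

__all__ = [
    "CommunityPartition",
    "ClusterSummary",
    "RenderAttributes",
    "louvain",
    "modularity",
    "betweenness",
    "cluster_summary",
    "render_attributes",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CommunityPartition:
    """node -> community id (0-based, contiguous), with the run's settings."""

    assignment: dict[str, int]
    resolution: float
    seed: int
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self, community: int) -> list[str]:
        return sorted(u for u, c in self.assignment.items() if c == community)


@dataclass(frozen=True)
class ClusterSummary:
    """Per-community node/edge counts with the inter-community edge matrix.

    ``order`` lists community ids by descending node count (ties: lower id
    first), the layout used for reporting; ``inter_matrix`` counts distinct
    edges (weights ignored) with one endpoint in each community of the pair.
    """

    order: tuple[int, ...]
    node_count: dict[int, int]
    intra_edges: dict[int, int]
    node_share_pct: dict[int, float]
    inter_matrix: dict[tuple[int, int], int]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {
            "No.": list(range(1, len(self.order) + 1)),
            "Cluster": list(self.order),
            "Nodes": [self.node_count[c] for c in self.order],
            "Edges": [self.intra_edges[c] for c in self.order],
            "Share %": [self.node_share_pct[c] for c in self.order],
        }
        for other in self.order:
            cols[f"To {other}"] = [
                0 if c == other else self.inter_matrix.get(tuple(sorted((c, other))), 0)
                for c in self.order
            ]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class RenderAttributes:
    node_size: dict[str, float]  # in [1, 100], log-scaled betweenness
    edge_width: dict[tuple[str, str], float]  # in [0.1, 1], linear in weight
    node_color: dict[str, int]  # community id


# ---------------------------------------------------------------------------
# Louvain


class _Level:
    """One Louvain level: weighted adjacency with self-loops from aggregation."""

    def __init__(self, adj: dict[int, dict[int, float]], loops: dict[int, float]):
        self.adj = adj
        self.loops = loops
        # degree counts each incident edge weight once, self-loops twice
        self.degree = {
            u: sum(nbrs.values()) + 2 * loops.get(u, 0.0) for u, nbrs in adj.items()
        }
        self.W = sum(self.degree.values())  # = 2m

    def quality(self, comm: dict[int, int], gamma: float) -> float:
        if self.W == 0:
            return 0.0
        inner: dict[int, float] = {}
        tot: dict[int, float] = {}
        for u, nbrs in self.adj.items():
            cu = comm[u]
            tot[cu] = tot.get(cu, 0.0) + self.degree[u]
            inner[cu] = inner.get(cu, 0.0) + 2 * self.loops.get(u, 0.0)
            for v, w in nbrs.items():
                if comm[v] == cu:
                    inner[cu] = inner.get(cu, 0.0) + w  # each edge seen twice
        return sum(
            inner.get(c, 0.0) / self.W - gamma * (tc / self.W) ** 2
            for c, tc in tot.items()
        )


def _local_move(level: _Level, gamma: float, rng: np.random.Generator
                ) -> dict[int, int]:
    """Greedy node moves until no single move improves modularity."""
    nodes = sorted(level.adj)
    comm = {u: u for u in nodes}
    tot = {u: level.degree[u] for u in nodes}
    if level.W == 0:
        return comm
    order = list(nodes)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            k_u = level.degree[u]
            # weight from u to each neighbouring community
            links: dict[int, float] = {}
            for v, w in level.adj[u].items():
                links[comm[v]] = links.get(comm[v], 0.0) + w
            tot[cu] -= k_u
            own_gain = links.get(cu, 0.0) - gamma * tot[cu] * k_u / level.W
            best_c, best_gain = cu, own_gain
            # ascending community order + strict improvement = lowest-id
            # tie-break among equally good targets; zero-gain ties stay put
            for c in sorted(links):
                if c == cu:
                    continue
                gain = links[c] - gamma * tot[c] * k_u / level.W
                if gain > best_gain + _EPS:
                    best_c, best_gain = c, gain
            tot[best_c] += k_u
            if best_c != cu:
                comm[u] = best_c
                improved = True
    return comm


def _aggregate_level(level: _Level, comm: dict[int, int]
                     ) -> tuple[_Level, dict[int, int]]:
    """Collapse communities into super-nodes; returns (new level, relabel map)."""
    labels = sorted(set(comm.values()))
    relabel = {c: i for i, c in enumerate(labels)}
    adj: dict[int, dict[int, float]] = {relabel[c]: {} for c in labels}
    loops: dict[int, float] = {}
    for u in level.adj:
        cu = relabel[comm[u]]
        loops[cu] = loops.get(cu, 0.0) + level.loops.get(u, 0.0)
        for v, w in level.adj[u].items():
            cv = relabel[comm[v]]
            if cu == cv:
                if u < v:
                    loops[cu] = loops.get(cu, 0.0) + w
            else:
                adj[cu][cv] = adj[cu].get(cv, 0.0) + w
    return _Level(adj, loops), relabel


def louvain(n: ComorbidityNetwork, resolution: float = 1.0,
            seed: int = 0) -> CommunityPartition:
    """Two-phase greedy modularity maximisation on edge weights.

    Local-move phase: nodes are visited in a seeded random order and moved to
    the neighbouring community with the largest positive modularity gain
    (ties broken towards the lowest community id); when no move helps, the
    communities are collapsed into super-nodes and the process repeats.  The
    result is deterministic given (network, resolution, seed), and its
    modularity is never below that of the all-singletons partition.
    """
    if n.n_nodes == 0:
        raise ValueError("louvain requires at least one node")
    names = sorted(n.nodes)
    index = {u: i for i, u in enumerate(names)}
    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(names))}
    for (u, v), w in n.edges.items():
        adj[index[u]][index[v]] = float(w)
        adj[index[v]][index[u]] = float(w)
    level = _Level(adj, {})
    rng = np.random.default_rng(seed)

    membership = {i: i for i in range(len(names))}  # original node -> community
    prev_q = level.quality({i: i for i in level.adj}, resolution)
    while True:
        comm = _local_move(level, resolution, rng)
        q = level.quality(comm, resolution)
        assert q >= prev_q - _EPS, "modularity decreased across a Louvain pass"
        if q <= prev_q + _EPS and len(set(comm.values())) == len(level.adj):
            break
        level, relabel = _aggregate_level(level, comm)
        membership = {u: relabel[comm[c]] for u, c in membership.items()}
        prev_q = q
        if len(level.adj) == 1:
            break

    # contiguous 0-based ids, numbered by first appearance in node-name order
    seen: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, u in enumerate(names):
        c = membership[i]
        if c not in seen:
            seen[c] = len(seen)
        assignment[u] = seen[c]
    final_q = modularity(n, assignment, resolution)
    return CommunityPartition(assignment=assignment, resolution=resolution,
                              seed=seed, modularity=final_q)


def modularity(n: ComorbidityNetwork, partition: Mapping[str, int],
               resolution: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity Q = sum_c [w_in/W - g (w_tot/W)^2].

    W is twice the total edge weight, w_in twice the intra-community weight
    and w_tot the summed weighted degree of the community; ``resolution`` is
    the scale parameter g.
    """
    missing = n.nodes - set(partition)
    if missing:
        raise ValueError(f"partition missing node(s): {sorted(missing)[:5]}")
    W = 2.0 * n.total_weight()
    if W == 0:
        return 0.0
    w_in: dict[int, float] = {}
    w_tot: dict[int, float] = {}
    for (u, v), w in n.edges.items():
        cu, cv = partition[u], partition[v]
        w_tot[cu] = w_tot.get(cu, 0.0) + w
        w_tot[cv] = w_tot.get(cv, 0.0) + w
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + 2.0 * w
    return sum(
        w_in.get(c, 0.0) / W - resolution * (t / W) ** 2
        for c, t in w_tot.items()
    )


# ---------------------------------------------------------------------------
# Betweenness (Brandes)


def betweenness(n: ComorbidityNetwork, use_weights: bool = False
                ) -> dict[str, float]:
    """Unnormalised betweenness centrality via Brandes' accumulation.

    Each unordered node pair is counted once.  By default shortest paths are
    hop counts; with ``use_weights`` the edge distance is 1/weight, so
    heavier co-occurrence means closer.
    """
    nodes = sorted(n.nodes)
    adj: dict[str, list[tuple[str, float]]] = {u: [] for u in nodes}
    for (u, v), w in n.edges.items():
        d = 1.0 / w if use_weights else 1.0
        adj[u].append((v, d))
        adj[v].append((u, d))
    bc = {u: 0.0 for u in nodes}
    for s in nodes:
        sigma = {u: 0.0 for u in nodes}
        sigma[s] = 1.0
        dist: dict[str, float] = {}
        pred: dict[str, list[str]] = {u: [] for u in nodes}
        stack: list[str] = []
        if not use_weights:
            dist[s] = 0.0
            queue = deque([s])
            while queue:
                v = queue.popleft()
                stack.append(v)
                for w_node, _ in adj[v]:
                    if w_node not in dist:
                        dist[w_node] = dist[v] + 1
                        queue.append(w_node)
                    if dist[w_node] == dist[v] + 1:
                        sigma[w_node] += sigma[v]
                        pred[w_node].append(v)
        else:
            seen: dict[str, float] = {s: 0.0}
            heap: list[tuple[float, int, str, str | None]] = [(0.0, 0, s, None)]
            counter = 1
            while heap:
                d, _, v, p = heapq.heappop(heap)
                if v in dist:
                    continue
                dist[v] = d
                stack.append(v)
                for w_node, cost in adj[v]:
                    nd = d + cost
                    if w_node not in dist and (w_node not in seen or nd < seen[w_node]):
                        seen[w_node] = nd
                        heapq.heappush(heap, (nd, counter, w_node, v))
                        counter += 1
                        sigma[w_node] = sigma[v]
                        pred[w_node] = [v]
                    elif w_node not in dist and nd == seen.get(w_node):
                        sigma[w_node] += sigma[v]
                        pred[w_node].append(v)
        delta = {u: 0.0 for u in stack}
        while stack:
            w_node = stack.pop()
            for v in pred[w_node]:
                delta[v] += sigma[v] / sigma[w_node] * (1.0 + delta[w_node])
            if w_node != s:
                bc[w_node] += delta[w_node]
    return {u: b / 2.0 for u, b in bc.items()}  # each unordered pair once


# ---------------------------------------------------------------------------
# Reporting


def _round_half_away(x: float, digits: int) -> float:
    scale = 10 ** digits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def cluster_summary(n: ComorbidityNetwork,
                    partition: CommunityPartition | Mapping[str, int]
                    ) -> ClusterSummary:
    """Per-community node/edge counts and the inter-community edge matrix.

    Communities are reported by descending node count (ties: lower id
    first); node shares are percentages of the network's nodes rounded to
    2 decimals; edge counts ignore weights.  Intra plus inter counts always
    conserve the network's total edge count.
    """
    assignment = (partition.assignment
                  if isinstance(partition, CommunityPartition) else dict(partition))
    missing = n.nodes - set(assignment)
    if missing:
        raise ValueError(f"partition missing node(s): {sorted(missing)[:5]}")
    node_count: dict[int, int] = {}
    for u in n.nodes:
        node_count[assignment[u]] = node_count.get(assignment[u], 0) + 1
    intra = {c: 0 for c in node_count}
    inter: dict[tuple[int, int], int] = {}
    for (u, v) in n.edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] += 1
        else:
            k = tuple(sorted((cu, cv)))
            inter[k] = inter.get(k, 0) + 1
    order = tuple(sorted(node_count, key=lambda c: (-node_count[c], c)))
    total = n.n_nodes
    share = {c: _round_half_away(100.0 * k / total, 2) for c, k in node_count.items()}
    return ClusterSummary(order=order, node_count=node_count, intra_edges=intra,
                          node_share_pct=share, inter_matrix=inter)


def render_attributes(n: ComorbidityNetwork,
                      bc: Mapping[str, float],
                      partition: CommunityPartition | Mapping[str, int]
                      ) -> RenderAttributes:
    """Visual attribute scaling for network figures.

    Node size maps betweenness through ln(1+b) min-max onto [1, 100]; edge
    width maps weight linearly onto [0.1, 1].  A degenerate span (all values
    equal) maps everything to the lower bound.  Node colour is the community
    id.
    """
    assignment = (partition.assignment
                  if isinstance(partition, CommunityPartition) else dict(partition))
    missing = n.nodes - set(bc)
    if missing:
        raise ValueError(f"betweenness missing node(s): {sorted(missing)[:5]}")
    missing = n.nodes - set(assignment)
    if missing:
        raise ValueError(f"partition missing node(s): {sorted(missing)[:5]}")

    sizes: dict[str, float] = {}
    if n.nodes:
        logs = {u: math.log1p(bc[u]) for u in n.nodes}
        lo, hi = min(logs.values()), max(logs.values())
        span = hi - lo
        for u, lb in logs.items():
            sizes[u] = 1.0 if span == 0 else 1.0 + 99.0 * (lb - lo) / span

    widths: dict[tuple[str, str], float] = {}
    if n.edges:
        weights = n.edges
        w_lo, w_hi = min(weights.values()), max(weights.values())
        span = w_hi - w_lo
        for e, w in weights.items():
            widths[e] = 0.1 if span == 0 else 0.1 + 0.9 * (w - w_lo) / span

    colors = {u: assignment[u] for u in n.nodes}
    return RenderAttributes(node_size=sizes, edge_width=widths, node_color=colors)
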