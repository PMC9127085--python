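"""Labeled alternative-route generation.

The choice-set generation follows the labeling approach: instead of
enumerating many candidate paths, exactly one route is produced per
criterion label —

* ``shortest``: the minimum-distance route (length as impedance);
* ``least_angular``: the route minimising cumulative angular turn cost,
  the space-syntax "least directional change" route.

Both are computed by a Dijkstra search on (node, incoming-edge) states so
that turn costs, which depend on consecutive edge pairs, are additive along
transitions.  Ties are broken deterministically: first by the secondary
cost (turn cost for the distance route, length for the angular route), then
by the lexicographically smallest edge-id sequence.  With strictly positive
edge lengths and turn costs obeying the triangle inequality at every
intersection, the canonical optimum never repeats an edge, so returned
routes are edge-simple.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .network import NoPathError, RoadNetwork, Route, to_segment_graph


def _optimal_route(net: RoadNetwork, origin: str, dest: str, primary: str) -> Route:
    """Best route under a lexicographic (primary, secondary, edge-seq) key.

    ``primary`` is ``"length"`` or ``"angular"``; the other cost serves as
    the secondary tie-break.
    """
    origin, dest = str(origin), str(dest)
    for node in (origin, dest):
        if node not in net.nodes:
            raise NoPathError(f"unknown node {node!r}")
    if origin == dest:
        raise NoPathError("origin and destination coincide")

    # heap entries: (primary, secondary, edge-seq, node, incoming edge)
    heap: list[tuple[float, float, tuple[str, ...], str, str | None]] = []
    for eid in net.incident_edges(origin):
        edge = net.edges[eid]
        length = edge.length
        p, s = (length, 0.0) if primary == "length" else (0.0, length)
        heapq.heappush(heap, (p, s, (eid,), edge.other_end(origin), eid))

    settled: set[tuple[str, str | None]] = set()
    while heap:
        p, s, seq, node, in_edge = heapq.heappop(heap)
        if (node, in_edge) in settled:
            continue
        settled.add((node, in_edge))
        if node == dest:
            if len(set(seq)) != len(seq):  # pragma: no cover - defensive
                raise RuntimeError("optimal route repeated an edge")
            return Route.from_edges(net, origin, seq)
        for out_eid in net.incident_edges(node):
            if out_eid == in_edge:
                continue
            edge = net.edges[out_eid]
            nxt = edge.other_end(node)
            if (nxt, out_eid) in settled:
                continue
            turn = net.angular_cost(in_edge, node, out_eid)
            if primary == "length":
                np_, ns = p + edge.length, s + turn
            else:
                np_, ns = p + turn, s + edge.length
            heapq.heappush(heap, (np_, ns, seq + (out_eid,), nxt, out_eid))
    raise NoPathError(f"no route from {origin!r} to {dest!r}")


def shortest_distance_route(net: RoadNetwork, origin: str, dest: str) -> Route:
    """Minimum-length route between two intersections.

    Among equal-length routes, the one with lower total turn cost is
    preferred, then the lexicographically smallest edge-id sequence, so the
    result is deterministic.
    """
    return _optimal_route(net, origin, dest, primary="length")


def least_angular_route(net: RoadNetwork, origin: str, dest: str) -> Route:
    """Route with the least directional change between two intersections.

    Minimises the summed angular cost over consecutive edge pairs; equal
    turn-cost routes are broken by total length, then lexicographic edge
    order.
    """
    return _optimal_route(net, origin, dest, primary="angular")


@dataclass(frozen=True)
class AngularDepthMap:
    """Angular step depth of every street segment from one origin.

    Depth of a segment is the cheapest cumulative angular cost of reaching
    it on the segment graph from any segment incident to the origin
    (origin-incident segments have depth 0).  Unreachable segments are
    absent from ``depths``.
    """

    origin: str
    depths: Mapping[str, float]

    def __getitem__(self, edge_id: str) -> float:
        return self.depths[edge_id]


def angular_step_depth(net: RoadNetwork, origin: str) -> AngularDepthMap:
    """Single-origin angular step-depth map on the segment graph."""
    origin = str(origin)
    if origin not in net.nodes:
        raise NoPathError(f"unknown node {origin!r}")
    seg = to_segment_graph(net)
    sources = list(net.incident_edges(origin))
    if not sources:
        return AngularDepthMap(origin, {})
    depths = nx.multi_source_dijkstra_path_length(
        seg.graph, sources, weight="angular_cost"
    )
    return AngularDepthMap(origin, dict(depths))
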