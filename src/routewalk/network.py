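"""Planar street-network data model, validation, I/O and the segment graph.

A :class:`RoadNetwork` is an undirected planar graph in projected metric
coordinates.  Edges carry polyline geometry and, optionally, the street
audit attribute record used by the choice models.  The angular
:class:`SegmentGraph` is the dual construction from space syntax: every
street edge becomes a segment node, and two segments sharing an intersection
are linked with a turn cost proportional to the angular deviation from
straight-ahead continuation (theta/90, so straight = 0, right angle = 1,
U-turn = 2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .environment import ATTRIBUTE_FIELDS, validate_attributes

#: Snapping tolerance (metres) when deriving nodes from LineString endpoints.
SNAP_TOLERANCE = 1e-6

#: Relative tolerance between a declared edge length and its polyline arc length.
LENGTH_RTOL = 1e-6


class NetworkValidationError(ValueError):
    """The network violates a structural invariant (named ids in message)."""


class NoPathError(ValueError):
    """No route exists between the requested origin and destination."""


def _arc_length(coords: Sequence[tuple[float, float]]) -> float:
    return sum(
        math.dist(coords[i], coords[i + 1]) for i in range(len(coords) - 1)
    )


@dataclass(frozen=True)
class Edge:
    """One undirected street segment with geometry from ``u`` to ``v``."""

    edge_id: str
    u: str
    v: str
    geometry: tuple[tuple[float, float], ...]
    length: float
    attributes: Mapping[str, float] = field(default_factory=dict)

    def other_end(self, node: str) -> str:
        if node == self.u:
            return self.v
        if node == self.v:
            return self.u
        raise KeyError(f"node {node!r} is not an endpoint of edge {self.edge_id!r}")


class RoadNetwork:
    """Validated undirected street network.

    Parameters
    ----------
    nodes:
        Mapping node-id -> (x, y) planar coordinates in metres.
    edges:
        Iterable of :class:`Edge`.  Every edge must reference existing,
        distinct nodes; at most one edge may join an unordered node pair;
        declared lengths must match polyline arc length to ``LENGTH_RTOL``.
        Attribute records, when present, must satisfy the audit schema.
    """

    def __init__(self, nodes: Mapping[str, tuple[float, float]], edges: Iterable[Edge]):
        self.nodes: dict[str, tuple[float, float]] = {
            str(k): (float(x), float(y)) for k, (x, y) in nodes.items()
        }
        self.edges: dict[str, Edge] = {}
        self._g = nx.Graph()
        self._g.add_nodes_from(self.nodes)
        for edge in edges:
            self._validate_edge(edge)
            self.edges[edge.edge_id] = edge
            self._g.add_edge(edge.u, edge.v, edge_id=edge.edge_id, length=edge.length)

    def _validate_edge(self, edge: Edge) -> None:
        eid = edge.edge_id
        if eid in self.edges:
            raise NetworkValidationError(f"duplicate edge id {eid!r}")
        for end in (edge.u, edge.v):
            if end not in self.nodes:
                raise NetworkValidationError(
                    f"edge {eid!r} references unknown node {end!r}"
                )
        if edge.u == edge.v:
            raise NetworkValidationError(f"edge {eid!r} is a self-loop at {edge.u!r}")
        if self._g.has_edge(edge.u, edge.v):
            other = self._g.edges[edge.u, edge.v]["edge_id"]
            raise NetworkValidationError(
                f"parallel edge {eid!r} duplicates {other!r} between "
                f"{edge.u!r} and {edge.v!r}"
            )
        if len(edge.geometry) < 2:
            raise NetworkValidationError(f"edge {eid!r} geometry has < 2 vertices")
        if edge.length <= 0:
            raise NetworkValidationError(f"edge {eid!r} has non-positive length")
        arc = _arc_length(edge.geometry)
        if arc <= 0 or abs(edge.length - arc) > LENGTH_RTOL * max(arc, 1.0):
            raise NetworkValidationError(
                f"edge {eid!r} length {edge.length} does not match polyline "
                f"arc length {arc}"
            )
        if math.dist(edge.geometry[0], self.nodes[edge.u]) > SNAP_TOLERANCE:
            raise NetworkValidationError(
                f"edge {eid!r} geometry does not start at node {edge.u!r}"
            )
        if math.dist(edge.geometry[-1], self.nodes[edge.v]) > SNAP_TOLERANCE:
            raise NetworkValidationError(
                f"edge {eid!r} geometry does not end at node {edge.v!r}"
            )
        if edge.attributes:
            validate_attributes(edge.attributes, edge_id=eid)

    # -- queries -----------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """Underlying networkx view (edge attrs: ``edge_id``, ``length``)."""
        return self._g

    def incident_edges(self, node: str) -> tuple[str, ...]:
        """Edge ids incident to ``node``, in sorted (deterministic) order."""
        return tuple(
            sorted(self._g.edges[node, nbr]["edge_id"] for nbr in self._g[node])
        )

    def edge_between(self, u: str, v: str) -> str:
        return self._g.edges[u, v]["edge_id"]

    def has_attributes(self) -> bool:
        return all(e.attributes for e in self.edges.values())

    def travel_heading(self, edge_id: str, at_node: str, arriving: bool) -> tuple[float, float]:
        """Unit heading of travel at ``at_node`` along ``edge_id``.

        ``arriving=True`` gives the direction of motion when reaching the
        node; ``arriving=False`` the direction when leaving it.  Curved
        polylines use the chord incident to the node, so the turn angle
        reflects the street's local bearing at the intersection.
        """
        edge = self.edges[edge_id]
        coords = edge.geometry
        if at_node == edge.u:
            a, b = coords[0], coords[1]
            vec = (b[0] - a[0], b[1] - a[1])  # heading away from u
            if arriving:
                vec = (-vec[0], -vec[1])
        elif at_node == edge.v:
            a, b = coords[-1], coords[-2]
            vec = (b[0] - a[0], b[1] - a[1])  # heading away from v
            if arriving:
                vec = (-vec[0], -vec[1])
        else:
            raise KeyError(f"node {at_node!r} not an endpoint of edge {edge_id!r}")
        norm = math.hypot(*vec)
        if norm == 0:
            raise NetworkValidationError(
                f"degenerate zero-length chord on edge {edge_id!r} at {at_node!r}"
            )
        return (vec[0] / norm, vec[1] / norm)

    def angular_cost(self, edge_in: str, node: str, edge_out: str) -> float:
        """Turn cost theta/90 for travelling through ``node``.

        ``theta`` is the deviation (degrees, in [0, 180]) between the arrival
        heading along ``edge_in`` and the departure heading along
        ``edge_out``; collinear continuation costs 0, a right angle 1 and a
        full reversal 2.  Symmetric in its two edges.
        """
        hin = self.travel_heading(edge_in, node, arriving=True)
        hout = self.travel_heading(edge_out, node, arriving=False)
        dot = max(-1.0, min(1.0, hin[0] * hout[0] + hin[1] * hout[1]))
        theta = math.degrees(math.acos(dot))
        return theta / 90.0


@dataclass(frozen=True)
class Route:
    """Ordered, edge-simple path between an origin and a destination."""

    origin: str
    destination: str
    edge_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    total_length: float

    @classmethod
    def from_edges(cls, net: RoadNetwork, origin: str, edge_ids: Sequence[str]) -> "Route":
        """Build and validate a route from an ordered edge-id sequence."""
        origin = str(origin)
        if origin not in net.nodes:
            raise NetworkValidationError(f"unknown origin node {origin!r}")
        nodes = [origin]
        total = 0.0
        seen: set[str] = set()
        for eid in edge_ids:
            eid = str(eid)
            if eid in seen:
                raise NetworkValidationError(f"route repeats edge {eid!r}")
            seen.add(eid)
            edge = net.edges.get(eid)
            if edge is None:
                raise NetworkValidationError(f"route uses unknown edge {eid!r}")
            nodes.append(edge.other_end(nodes[-1]))
            total += edge.length
        return cls(
            origin=origin,
            destination=nodes[-1],
            edge_ids=tuple(str(e) for e in edge_ids),
            node_ids=tuple(nodes),
            total_length=total,
        )

    def turn_cost(self, net: RoadNetwork) -> float:
        """Summed angular cost over consecutive edge pairs."""
        return sum(
            net.angular_cost(self.edge_ids[i], self.node_ids[i + 1], self.edge_ids[i + 1])
            for i in range(len(self.edge_ids) - 1)
        )


@dataclass(frozen=True)
class SegmentLink:
    """Angular link between two street segments sharing an intersection."""

    seg_a: str
    seg_b: str
    node: str
    angular_cost: float


class SegmentGraph:
    """Dual (segment-map) graph: street edges as nodes, turns as links."""

    def __init__(self, links: Iterable[SegmentLink], segments: Iterable[str]):
        self._g = nx.Graph()
        self._g.add_nodes_from(segments)
        self.links: list[SegmentLink] = []
        for link in links:
            self._g.add_edge(
                link.seg_a, link.seg_b, angular_cost=link.angular_cost, node=link.node
            )
            self.links.append(link)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()


def to_segment_graph(net: RoadNetwork) -> SegmentGraph:
    """Convert a road network to its angular segment graph.

    One segment node per street edge; one link for every unordered pair of
    edges sharing an intersection, weighted by the angular turn cost at that
    intersection.
    """
    links: list[SegmentLink] = []
    for node in sorted(net.nodes):
        incident = net.incident_edges(node)
        for i in range(len(incident)):
            for j in range(i + 1, len(incident)):
                a, b = incident[i], incident[j]
                links.append(
                    SegmentLink(a, b, node, net.angular_cost(a, node, b))
                )
    return SegmentGraph(links, sorted(net.edges))


# -- I/O -------------------------------------------------------------------


def _snap_key(x: float, y: float) -> tuple[int, int]:
    return (round(x / SNAP_TOLERANCE), round(y / SNAP_TOLERANCE))


def load_network(network_file: str, attributes_file: str | None = None) -> RoadNetwork:
    """Load a road network from GeoJSON (+ optional attribute CSV).

    The GeoJSON must be a FeatureCollection of LineStrings, each with an
    ``edge_id`` property; nodes are derived from endpoints snapped at
    ``SNAP_TOLERANCE``.  The CSV must have one row per edge id with every
    audit attribute column.  Validation errors name the offending ids.
    """
    with open(network_file) as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise NetworkValidationError(f"{network_file}: not a GeoJSON FeatureCollection")

    attr_by_edge: dict[str, dict[str, float]] = {}
    if attributes_file is not None:
        table = pd.read_csv(attributes_file, dtype={"edge_id": str})
        if "edge_id" not in table.columns:
            raise NetworkValidationError(f"{attributes_file}: missing edge_id column")
        missing_cols = [c for c in ATTRIBUTE_FIELDS if c not in table.columns]
        if missing_cols:
            raise NetworkValidationError(
                f"{attributes_file}: missing attribute columns {missing_cols}"
            )
        dup = table["edge_id"][table["edge_id"].duplicated()].tolist()
        if dup:
            raise NetworkValidationError(f"duplicate attribute rows for edges {dup}")
        for _, row in table.iterrows():
            attr_by_edge[str(row["edge_id"])] = {
                c: float(row[c]) for c in ATTRIBUTE_FIELDS
            }

    nodes: dict[str, tuple[float, float]] = {}
    key_to_node: dict[tuple[int, int], str] = {}

    def node_for(x: float, y: float, preferred: str | None = None) -> str:
        key = _snap_key(x, y)
        if key not in key_to_node:
            nid = str(preferred) if preferred is not None else f"n{len(key_to_node)}"
            key_to_node[key] = nid
            nodes[nid] = (x, y)
        return key_to_node[key]

    edges: list[Edge] = []
    seen_ids: set[str] = set()
    for feat in collection.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise NetworkValidationError(
                f"feature geometry {geom.geom_type} is not a LineString"
            )
        props = feat.get("properties") or {}
        if "edge_id" not in props:
            raise NetworkValidationError("LineString feature without edge_id property")
        eid = str(props["edge_id"])
        coords = tuple((float(x), float(y)) for x, y in geom.coords)
        # optional stable endpoint ids (written by write_network)
        u = node_for(*coords[0], preferred=props.get("u"))
        v = node_for(*coords[-1], preferred=props.get("v"))
        length = float(props.get("length", _arc_length(coords)))
        attrs = attr_by_edge.get(eid, {})
        if attributes_file is not None and not attrs:
            raise NetworkValidationError(
                f"attribute table has no row for edge {eid!r}"
            )
        edges.append(Edge(eid, u, v, coords, length, attrs))
        seen_ids.add(eid)

    if attributes_file is not None:
        orphans = sorted(set(attr_by_edge) - seen_ids)
        if orphans:
            raise NetworkValidationError(
                f"attribute rows for unknown edges {orphans}"
            )
    return RoadNetwork(nodes, edges)


def write_network(net: RoadNetwork, network_file: str, attributes_file: str | None = None) -> None:
    """Write a network back to GeoJSON (+ attribute CSV), inverse of load."""
    features = []
    for eid in sorted(net.edges):
        edge = net.edges[eid]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(LineString(edge.geometry)),
                "properties": {"edge_id": eid, "length": edge.length,
                               "u": edge.u, "v": edge.v},
            }
        )
    with open(network_file, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")
    if attributes_file is not None:
        rows = []
        for eid in sorted(net.edges):
            attrs = net.edges[eid].attributes
            rows.append({"edge_id": eid, **{c: attrs[c] for c in ATTRIBUTE_FIELDS}})
        pd.DataFrame(rows, columns=["edge_id", *ATTRIBUTE_FIELDS]).to_csv(
            attributes_file, index=False
        )


def load_routes(routes_file: str, net: RoadNetwork) -> dict[str, Route]:
    """Load routes from GeoJSON features carrying ``od_id``/``origin``/``edges``.

    Each feature's ``edges`` property is the ordered edge-id list; the
    geometry is informational.  Returns a mapping od_id -> Route.
    """
    with open(routes_file) as fh:
        collection = json.load(fh)
    routes: dict[str, Route] = {}
    for feat in collection.get("features", []):
        props = feat.get("properties") or {}
        od_id = str(props["od_id"])
        edge_ids = props["edges"]
        if isinstance(edge_ids, str):
            edge_ids = [e for e in edge_ids.split(",") if e]
        try:
            routes[od_id] = Route.from_edges(net, str(props["origin"]), edge_ids)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"route {od_id!r}: {exc}") from exc
    return routes


def write_routes(
    routes: Mapping[str, Route], net: RoadNetwork, routes_file: str,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Write routes as GeoJSON LineStrings with od_id/origin/edges properties."""
    features = []
    for od_id in routes:
        route = routes[od_id]
        coords: list[tuple[float, float]] = []
        for i, eid in enumerate(route.edge_ids):
            edge = net.edges[eid]
            geom = list(edge.geometry)
            if route.node_ids[i] == edge.v:
                geom = geom[::-1]
            coords.extend(geom if not coords else geom[1:])
        if not coords:
            coords = [net.nodes[route.origin]]
        props = {
            "od_id": od_id,
            "origin": route.origin,
            "destination": route.destination,
            "edges": list(route.edge_ids),
            "length": route.total_length,
        }
        if labels is not None:
            props["label"] = labels[od_id]
        geometry = (
            mapping(LineString(coords))
            if len(coords) >= 2
            else {"type": "Point", "coordinates": list(coords[0])}
        )
        features.append({"type": "Feature", "geometry": geometry, "properties": props})
    with open(routes_file, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")
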