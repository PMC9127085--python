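"""Shared builders and fixtures for the test suite."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pytest

from routewalk.environment import ATTRIBUTE_FIELDS
from routewalk.network import Edge, RoadNetwork

DATA_DIR = Path(__file__).parent / "data"

#: A valid, constant audit record used wherever attribute values are not
#: the point of the test.
BASE_ATTRS = {
    "sidewalk_width": 2.0,
    "on_street_parking": 2,
    "sidewalk_walkability": 2,
    "traffic_signals": 1,
    "driveway_width": 6.0,
    "dh_ratio": 1.2,
    "green_spaces": 2,
    "street_walls": 1,
    "garbage_bins": 2,
    "streetlights": 3,
    "benches": 1,
    "shops": 0.2,
    "life_facilities": 0.1,
    "bus_stops": 0.05,
    "leisure_facilities": 0.1,
}
assert set(BASE_ATTRS) == set(ATTRIBUTE_FIELDS)


def const_attrs(**overrides) -> dict[str, float]:
    attrs = dict(BASE_ATTRS)
    attrs.update(overrides)
    return attrs


def build_network(
    coords: dict[str, tuple[float, float]],
    edge_pairs: list[tuple[str, str, str]],
    attrs: dict[str, dict[str, float]] | None = None,
    with_attrs: bool = True,
) -> RoadNetwork:
    """Straight-edge network from node coords and (edge_id, u, v) triples."""
    edges = []
    for eid, u, v in edge_pairs:
        geom = (coords[u], coords[v])
        length = math.dist(*geom)
        a = (attrs or {}).get(eid, const_attrs()) if with_attrs else {}
        edges.append(Edge(eid, u, v, geom, length, a))
    return RoadNetwork(coords, edges)


def make_grid(
    rows: int,
    cols: int,
    spacing: float = 100.0,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    drop_edges: int = 0,
    with_attrs: bool = True,
) -> RoadNetwork:
    """Small rectilinear (optionally jittered/thinned) grid for tests."""
    rng = rng or np.random.default_rng(0)
    coords = {}
    for r in range(rows):
        for c in range(cols):
            jx, jy = rng.normal(0, jitter, 2) if jitter > 0 else (0.0, 0.0)
            coords[f"n{r}_{c}"] = (c * spacing + jx, r * spacing + jy)
    pairs = []
    for r in range(rows):
        for c in range(cols - 1):
            pairs.append((f"h{r}_{c}", f"n{r}_{c}", f"n{r}_{c + 1}"))
    for r in range(rows - 1):
        for c in range(cols):
            pairs.append((f"v{r}_{c}", f"n{r}_{c}", f"n{r + 1}_{c}"))
    if drop_edges:
        import networkx as nx

        keep = list(pairs)
        removable = rng.permutation(len(keep))
        removed = 0
        for idx in removable:
            if removed >= drop_edges:
                break
            candidate = [p for i, p in enumerate(keep) if i != idx]
            g = nx.Graph((u, v) for _, u, v in candidate)
            g.add_nodes_from(coords)
            if nx.is_connected(g):
                keep[idx] = None
                removed += 1
        pairs = [p for p in keep if p is not None]
    return build_network(coords, pairs, with_attrs=with_attrs)


@pytest.fixture
def grid3x3() -> RoadNetwork:
    return make_grid(3, 3)


@pytest.fixture
def two_loop():
    """Straight main street with two one-block detours.

    Alternative: a0-a1-a2-a3-a4-a5 along y=0.  Chosen deviates via b1
    between a1 and a2 and via b2 between a3 and a4.
    """
    coords = {f"a{i}": (100.0 * i, 0.0) for i in range(6)}
    coords["b1"] = (150.0, 100.0)
    coords["b2"] = (350.0, 100.0)
    pairs = [(f"m{i}", f"a{i}", f"a{i + 1}") for i in range(5)]
    pairs += [("d1a", "a1", "b1"), ("d1b", "b1", "a2"),
              ("d2a", "a3", "b2"), ("d2b", "b2", "a4")]
    net = build_network(coords, pairs)
    from routewalk.network import Route

    alt = Route.from_edges(net, "a0", ["m0", "m1", "m2", "m3", "m4"])
    chosen = Route.from_edges(
        net, "a0", ["m0", "d1a", "d1b", "m2", "d2a", "d2b", "m4"]
    )
    return net, chosen, alt
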