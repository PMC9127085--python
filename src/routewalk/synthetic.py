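"""Synthetic street networks and utility-maximising route choices.

This module emulates the inputs of a neighbourhood route-choice study so
the whole pipeline is testable end to end with a known data-generating
process: a jittered grid street network with audited per-edge environment
attributes, origin-destination pairs at short walking-trip scale, and
choices simulated from the same random-utility model the estimator fits
(systematic utility ``beta' x`` plus standard Gumbel noise).

All randomness flows through one seed; each stage (grid layout, attribute
draws, OD sampling, choice noise) draws from an independent child stream
keyed by stage name, so regenerating any stage is reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .clogit import ChoiceObservation
from .environment import ATTRIBUTE_FIELDS, aggregate_route_environment
from .network import Edge, RoadNetwork, Route
from .routing import least_angular_route, shortest_distance_route

_STAGES = {"layout": 0, "attributes": 1, "od": 2, "choices": 3, "detours": 4}

#: Per-edge attribute sampling families.  Widths and D/H are lognormal,
#: condition codes categorical, street-furniture counts Poisson with a
#: per-100 m rate scaled by edge length, frontage proportions Beta.
DEFAULT_ATTRIBUTE_PARAMS: Mapping[str, tuple] = {
    "sidewalk_width": ("lognormal", math.log(2.0), 0.30),
    "driveway_width": ("lognormal", math.log(6.0), 0.30),
    "dh_ratio": ("lognormal", math.log(1.2), 0.40),
    "on_street_parking": ("categorical", {1: 0.30, 2: 0.40, 3: 0.30}),
    "sidewalk_walkability": ("categorical", {1: 0.20, 2: 0.50, 3: 0.30}),
    "green_spaces": ("categorical", {1: 0.40, 2: 0.40, 3: 0.20}),
    "street_walls": ("categorical", {0: 0.50, 1: 0.30, 2: 0.20}),
    "traffic_signals": ("poisson_per_100m", 0.3),
    "garbage_bins": ("poisson_per_100m", 1.5),
    "streetlights": ("poisson_per_100m", 3.0),
    "benches": ("poisson_per_100m", 0.5),
    "shops": ("beta", 1.2, 6.0),
    "life_facilities": ("beta", 1.0, 8.0),
    "bus_stops": ("beta", 0.5, 15.0),
    "leisure_facilities": ("beta", 0.8, 10.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a dense old residential neighbourhood: ~100 m blocks
    on an 8x8 intersection grid with mild geometric jitter, 219 pedestrians
    making short utilitarian trips around a 350 m scale, and true utility
    weights favouring green spaces and (negatively) sidewalk width.
    """

    rows: int = 8
    cols: int = 8
    block_length_range: tuple[float, float] = (60.0, 140.0)
    jitter_std: float = 4.0
    n_od_pairs: int = 219
    trip_length_scale: float = 350.0
    beta_true: Mapping[str, float] = field(
        default_factory=lambda: {"green_spaces": 1.0, "sidewalk_width": -0.5}
    )
    attribute_params: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTE_PARAMS)
    )
    seed: int = 0

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "block_length_range" in raw:
            raw["block_length_range"] = tuple(raw["block_length_range"])
        if "attribute_params" in raw:
            raw["attribute_params"] = {
                k: tuple(v) for k, v in raw["attribute_params"].items()
            }
        return cls(**raw)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent child stream for one generation stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    )


def _draw_attribute(rng: np.random.Generator, dist: tuple, length: float) -> float:
    family = dist[0]
    if family == "lognormal":
        return float(rng.lognormal(mean=dist[1], sigma=dist[2]))
    if family == "categorical":
        codes = sorted(dist[1])
        probs = np.array([dist[1][c] for c in codes], dtype=float)
        return float(rng.choice(codes, p=probs / probs.sum()))
    if family == "poisson_per_100m":
        return float(rng.poisson(dist[1] * length / 100.0))
    if family == "beta":
        return float(rng.beta(dist[1], dist[2]))
    raise ValueError(f"unknown attribute family {family!r}")


def sample_edge_attributes(
    rng: np.random.Generator,
    length: float,
    params: Mapping[str, tuple] = DEFAULT_ATTRIBUTE_PARAMS,
) -> dict[str, float]:
    """One audit record for an edge of the given length."""
    return {f: _draw_attribute(rng, params[f], length) for f in ATTRIBUTE_FIELDS}


def generate_network(cfg: SyntheticConfig) -> RoadNetwork:
    """Jittered grid street network with audited per-edge attributes.

    Column and row spacings are drawn uniformly from the block-length
    range; nodes are then jittered with isotropic Gaussian noise of
    ``jitter_std`` metres, so streets are nearly but not exactly
    rectilinear (turn costs spread around 0 and 1).
    """
    if cfg.rows < 2 or cfg.cols < 2:
        raise ValueError("grid must be at least 2x2 intersections")
    rng = stage_rng(cfg.seed, "layout")
    lo, hi = cfg.block_length_range
    xs = np.concatenate([[0.0], np.cumsum(rng.uniform(lo, hi, size=cfg.cols - 1))])
    ys = np.concatenate([[0.0], np.cumsum(rng.uniform(lo, hi, size=cfg.rows - 1))])
    nodes: dict[str, tuple[float, float]] = {}
    for r in range(cfg.rows):
        for c in range(cfg.cols):
            jx, jy = (
                rng.normal(0.0, cfg.jitter_std, size=2)
                if cfg.jitter_std > 0
                else (0.0, 0.0)
            )
            nodes[f"n{r:02d}_{c:02d}"] = (float(xs[c] + jx), float(ys[r] + jy))

    attr_rng = stage_rng(cfg.seed, "attributes")
    edges: list[Edge] = []

    def add_edge(eid: str, u: str, v: str) -> None:
        geom = (nodes[u], nodes[v])
        length = math.dist(*geom)
        attrs = sample_edge_attributes(attr_rng, length, cfg.attribute_params)
        edges.append(Edge(eid, u, v, geom, length, attrs))

    for r in range(cfg.rows):
        for c in range(cfg.cols - 1):
            add_edge(f"h{r:02d}_{c:02d}", f"n{r:02d}_{c:02d}", f"n{r:02d}_{c + 1:02d}")
    for r in range(cfg.rows - 1):
        for c in range(cfg.cols):
            add_edge(f"v{r:02d}_{c:02d}", f"n{r:02d}_{c:02d}", f"n{r + 1:02d}_{c:02d}")
    return RoadNetwork(nodes, edges)


def sample_od_pairs(net: RoadNetwork, cfg: SyntheticConfig) -> list[tuple[str, str]]:
    """OD pairs whose shortest-path length is within [0.5, 2] x trip scale.

    Within that band, candidates are accepted with a Gaussian weight centred
    on the trip-length scale (sd = 30% of the scale), so the cohort's mean
    trip length sits near the scale rather than at the band's centre of
    mass — short neighbourhood trips, not grid-diameter walks.
    """
    rng = stage_rng(cfg.seed, "od")
    node_ids = sorted(net.nodes)
    scale = cfg.trip_length_scale
    lo, hi = 0.5 * scale, 2.0 * scale
    sigma = 0.3 * scale
    pairs: list[tuple[str, str]] = []
    attempts = 0
    max_attempts = max(2000 * cfg.n_od_pairs, 10_000)
    while len(pairs) < cfg.n_od_pairs:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {cfg.n_od_pairs} OD pairs with shortest length in "
                f"[{lo:.0f}, {hi:.0f}] m after {attempts} draws"
            )
        attempts += 1
        o, d = rng.choice(len(node_ids), size=2, replace=False)
        o, d = node_ids[o], node_ids[d]
        try:
            dist = nx.shortest_path_length(net.graph, o, d, weight="length")
        except nx.NetworkXNoPath:
            continue
        if not lo <= dist <= hi:
            continue
        if rng.random() < math.exp(-0.5 * ((dist - scale) / sigma) ** 2):
            pairs.append((o, d))
    return pairs


def labeled_alternatives(
    net: RoadNetwork, od_pairs: Sequence[tuple[str, str]]
) -> list[tuple[Route, Route]]:
    """(shortest-distance, least-angular) route pair per OD, with caching."""
    cache: dict[tuple[str, str], tuple[Route, Route]] = {}
    out = []
    for o, d in od_pairs:
        key = (str(o), str(d))
        if key not in cache:
            cache[key] = (
                shortest_distance_route(net, *key),
                least_angular_route(net, *key),
            )
        out.append(cache[key])
    return out


def pairwise_design(
    net: RoadNetwork,
    od_pairs: Sequence[tuple[str, str]],
    attributes: Sequence[str],
) -> tuple[np.ndarray, list[tuple[Route, Route]]]:
    """Attribute design for the two labeled alternatives of every OD pair.

    Returns an array of shape (n, 2, k) — rows ordered (shortest,
    least-angular) — and the route pairs themselves.  Aggregation is the
    length-weighted route environment.
    """
    pairs = labeled_alternatives(net, od_pairs)
    X = np.empty((len(pairs), 2, len(attributes)))
    env_cache: dict[tuple[str, ...], np.ndarray] = {}
    for i, (rs, ra) in enumerate(pairs):
        for j, route in enumerate((rs, ra)):
            key = route.edge_ids
            if key not in env_cache:
                env = aggregate_route_environment(net, route)
                env_cache[key] = np.array([env[a] for a in attributes])
            X[i, j] = env_cache[key]
    return X, pairs


def draw_choices(X: np.ndarray, beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argmax of ``beta' x + Gumbel(0, 1)`` per observation; shape (n,)."""
    util = X @ np.asarray(beta, dtype=float)
    util = util + rng.gumbel(size=util.shape)
    return util.argmax(axis=1)


def simulate_choices(
    net: RoadNetwork,
    od_pairs: Sequence[tuple[str, str]],
    beta_true: Mapping[str, float],
    mode: str = "pairwise",
    seed: int = 0,
    k_detours: int = 3,
) -> list[Route]:
    """Utility-maximising chosen route per OD pair.

    In ``pairwise`` mode the choice set is the two labeled alternatives; in
    ``choice-set`` mode it additionally contains up to ``k_detours`` random
    simple-path detours (shortest paths under randomly perturbed edge
    weights).  When all alternatives coincide, the common route is returned
    (the trip is a full-overlap case by construction).
    """
    attributes = sorted(beta_true)
    beta = np.array([beta_true[a] for a in attributes], dtype=float)
    rng = stage_rng(seed, "choices")
    chosen: list[Route] = []
    if mode == "pairwise":
        X, pairs = pairwise_design(net, od_pairs, attributes)
        idx = draw_choices(X, beta, rng)
        for i, (rs, ra) in enumerate(pairs):
            if set(rs.edge_ids) == set(ra.edge_ids):
                chosen.append(rs)
            else:
                chosen.append((rs, ra)[idx[i]])
        return chosen
    if mode != "choice-set":
        raise ValueError(f"unknown mode {mode!r}")

    detour_rng = stage_rng(seed, "detours")
    edge_order = sorted(net.edges)
    for o, d in od_pairs:
        rs = shortest_distance_route(net, str(o), str(d))
        ra = least_angular_route(net, str(o), str(d))
        routes = [rs]
        if set(ra.edge_ids) != set(rs.edge_ids):
            routes.append(ra)
        seen = {frozenset(r.edge_ids) for r in routes}
        for _ in range(k_detours):
            factors = dict(
                zip(edge_order, detour_rng.uniform(0.5, 2.0, size=len(edge_order)))
            )
            path = nx.shortest_path(
                net.graph, str(o), str(d),
                weight=lambda u, v, data: data["length"] * factors[data["edge_id"]],
            )
            eids = [net.edge_between(path[i], path[i + 1]) for i in range(len(path) - 1)]
            route = Route.from_edges(net, str(o), eids)
            if frozenset(route.edge_ids) not in seen:
                seen.add(frozenset(route.edge_ids))
                routes.append(route)
        if len(routes) == 1:
            chosen.append(routes[0])
            continue
        X = np.array(
            [
                [aggregate_route_environment(net, r)[a] for a in attributes]
                for r in routes
            ]
        )
        util = X @ beta + rng.gumbel(size=len(routes))
        chosen.append(routes[int(util.argmax())])
    return chosen


def pairwise_observations(
    X: np.ndarray, choices: np.ndarray, attributes: Sequence[str]
) -> list[ChoiceObservation]:
    """Package a pairwise design and simulated choices for estimation."""
    return [
        ChoiceObservation(chooser_id=f"od{i:04d}", X=X[i], chosen=int(choices[i]))
        for i in range(X.shape[0])
    ]
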