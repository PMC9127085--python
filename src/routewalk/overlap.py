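"""Chosen-versus-alternative route overlap decomposition.

A chosen route is compared with a labeled alternative sharing its OD pair.
The overlap ratio is the length of the shared edges divided by the chosen
route's length; full overlap (identical edge sets) marks trips whose choice
is explained by the labeling criterion alone, and such trips are excluded
before model fitting.  For partially overlapping trips the chosen route is
decomposed into shared runs and deviated part-routes, each bounded by a
divergence and a reconvergence intersection that also lie on the
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .network import RoadNetwork, Route


def _check_same_od(chosen: Route, alt: Route) -> None:
    if chosen.origin != alt.origin or chosen.destination != alt.destination:
        raise ValueError(
            f"OD mismatch: chosen {chosen.origin}->{chosen.destination}, "
            f"alternative {alt.origin}->{alt.destination}"
        )


@dataclass(frozen=True)
class OverlapResult:
    """Full decomposition of one chosen route against one alternative."""

    overlap_ratio: float
    shared_edges: frozenset[str]
    is_full_overlap: bool
    deviation_pairs: tuple[tuple[Route, Route], ...]


def overlap_ratio(
    chosen: Route, alt: Route, net: RoadNetwork, denominator: str = "chosen"
) -> float:
    """Shared-edge length as a fraction of the chosen route's length.

    ``denominator="symmetric"`` divides by the mean of the two route
    lengths instead, a symmetric variant of the same statistic.
    """
    _check_same_od(chosen, alt)
    shared = set(chosen.edge_ids) & set(alt.edge_ids)
    if shared == set(chosen.edge_ids) == set(alt.edge_ids):
        return 1.0  # exact, independent of float summation order
    shared_len = sum(net.edges[e].length for e in shared)
    if denominator == "chosen":
        denom = chosen.total_length
    elif denominator == "symmetric":
        denom = 0.5 * (chosen.total_length + alt.total_length)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError("route has non-positive length")
    return shared_len / denom


def is_full_overlap(chosen: Route, alt: Route) -> bool:
    """Exact edge-set equality between chosen and alternative."""
    _check_same_od(chosen, alt)
    return set(chosen.edge_ids) == set(alt.edge_ids)


def _round_pct(count: int, total: int) -> int:
    return int(math.floor(100.0 * count / total + 0.5))


def classify_overlap(
    chosen: Sequence[Route], alts: Sequence[Route]
) -> tuple[int, int, int]:
    """Count fully overlapping trips: (n_full, n_total, percentage).

    Percentage is rounded to the nearest integer (half up), the convention
    used when reporting e.g. 145 of 219 trips as 66%.
    """
    if len(chosen) != len(alts):
        raise ValueError(
            f"aligned route lists required ({len(chosen)} chosen vs {len(alts)} alternatives)"
        )
    if not chosen:
        raise ValueError("empty route lists")
    n_full = sum(1 for c, a in zip(chosen, alts) if is_full_overlap(c, a))
    return n_full, len(chosen), _round_pct(n_full, len(chosen))


def overlap_distribution(
    ratios: Sequence[float], thresholds: Sequence[float]
) -> list[float]:
    """Share of trips whose overlap ratio is >= each threshold.

    Shares are non-increasing in the threshold; ratios must lie in [0, 1].
    """
    if not ratios:
        raise ValueError("no overlap ratios given")
    for r in ratios:
        if not 0.0 <= r <= 1.0 + 1e-12:
            raise ValueError(f"overlap ratio {r} outside [0, 1]")
    n = len(ratios)
    return [sum(1 for r in ratios if r >= t) / n for t in thresholds]


def extract_deviation_pairs(
    chosen: Route, alt: Route, net: RoadNetwork
) -> list[tuple[Route, Route]]:
    """Deviated part-routes of a chosen route against an alternative.

    Each pair is a maximal chosen sub-path absent from the alternative,
    together with the alternative's sub-path between the same divergence
    and reconvergence intersections, ordered along the chosen route.  Fully
    overlapping trips yield an empty list.
    """
    _check_same_od(chosen, alt)
    alt_edges = set(alt.edge_ids)
    pairs: list[tuple[Route, Route]] = []
    i = 0
    n = len(chosen.edge_ids)
    while i < n:
        if chosen.edge_ids[i] in alt_edges:
            i += 1
            continue
        j = i
        while j < n and chosen.edge_ids[j] not in alt_edges:
            j += 1
        diverge = chosen.node_ids[i]
        reconverge = chosen.node_ids[j]
        chosen_sub = Route.from_edges(net, diverge, chosen.edge_ids[i:j])
        pairs.append((chosen_sub, _alt_subroute(alt, diverge, reconverge, net)))
        i = j
    return pairs


def _alt_subroute(alt: Route, diverge: str, reconverge: str, net: RoadNetwork) -> Route:
    """Alternative's sub-path between two intersections on it."""
    try:
        a = alt.node_ids.index(diverge)
    except ValueError:
        raise ValueError(f"divergence node {diverge!r} not on the alternative route")
    try:
        b = alt.node_ids.index(reconverge, a)
    except ValueError:
        # reconvergence occurs before the divergence along the alternative;
        # return the reversed slice so endpoints still match the chosen side.
        try:
            b = alt.node_ids.index(reconverge)
        except ValueError:
            raise ValueError(
                f"reconvergence node {reconverge!r} not on the alternative route"
            )
        return Route.from_edges(net, diverge, alt.edge_ids[b:a][::-1])
    return Route.from_edges(net, diverge, alt.edge_ids[a:b])


def decompose(chosen: Route, alt: Route, net: RoadNetwork, denominator: str = "chosen") -> OverlapResult:
    """Overlap ratio, shared edges, full-overlap flag and deviation pairs."""
    ratio = overlap_ratio(chosen, alt, net, denominator=denominator)
    full = is_full_overlap(chosen, alt)
    pairs = () if full else tuple(extract_deviation_pairs(chosen, alt, net))
    return OverlapResult(
        overlap_ratio=ratio,
        shared_edges=frozenset(set(chosen.edge_ids) & set(alt.edge_ids)),
        is_full_overlap=full,
        deviation_pairs=pairs,
    )


def summarize_route_lengths(
    routes: Sequence[Route], full_overlap_flags: Sequence[bool]
) -> dict[str, float | None]:
    """Mean trip length (metres) overall and by full-overlap group."""
    if len(routes) != len(full_overlap_flags):
        raise ValueError("routes and flags must align")
    if not routes:
        raise ValueError("no routes to summarize")
    lengths = [r.total_length for r in routes]
    full = [l for l, f in zip(lengths, full_overlap_flags) if f]
    partial = [l for l, f in zip(lengths, full_overlap_flags) if not f]
    mean = lambda xs: sum(xs) / len(xs) if xs else None
    return {
        "mean_length": mean(lengths),
        "mean_length_full_overlap": mean(full),
        "mean_length_partial_overlap": mean(partial),
        "n": len(lengths),
        "n_full_overlap": len(full),
    }
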