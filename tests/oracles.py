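"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the library's search code: routes are found by
exhaustive depth-first enumeration of edge-simple paths (with cost-bound
pruning), angular depths by Bellman-Ford-style value iteration on the
segment links, and the scalar conditional-logit MLE by ternary search on
the concave log-likelihood.
"""

from __future__ import annotations

import math

from routewalk.network import RoadNetwork


def enumerate_best_route(
    net: RoadNetwork, origin: str, dest: str, primary: str
) -> tuple[str, ...]:
    """Best edge-simple path by exhaustive enumeration.

    Key: (primary cost, secondary cost, edge-id sequence) with
    primary/secondary = (length, turn cost) or (turn cost, length).
    Returns the edge-id tuple, or raises if no path exists.
    """
    best: tuple[float, float, tuple[str, ...]] | None = None

    def rec(node: str, in_edge: str | None, length: float, turns: float,
            seq: tuple[str, ...], used: frozenset[str]) -> None:
        nonlocal best
        p, s = (length, turns) if primary == "length" else (turns, length)
        if best is not None and (p, s) > (best[0], best[1]):
            return
        if node == dest:
            key = (p, s, seq)
            if best is None or key < best:
                best = key
            return
        for nbr in net.graph[node]:
            eid = net.graph.edges[node, nbr]["edge_id"]
            if eid in used:
                continue
            turn = 0.0 if in_edge is None else net.angular_cost(in_edge, node, eid)
            rec(nbr, eid, length + net.edges[eid].length, turns + turn,
                seq + (eid,), used | {eid})

    rec(str(origin), None, 0.0, 0.0, (), frozenset())
    if best is None:
        raise ValueError(f"no path {origin!r} -> {dest!r}")
    return best[2]


def bellman_depths(net: RoadNetwork, origin: str) -> dict[str, float]:
    """Angular step depths by repeated relaxation over all segment links."""
    links = []
    for node in net.nodes:
        incident = net.incident_edges(node)
        for i in range(len(incident)):
            for j in range(i + 1, len(incident)):
                a, b = incident[i], incident[j]
                links.append((a, b, net.angular_cost(a, node, b)))
    depth = {e: math.inf for e in net.edges}
    for e in net.incident_edges(str(origin)):
        depth[e] = 0.0
    changed = True
    while changed:
        changed = False
        for a, b, cost in links:
            if depth[a] + cost < depth[b]:
                depth[b] = depth[a] + cost
                changed = True
            if depth[b] + cost < depth[a]:
                depth[a] = depth[b] + cost
                changed = True
    return {e: d for e, d in depth.items() if d < math.inf}


def scalar_clogit_mle(loglik, lo: float = -20.0, hi: float = 20.0,
                      tol: float = 1e-10) -> float:
    """Ternary search for the maximiser of a concave scalar function."""
    while hi - lo > tol:
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        if loglik(m1) < loglik(m2):
            lo = m1
        else:
            hi = m2
    return 0.5 * (lo + hi)


def segment_pair_count(net: RoadNetwork) -> int:
    """Number of node-sharing edge pairs, counted by direct enumeration."""
    count = 0
    for node in net.nodes:
        deg = len(net.incident_edges(node))
        count += deg * (deg - 1) // 2
    return count
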