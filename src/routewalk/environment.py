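"""Street-environment attribute schema and route-level aggregation.

The walkability audit records fifteen attributes per street segment, grouped
into four functional categories:

* **Roadway features** — sidewalk width (m), on-street parking type
  (ordinal 1–3), sidewalk walkability condition (ordinal 1–3: poor/fair/good),
  number of traffic-control signals, driveway width (m).
* **Streetscape** — D/H ratio (street width over flanking building height),
  green-space provision (ordinal 1–3), street-wall character (ordinal 0–2:
  none / railing / solid wall).
* **Pedestrian infrastructure** — counts of garbage bins, streetlights and
  benches along the segment.
* **Facilities** — proportion of street frontage occupied by shops, daily-life
  facilities, bus stops and leisure facilities (each in [0, 1]).

Route-level values are produced by length-weighting the condition and
magnitude variables over member edges and summing the count variables, so a
route inherits the audit scale of its segments.  Ordinal condition codes are
treated as interval-scaled for the weighted mean; this is a deliberate
modelling simplification (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a runtime cycle
    from .network import RoadNetwork, Route

ROADWAY_FIELDS = (
    "sidewalk_width",
    "on_street_parking",
    "sidewalk_walkability",
    "traffic_signals",
    "driveway_width",
)
STREETSCAPE_FIELDS = ("dh_ratio", "green_spaces", "street_walls")
INFRASTRUCTURE_FIELDS = ("garbage_bins", "streetlights", "benches")
FACILITY_FIELDS = ("shops", "life_facilities", "bus_stops", "leisure_facilities")

#: Audit attributes in schema order (CSV column order).
ATTRIBUTE_FIELDS = (
    ROADWAY_FIELDS + STREETSCAPE_FIELDS + INFRASTRUCTURE_FIELDS + FACILITY_FIELDS
)

#: Attributes aggregated by summation over route edges (raw counts).
COUNT_FIELDS = ("traffic_signals", "garbage_bins", "streetlights", "benches")

#: Attributes aggregated as length-weighted means over route edges.
MEAN_FIELDS = tuple(f for f in ATTRIBUTE_FIELDS if f not in COUNT_FIELDS)

#: Ordinal condition codes and their coded ranges.
ORDINAL_RANGES: Mapping[str, tuple[int, int]] = {
    "on_street_parking": (1, 3),
    "sidewalk_walkability": (1, 3),
    "green_spaces": (1, 3),
    "street_walls": (0, 2),
}

#: Street-frontage proportions, constrained to [0, 1].
PROPORTION_FIELDS = FACILITY_FIELDS

CATEGORY_LABELS = {
    "roadway": "Roadway features",
    "streetscape": "Streetscape",
    "infrastructure": "Pedestrian infrastructure",
    "facilities": "Facilities",
}

#: Category key for every attribute, used to group model-output rows.
CATEGORY_OF = {
    **{f: "roadway" for f in ROADWAY_FIELDS},
    **{f: "streetscape" for f in STREETSCAPE_FIELDS},
    **{f: "infrastructure" for f in INFRASTRUCTURE_FIELDS},
    **{f: "facilities" for f in FACILITY_FIELDS},
}


class AttributeValidationError(ValueError):
    """An attribute record violates the audit-tool schema."""


def validate_attributes(attrs: Mapping[str, float], edge_id: str | None = None) -> None:
    """Check a per-edge attribute record against the audit schema.

    Raises :class:`AttributeValidationError` naming the offending edge and
    field.  A record must carry every schema field.
    """
    where = f" (edge {edge_id})" if edge_id is not None else ""
    missing = [f for f in ATTRIBUTE_FIELDS if f not in attrs]
    if missing:
        raise AttributeValidationError(f"missing attribute fields {missing}{where}")
    for field in ATTRIBUTE_FIELDS:
        value = float(attrs[field])
        if value != value:  # NaN
            raise AttributeValidationError(f"{field} is NaN{where}")
        if field in ORDINAL_RANGES:
            lo, hi = ORDINAL_RANGES[field]
            if value != int(value) or not lo <= value <= hi:
                raise AttributeValidationError(
                    f"{field}={value} outside ordinal codes {lo}..{hi}{where}"
                )
        elif field in PROPORTION_FIELDS:
            if not 0.0 <= value <= 1.0:
                raise AttributeValidationError(
                    f"{field}={value} not a proportion in [0, 1]{where}"
                )
        elif field == "dh_ratio":
            if value <= 0:
                raise AttributeValidationError(f"dh_ratio={value} must be > 0{where}")
        else:  # widths and counts
            if value < 0:
                raise AttributeValidationError(f"{field}={value} must be >= 0{where}")


@dataclass(frozen=True)
class RouteEnvironment:
    """Street-environment attribute vector aggregated over a route."""

    values: Mapping[str, float]
    total_length: float

    def __getitem__(self, field: str) -> float:
        return self.values[field]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def aggregate_edges_environment(
    net: "RoadNetwork",
    edge_ids: Iterable[str],
    counts_per_100m: bool = False,
) -> RouteEnvironment:
    """Aggregate per-edge attributes over an arbitrary edge set.

    Mean-type fields (widths, D/H, ordinal condition codes, frontage
    proportions) are length-weighted means; count fields are raw sums, or
    per-100 m rates when ``counts_per_100m`` is set.
    """
    edge_ids = list(edge_ids)
    if not edge_ids:
        raise ValueError("cannot aggregate an empty edge set")
    edges = []
    for eid in edge_ids:
        edge = net.edges.get(eid)
        if edge is None:
            raise KeyError(f"unknown edge {eid!r}")
        if not edge.attributes:
            raise AttributeValidationError(f"edge {eid!r} has no attribute record")
        edges.append(edge)
    total = sum(e.length for e in edges)
    values: dict[str, float] = {}
    for field in MEAN_FIELDS:
        values[field] = sum(e.attributes[field] * e.length for e in edges) / total
    for field in COUNT_FIELDS:
        count = float(sum(e.attributes[field] for e in edges))
        values[field] = count * 100.0 / total if counts_per_100m else count
    return RouteEnvironment(values=values, total_length=total)


def aggregate_route_environment(
    net: "RoadNetwork", route: "Route", counts_per_100m: bool = False
) -> RouteEnvironment:
    """Length-weighted attribute vector of a route (see module docstring)."""
    if not route.edge_ids:
        raise ValueError("cannot aggregate an empty route")
    return aggregate_edges_environment(net, route.edge_ids, counts_per_100m)


def attribute_difference(
    a: RouteEnvironment, b: RouteEnvironment, include_length: bool = False
) -> dict[str, float]:
    """Elementwise attribute difference ``a - b`` between two routes.

    Total length is excluded unless ``include_length`` is set (the choice
    models compare environments, not distances, between alternatives).
    """
    if set(a.values) != set(b.values):
        raise ValueError("route environments have different attribute schemas")
    diff = {field: a.values[field] - b.values[field] for field in a.values}
    if include_length:
        diff["total_length"] = a.total_length - b.total_length
    return diff
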