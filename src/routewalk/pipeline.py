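"""Full route-choice analysis pipeline.

Given a street network with audit attributes and a cohort of chosen
routes, the pipeline

1. generates both labeled alternatives (shortest-distance, least-angular)
   per OD pair,
2. computes overlap statistics and the full-overlap classification against
   each alternative and against both,
3. excludes trips whose chosen route completely overlaps the respective
   alternative (their choice is explained by distance or direction alone),
4. aggregates street-environment attributes for entire routes and for the
   deviated part-routes, and
5. fits four conditional-logit models — {entire, part} x {shortest,
   least_angular} — each comparing the chosen side against the alternative
   side on a configurable attribute subset.

Outputs are deterministic given inputs and configuration; CSV/JSON writers
use fixed float formatting so re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .clogit import (
    CLFit,
    ChoiceObservation,
    MODEL_PRESETS,
    NotConvergedError,
    SeparationError,
    fit_clogit,
    model_table,
)
from .environment import aggregate_edges_environment, aggregate_route_environment
from .network import RoadNetwork, Route
from .overlap import (
    classify_overlap,
    decompose,
    overlap_distribution,
    summarize_route_lengths,
)
from .synthetic import labeled_alternatives

log = logging.getLogger("routewalk")

MODEL_KEYS = ("entire_shortest", "entire_least_angular", "part_shortest", "part_least_angular")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis configuration (one YAML document)."""

    overlap_thresholds: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0)
    overlap_denominator: str = "chosen"
    #: minimum summed deviated length (m) for a trip to enter part-route models
    min_deviation_length: float = 0.0
    #: attribute subset per model; defaults to the four named presets
    model_attributes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: MODEL_PRESETS[k] for k in MODEL_KEYS}
    )
    counts_per_100m: bool = False
    zscore: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown pipeline config keys {sorted(unknown)}")
        if "overlap_thresholds" in raw:
            raw["overlap_thresholds"] = tuple(float(t) for t in raw["overlap_thresholds"])
        if "model_attributes" in raw:
            merged = {k: MODEL_PRESETS[k] for k in MODEL_KEYS}
            for k, attrs in raw["model_attributes"].items():
                if k not in MODEL_KEYS:
                    raise ValueError(f"unknown model key {k!r}")
                merged[k] = tuple(attrs)
            raw["model_attributes"] = merged
        return cls(**raw)

    def canonical_json(self) -> str:
        payload = {
            "overlap_thresholds": list(self.overlap_thresholds),
            "overlap_denominator": self.overlap_denominator,
            "min_deviation_length": self.min_deviation_length,
            "model_attributes": {k: list(v) for k, v in sorted(self.model_attributes.items())},
            "counts_per_100m": self.counts_per_100m,
            "zscore": self.zscore,
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class ModelResult:
    """One fitted model (or the reason it was skipped)."""

    key: str
    attributes: tuple[str, ...]
    n_obs: int
    fit: CLFit | None
    od_ids: tuple[str, ...] = ()
    notice: str | None = None


@dataclass
class AnalysisReport:
    """Everything the pipeline computes for one cohort."""

    n_trips: int
    length_summary: dict
    full_overlap: dict[str, tuple[int, int, int]]  # label -> (n_full, n, pct)
    overlap_thresholds: tuple[float, ...]
    overlap_shares: dict[str, list[float]]
    overlap_rows: list[dict]
    models: dict[str, ModelResult]
    config_digest: str
    seed: int
    version: str


def _model_observations_entire(
    net: RoadNetwork,
    trips: Sequence[tuple[str, Route, Route]],
    attributes: Sequence[str],
    counts_per_100m: bool,
) -> list[ChoiceObservation]:
    obs = []
    for od_id, chosen, alt in trips:
        xc = aggregate_route_environment(net, chosen, counts_per_100m)
        xa = aggregate_route_environment(net, alt, counts_per_100m)
        X = np.array([[xc[a] for a in attributes], [xa[a] for a in attributes]])
        obs.append(ChoiceObservation(chooser_id=od_id, X=X, chosen=0))
    return obs


def _model_observations_part(
    net: RoadNetwork,
    trips: Sequence[tuple[str, Route, Route]],
    attributes: Sequence[str],
    counts_per_100m: bool,
    min_deviation_length: float,
) -> tuple[list[ChoiceObservation], int]:
    """Part-route observations; returns (observations, n_skipped)."""
    obs = []
    skipped = 0
    for od_id, chosen, alt in trips:
        alt_edges = set(alt.edge_ids)
        chosen_edges = set(chosen.edge_ids)
        dev_chosen = [e for e in chosen.edge_ids if e not in alt_edges]
        dev_alt = [e for e in alt.edge_ids if e not in chosen_edges]
        if not dev_chosen or not dev_alt:
            skipped += 1
            continue
        if min_deviation_length > 0:
            dev_len = sum(net.edges[e].length for e in dev_chosen)
            if dev_len < min_deviation_length:
                skipped += 1
                continue
        xc = aggregate_edges_environment(net, dev_chosen, counts_per_100m)
        xa = aggregate_edges_environment(net, dev_alt, counts_per_100m)
        X = np.array([[xc[a] for a in attributes], [xa[a] for a in attributes]])
        obs.append(ChoiceObservation(chooser_id=od_id, X=X, chosen=0))
    return obs, skipped


def _fit_model(key: str, obs: list[ChoiceObservation], attributes: tuple[str, ...], zscore: bool) -> ModelResult:
    od_ids = tuple(ob.chooser_id for ob in obs)
    if not obs:
        return ModelResult(key, attributes, 0, None, od_ids, notice="no eligible trips; model skipped")
    try:
        fit = fit_clogit(obs, attributes=attributes, zscore=zscore)
    except (SeparationError, NotConvergedError, ValueError) as exc:
        return ModelResult(key, attributes, len(obs), None, od_ids, notice=str(exc))
    return ModelResult(key, attributes, len(obs), fit, od_ids)


def run_pipeline(
    net: RoadNetwork,
    chosen_routes: Mapping[str, Route],
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis on a cohort of chosen routes.

    ``chosen_routes`` maps od_id -> chosen Route; alternatives are generated
    from each route's own OD pair.  Raises if a chosen route references an
    unknown edge (named by od_id).
    """
    config = config or PipelineConfig()
    od_ids = sorted(chosen_routes)
    if not od_ids:
        raise ValueError("empty cohort")
    for od_id in od_ids:
        for eid in chosen_routes[od_id].edge_ids:
            if eid not in net.edges:
                raise ValueError(f"chosen route {od_id!r} uses unknown edge {eid!r}")

    od_pairs = [
        (chosen_routes[i].origin, chosen_routes[i].destination) for i in od_ids
    ]
    alternatives = labeled_alternatives(net, od_pairs)
    log.info("generated labeled alternatives for %d trips", len(od_ids))

    labels = ("shortest", "least_angular")
    results = {lab: [] for lab in labels}
    overlap_rows: list[dict] = []
    for od_id, (rs, ra) in zip(od_ids, alternatives):
        chosen = chosen_routes[od_id]
        for lab, alt in zip(labels, (rs, ra)):
            res = decompose(chosen, alt, net, denominator=config.overlap_denominator)
            results[lab].append(res)
            overlap_rows.append(
                {
                    "od_id": od_id,
                    "label": lab,
                    "overlap_ratio": res.overlap_ratio,
                    "is_full_overlap": res.is_full_overlap,
                    "n_deviation_pairs": len(res.deviation_pairs),
                }
            )

    chosen_list = [chosen_routes[i] for i in od_ids]
    full_overlap: dict[str, tuple[int, int, int]] = {}
    for lab, alts in zip(labels, zip(*alternatives)):
        full_overlap[lab] = classify_overlap(chosen_list, list(alts))
    both_flags = [
        results["shortest"][i].is_full_overlap
        and results["least_angular"][i].is_full_overlap
        for i in range(len(od_ids))
    ]
    n_both = sum(both_flags)
    full_overlap["both"] = (
        n_both,
        len(od_ids),
        int(np.floor(100.0 * n_both / len(od_ids) + 0.5)),
    )

    overlap_shares = {
        lab: overlap_distribution(
            [r.overlap_ratio for r in results[lab]], config.overlap_thresholds
        )
        for lab in labels
    }
    length_summary = summarize_route_lengths(
        chosen_list, [results["shortest"][i].is_full_overlap for i in range(len(od_ids))]
    )

    models: dict[str, ModelResult] = {}
    for lab, (model_entire, model_part) in zip(
        labels, (("entire_shortest", "part_shortest"), ("entire_least_angular", "part_least_angular"))
    ):
        alt_of = dict(zip(od_ids, [a[labels.index(lab)] for a in alternatives]))
        kept = [
            (od_id, chosen_routes[od_id], alt_of[od_id])
            for i, od_id in enumerate(od_ids)
            if not results[lab][i].is_full_overlap
        ]
        log.info(
            "%s alternative: %d of %d trips retained after full-overlap exclusion",
            lab, len(kept), len(od_ids),
        )
        attrs_e = tuple(config.model_attributes[model_entire])
        obs_e = _model_observations_entire(net, kept, attrs_e, config.counts_per_100m)
        models[model_entire] = _fit_model(model_entire, obs_e, attrs_e, config.zscore)

        attrs_p = tuple(config.model_attributes[model_part])
        obs_p, skipped = _model_observations_part(
            net, kept, attrs_p, config.counts_per_100m, config.min_deviation_length
        )
        result = _fit_model(model_part, obs_p, attrs_p, config.zscore)
        if skipped:
            extra = f"{skipped} trips without usable deviated part-routes skipped"
            result.notice = f"{result.notice}; {extra}" if result.notice else extra
        models[model_part] = result

    return AnalysisReport(
        n_trips=len(od_ids),
        length_summary=length_summary,
        full_overlap=full_overlap,
        overlap_thresholds=config.overlap_thresholds,
        overlap_shares=overlap_shares,
        overlap_rows=overlap_rows,
        models=models,
        config_digest=config.digest(),
        seed=config.seed,
        version=__version__,
    )


# -- report serialisation --------------------------------------------------


def _fmt(x: float, nd: int = 6) -> str:
    return f"{x:.{nd}f}"


def write_report(report: AnalysisReport, out_dir: str) -> None:
    """Write overlap.csv, one model_*.csv per model, and report.json.

    Coefficients are printed to 3 decimals (table convention); overlap
    ratios to 6.  Output is byte-identical across re-runs on the same
    inputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "overlap.csv"), "w") as fh:
        fh.write("od_id,label,overlap_ratio,is_full_overlap,n_deviation_pairs\n")
        for row in report.overlap_rows:
            fh.write(
                f"{row['od_id']},{row['label']},{_fmt(row['overlap_ratio'])},"
                f"{int(row['is_full_overlap'])},{row['n_deviation_pairs']}\n"
            )

    name_of = {
        "entire_shortest": "model_entire_shortest.csv",
        "entire_least_angular": "model_entire_angular.csv",
        "part_shortest": "model_part_shortest.csv",
        "part_least_angular": "model_part_angular.csv",
    }
    for key, result in report.models.items():
        path = os.path.join(out_dir, name_of[key])
        with open(path, "w") as fh:
            fh.write("category,attribute,coef,se,z,p\n")
            if result.fit is not None:
                table = model_table(result.fit)
                for _, row in table.iterrows():
                    fh.write(
                        f"{row['category']},{row['attribute']},{_fmt(row['coef'], 3)},"
                        f"{_fmt(row['se'], 3)},{_fmt(row['z'], 3)},{_fmt(row['p'], 3)}\n"
                    )
                fh.write(f"# log-likelihood,{_fmt(result.fit.loglik, 3)}\n")
                fh.write(f"# null log-likelihood,{_fmt(result.fit.loglik_null, 3)}\n")
                fh.write(f"# n,{result.fit.n_obs}\n")
            if result.notice:
                fh.write(f"# notice,{result.notice}\n")

    payload = {
        "n_trips": report.n_trips,
        "mean_trip_length_m": report.length_summary["mean_length"],
        "length_summary": report.length_summary,
        "full_overlap": {
            lab: {"n_full": v[0], "n": v[1], "pct": v[2]}
            for lab, v in report.full_overlap.items()
        },
        "overlap_thresholds": list(report.overlap_thresholds),
        "overlap_shares": report.overlap_shares,
        "models": {
            key: {
                "attributes": list(r.attributes),
                "n_obs": r.n_obs,
                "fitted": r.fit is not None,
                "loglik": None if r.fit is None else round(r.fit.loglik, 6),
                "coef": None
                if r.fit is None
                else {a: round(float(b), 6) for a, b in zip(r.attributes, r.fit.beta)},
                "notice": r.notice,
            }
            for key, r in report.models.items()
        },
        "metadata": {
            "config_digest": report.config_digest,
            "seed": report.seed,
            "version": report.version,
        },
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
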