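"""Conditional-logit estimation for route choice.

The model follows random-utility theory: a chooser facing alternatives
j = 1..J receives utility U_j = beta' x_j + eps_j with i.i.d. standard
Gumbel errors, and picks the alternative with highest utility, so

    P(choose j) = exp(beta' x_j) / sum_k exp(beta' x_k).

Only attribute *differences* between alternatives are identified; there is
no intercept.  The log-likelihood is globally concave in beta, and the fit
uses Newton iteration with the analytic gradient and Hessian, standard
errors from the inverse observed information at the optimum, and two-sided
normal p values (the "p > z" convention of choice-model output tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from scipy.stats import norm

from .environment import ATTRIBUTE_FIELDS, CATEGORY_LABELS, CATEGORY_OF

#: Category display order for model output tables.
CATEGORY_ORDER = ("roadway", "streetscape", "infrastructure", "facilities")

#: Named attribute subsets for the four headline route-choice models
#: ({entire, part} x {shortest-distance, least-angular} comparisons).
MODEL_PRESETS: Mapping[str, tuple[str, ...]] = {
    "entire_shortest": (
        "driveway_width", "garbage_bins", "street_walls", "green_spaces", "shops",
    ),
    "entire_least_angular": (
        "sidewalk_width", "benches", "green_spaces", "street_walls",
        "leisure_facilities", "bus_stops",
    ),
    "part_shortest": (
        "sidewalk_width", "sidewalk_walkability", "driveway_width",
        "street_walls", "green_spaces", "streetlights",
    ),
    "part_least_angular": (
        "driveway_width", "traffic_signals", "on_street_parking",
        "street_walls", "dh_ratio", "green_spaces",
        "leisure_facilities", "shops",
    ),
}


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a direction perfectly separates choices."""


class NotConvergedError(RuntimeError):
    """Estimation did not reach the convergence tolerance."""


@dataclass(frozen=True)
class ChoiceObservation:
    """One chooser's alternatives (rows of ``X``) and the chosen row index."""

    chooser_id: str
    X: np.ndarray  # (n_alternatives, n_attributes)
    chosen: int

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError(
                f"observation {self.chooser_id!r} needs >= 2 alternatives"
            )
        if not 0 <= self.chosen < X.shape[0]:
            raise ValueError(
                f"observation {self.chooser_id!r}: chosen index {self.chosen} invalid"
            )


def observations_from_frame(
    df: pd.DataFrame, attributes: Sequence[str]
) -> list[ChoiceObservation]:
    """Build observations from a long-format table.

    Expects columns ``od_id``, ``alternative_label``, ``chosen`` (0/1, one 1
    per od_id) and one column per attribute.  Alternatives are ordered by
    label within each od_id for determinism.
    """
    required = {"od_id", "chosen", *attributes}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"long-format table missing columns {missing}")
    obs = []
    for od_id, group in df.groupby("od_id", sort=True):
        if "alternative_label" in group.columns:
            group = group.sort_values("alternative_label")
        chosen_flags = group["chosen"].to_numpy()
        if chosen_flags.sum() != 1:
            raise ValueError(f"od_id {od_id!r} must have exactly one chosen row")
        obs.append(
            ChoiceObservation(
                chooser_id=str(od_id),
                X=group[list(attributes)].to_numpy(dtype=float),
                chosen=int(np.argmax(chosen_flags)),
            )
        )
    return obs


def _check_dim(beta: np.ndarray, data: Sequence[ChoiceObservation]) -> None:
    k = beta.shape[0]
    for ob in data:
        if ob.X.shape[1] != k:
            raise ValueError(
                f"observation {ob.chooser_id!r} has {ob.X.shape[1]} attributes, "
                f"beta has {k}"
            )


def cl_loglik(beta: np.ndarray, data: Sequence[ChoiceObservation]) -> float:
    """Conditional-logit log-likelihood (log-sum-exp stabilised)."""
    beta = np.asarray(beta, dtype=float)
    _check_dim(beta, data)
    terms = []
    for ob in data:
        util = ob.X @ beta
        terms.append(util[ob.chosen] - logsumexp(util))
    return math.fsum(terms)


def cl_score(beta: np.ndarray, data: Sequence[ChoiceObservation]) -> np.ndarray:
    """Analytic gradient of the log-likelihood."""
    beta = np.asarray(beta, dtype=float)
    _check_dim(beta, data)
    grad = np.zeros_like(beta)
    for ob in data:
        p = softmax(ob.X @ beta)
        grad += ob.X[ob.chosen] - p @ ob.X
    return grad


def cl_hessian(beta: np.ndarray, data: Sequence[ChoiceObservation]) -> np.ndarray:
    """Analytic Hessian (negative semi-definite everywhere)."""
    beta = np.asarray(beta, dtype=float)
    _check_dim(beta, data)
    k = beta.shape[0]
    hess = np.zeros((k, k))
    for ob in data:
        p = softmax(ob.X @ beta)
        xbar = p @ ob.X
        hess -= (ob.X * p[:, None]).T @ ob.X - np.outer(xbar, xbar)
    return hess


@dataclass(frozen=True)
class CLFit:
    """Estimated conditional-logit model."""

    attributes: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    cov: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int

    def coef(self, attribute: str) -> float:
        return float(self.beta[self.attributes.index(attribute)])

    def stderr(self, attribute: str) -> float:
        return float(self.se[self.attributes.index(attribute)])


def fit_clogit(
    data: Sequence[ChoiceObservation],
    attributes: Sequence[str] | None = None,
    zscore: bool = False,
    gtol: float = 1e-8,
    lltol: float = 1e-12,
    max_iter: int = 100,
) -> CLFit:
    """Maximum-likelihood conditional-logit fit.

    Newton iteration from beta = 0 with step halving; converges when the
    gradient max-norm drops below ``gtol`` or the relative log-likelihood
    change below ``lltol``.  Standard errors come from the inverse observed
    information.  ``zscore`` rescales each attribute by its pooled standard
    deviation before fitting (coefficients are reported back on the
    original scale).

    Raises
    ------
    SeparationError
        if the likelihood is unbounded (choices perfectly separable).
    NotConvergedError
        if ``max_iter`` Newton steps do not reach tolerance.
    """
    data = list(data)
    if not data:
        raise ValueError("no observations")
    k = data[0].X.shape[1]
    if attributes is None:
        attributes = tuple(f"x{i}" for i in range(k))
    attributes = tuple(attributes)
    if len(attributes) != k:
        raise ValueError(
            f"{len(attributes)} attribute names for {k} attribute columns"
        )

    scale = np.ones(k)
    if zscore:
        stacked = np.vstack([ob.X for ob in data])
        sd = stacked.std(axis=0, ddof=0)
        scale = np.where(sd > 0, sd, 1.0)
        data = [
            ChoiceObservation(ob.chooser_id, ob.X / scale, ob.chosen) for ob in data
        ]

    # identification: at least one attribute must vary within an observation
    varies = np.zeros(k, dtype=bool)
    for ob in data:
        varies |= np.ptp(ob.X, axis=0) > 0
    if not varies.any():
        raise ValueError("no attribute varies across alternatives in any observation")

    beta = np.zeros(k)
    ll = cl_loglik(beta, data)
    ll_null = ll
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = cl_score(beta, data)
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        hess = cl_hessian(beta, data)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            # singular information: fall back to a ridge-damped step
            step = np.linalg.solve(-hess + 1e-8 * np.eye(k), grad)
        # step halving to guarantee ascent
        t = 1.0
        while t > 1e-12:
            ll_new = cl_loglik(beta + t * step, data)
            if ll_new >= ll:
                break
            t /= 2.0
        beta = beta + t * step
        if np.max(np.abs(beta)) > 50.0:
            raise SeparationError(
                "coefficients diverged (|beta| > 50): the chosen alternatives are "
                "perfectly separable and the likelihood has no finite maximum"
            )
        if ll_new - ll <= lltol * (abs(ll) + 1.0):
            ll = ll_new
            grad = cl_score(beta, data)
            converged = bool(np.max(np.abs(grad)) < max(gtol, 1e-6))
            break
        ll = ll_new

    if not converged:
        raise NotConvergedError(
            f"Newton iteration did not converge in {n_iter} steps "
            f"(gradient max-norm {np.max(np.abs(cl_score(beta, data))):.2e})"
        )

    info = -cl_hessian(beta, data)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NotConvergedError(f"observed information is singular: {exc}") from exc
    if np.any(np.diag(cov) <= 0):
        raise NotConvergedError("observed information is not positive definite")

    # undo the z-scoring so coefficients refer to original attribute units
    beta = beta / scale
    cov = cov / np.outer(scale, scale)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return CLFit(
        attributes=attributes,
        beta=beta,
        se=se,
        z=z,
        p=p,
        loglik=float(cl_loglik(beta * scale, data)),
        loglik_null=float(ll_null),
        cov=cov,
        converged=converged,
        n_iter=n_iter,
        n_obs=len(data),
    )


def model_table(fit: CLFit) -> pd.DataFrame:
    """Model output rows (category, attribute, coef, se, z, p).

    Rows are grouped by the audit tool's category headings in their fixed
    order (Roadway features, Streetscape, Pedestrian infrastructure,
    Facilities); attributes outside the audit schema come last.
    """
    if not fit.converged:
        raise NotConvergedError("refusing to tabulate an unconverged fit")

    def sort_key(attr: str) -> tuple[int, int]:
        cat = CATEGORY_OF.get(attr)
        cat_rank = CATEGORY_ORDER.index(cat) if cat in CATEGORY_ORDER else len(CATEGORY_ORDER)
        attr_rank = ATTRIBUTE_FIELDS.index(attr) if attr in ATTRIBUTE_FIELDS else 0
        return (cat_rank, attr_rank)

    order = sorted(range(len(fit.attributes)), key=lambda i: sort_key(fit.attributes[i]))
    rows = []
    for i in order:
        attr = fit.attributes[i]
        cat = CATEGORY_OF.get(attr)
        rows.append(
            {
                "category": CATEGORY_LABELS.get(cat, "Other"),
                "attribute": attr,
                "coef": float(fit.beta[i]),
                "se": float(fit.se[i]),
                "z": float(fit.z[i]),
                "p": float(fit.p[i]),
            }
        )
    return pd.DataFrame(rows, columns=["category", "attribute", "coef", "se", "z", "p"])
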