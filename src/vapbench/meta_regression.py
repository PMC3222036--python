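"""Weighted meta-regression of group-level logit incidence on moderators.

The six standard models contrast benchmark groups (the reference level,
carried by the intercept) with control arms (models 1-3) or intervention
arms (models 4-6) of the prevention studies.  Models 1 and 4 contain series
indicators only; models 2 and 5 add three group-level covariates (mode of
diagnosis, trauma-admission proportion, <90%-ventilated flag); models 3 and
6 repeat the full model restricted to majority-quality prevention studies
(benchmark groups are always retained).

The residual between-group variance tau^2 is estimated by REML (default) or
a method-of-moments extension, then plugged into weights
``w_i = 1 / (v_i + tau^2)``; coefficients are generalized least squares
``(X'WX)^-1 X'Wy`` with covariance ``(X'WX)^-1`` and z-based inference.

Note on scaling: ``trauma_proportion`` enters as a fraction in [0, 1], so a
one-unit change means 0% -> 100% trauma admissions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .group_data import GroupRecord
from .logit_core import logit_proportion
from .random_effects import reml_tau2

__all__ = [
    "ModelSpec",
    "MetaRegressionFit",
    "ContrastResult",
    "standard_model",
    "build_design",
    "fit_meta_regression",
    "run_model",
    "linear_contrast",
    "fit_to_dataframe",
]

logger = logging.getLogger(__name__)

#: Covariates added by the full models, in design-column order.
FULL_MODEL_COVARIATES = ("bronchoscopic_diagnosis", "trauma_proportion", "mv_lt90")

SERIES_TERMS = ("non_antimicrobial", "sdd")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one meta-regression model."""

    model_id: int | str
    arm_scope: str  # "control" or "intervention"
    moderators: tuple[str, ...] = ()
    quality_restricted: bool = False
    tau2_method: str = "reml"

    def __post_init__(self) -> None:
        if self.arm_scope not in ("control", "intervention"):
            raise ValueError(f"arm_scope must be control|intervention, got {self.arm_scope!r}")
        if self.tau2_method not in ("reml", "mm"):
            raise ValueError(f"tau2_method must be reml|mm, got {self.tau2_method!r}")


def standard_model(model_id: int, tau2_method: str = "reml") -> ModelSpec:
    """The spec of one of the six standard models.

    1/4: series indicators only, control/intervention scope.
    2/5: add the three covariates.  3/6: full model, majority-quality only.
    """
    if model_id not in range(1, 7):
        raise ValueError(f"model_id must be 1..6, got {model_id}")
    scope = "control" if model_id <= 3 else "intervention"
    full = model_id in (2, 3, 5, 6)
    return ModelSpec(
        model_id=model_id,
        arm_scope=scope,
        moderators=FULL_MODEL_COVARIATES if full else (),
        quality_restricted=model_id in (3, 6),
        tau2_method=tau2_method,
    )


@dataclass(frozen=True)
class MetaRegressionFit:
    """Coefficients, covariance and residual heterogeneity of one model."""

    beta: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...]
    tau2_resid: float
    k: int
    model: ModelSpec | None = None
    level: float = 0.95

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def ci(self) -> np.ndarray:
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        se = self.se
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def coefficient(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci": self.ci.tolist(),
            "p_values": self.p_values.tolist(),
            "cov": self.cov.tolist(),
            "tau2_resid": self.tau2_resid,
            "k": self.k,
            "level": self.level,
            "model_id": None if self.model is None else self.model.model_id,
            "tau2_method": None if self.model is None else self.model.tau2_method,
        }

    def to_json(self, destination: str | IO[str] | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if destination is not None:
            if hasattr(destination, "write"):
                destination.write(text)
            else:
                with open(destination, "w") as fh:
                    fh.write(text)
        return text


def build_design(
    groups: Sequence[GroupRecord],
    spec: ModelSpec,
    on_missing: str = "drop",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...], list[GroupRecord]]:
    """Response, variance and design matrix for one model.

    Selects benchmark groups plus arms matching ``spec.arm_scope``; under
    ``quality_restricted`` prevention arms additionally require a majority
    quality score while every benchmark group is retained.  The intercept
    column encodes benchmark membership (reference); indicator columns for
    the non-antimicrobial and SDD series follow, then any covariates.

    Groups with a missing value in a required covariate are dropped with a
    logged count (``on_missing="drop"``, default) or rejected with an error
    listing the offending groups (``on_missing="error"``).

    Returns ``(y, v, X, column_names, groups_used)``.
    """
    if on_missing not in ("drop", "error"):
        raise ValueError(f"on_missing must be drop|error, got {on_missing!r}")
    selected = [
        g for g in groups if g.arm_role in ("benchmark", spec.arm_scope)
    ]
    if spec.quality_restricted:
        selected = [
            g for g in selected
            if g.arm_role == "benchmark" or g.quality_majority is True
        ]

    if spec.moderators:
        incomplete = [
            g for g in selected
            if any(getattr(g, m) is None for m in spec.moderators)
        ]
        if incomplete:
            ids = [f"{g.study_id}/{g.arm_role}" for g in incomplete]
            if on_missing == "error":
                raise ValueError(
                    f"missing covariate values in required columns for groups: {ids}"
                )
            logger.warning(
                "dropping %d group(s) with missing covariates: %s",
                len(incomplete), ids,
            )
            selected = [g for g in selected if g not in incomplete]

    # indicator columns only for non-benchmark series actually present, so a
    # two-series subset (e.g. benchmark + SDD controls) stays full rank
    present_series = tuple(
        s for s in SERIES_TERMS if any(g.series == s for g in selected)
    )
    names = ["benchmark_reference"] + [
        f"series_{s}" for s in present_series
    ] + list(spec.moderators)
    rows = []
    y = []
    v = []
    for g in selected:
        est = logit_proportion(g.events, g.denominator)
        y.append(est.logit_value)
        v.append(est.variance)
        row = [1.0]
        for s in present_series:
            row.append(1.0 if g.series == s else 0.0)
        for m in spec.moderators:
            val = getattr(g, m)
            row.append(float(val))
        rows.append(row)
    return (
        np.array(y, dtype=float),
        np.array(v, dtype=float),
        np.array(rows, dtype=float),
        tuple(names),
        selected,
    )


def _mm_tau2(y: np.ndarray, v: np.ndarray, x: np.ndarray) -> float:
    """Method-of-moments residual tau^2 for meta-regression.

    Generalizes the DerSimonian-Laird estimator: with fixed-effect weights
    ``W = diag(1/v)`` and hat-type matrix ``P = W - W X (X'WX)^-1 X'W``,
    ``tau^2 = max(0, (RSS - (k - p)) / tr(P))`` where RSS is the weighted
    residual sum of squares of the fixed-effect fit.
    """
    w = 1.0 / v
    xtwx = x.T @ (x * w[:, None])
    beta = np.linalg.solve(xtwx, x.T @ (w * y))
    resid = y - x @ beta
    rss = float(np.sum(w * resid**2))
    k, p = x.shape
    wx = x * w[:, None]
    trace_p = float(np.sum(w)) - float(np.trace(np.linalg.solve(xtwx, wx.T @ wx)))
    if trace_p <= 0:
        return 0.0
    return max(0.0, (rss - (k - p)) / trace_p)


def fit_meta_regression(
    y: np.ndarray,
    v: np.ndarray,
    design: np.ndarray,
    tau2_method: str = "reml",
    names: Sequence[str] | None = None,
    model: ModelSpec | None = None,
    level: float = 0.95,
) -> MetaRegressionFit:
    """Weighted meta-regression with additive residual heterogeneity.

    Estimates tau^2 (REML profile maximization or method of moments), then
    solves GLS: ``beta = (X'WX)^-1 X'Wy`` with ``W = diag(1/(v_i + tau^2))``
    and ``cov(beta) = (X'WX)^-1``.  Rejects rank-deficient designs, naming
    the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    x = np.atleast_2d(np.asarray(design, dtype=float))
    k, p = x.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    if k < p + 2:
        raise ValueError(f"need at least {p + 2} groups for {p} coefficients, got {k}")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # identify a maximal independent prefix; the rest are collinear
        dependent = []
        for j in range(p):
            if np.linalg.matrix_rank(x[:, : j + 1]) <= np.linalg.matrix_rank(x[:, :j]):
                dependent.append(names[j])
        raise ValueError(f"singular design; collinear columns: {dependent}")
    if tau2_method == "reml":
        tau2 = reml_tau2(y, v, x)
    elif tau2_method == "mm":
        tau2 = _mm_tau2(y, v, x)
    else:
        raise ValueError(f"unknown tau2_method {tau2_method!r}")
    w = 1.0 / (v + tau2)
    xtwx = x.T @ (x * w[:, None])
    cov = np.linalg.inv(xtwx)
    beta = cov @ (x.T @ (w * y))
    cov = 0.5 * (cov + cov.T)  # enforce symmetry against round-off
    return MetaRegressionFit(
        beta=beta, cov=cov, names=tuple(names), tau2_resid=tau2, k=k,
        model=model, level=level,
    )


def run_model(
    groups: Sequence[GroupRecord],
    spec: ModelSpec,
    on_missing: str = "drop",
    level: float = 0.95,
) -> MetaRegressionFit:
    """Build the design for ``spec`` from ``groups`` and fit it."""
    y, v, x, names, _ = build_design(groups, spec, on_missing=on_missing)
    return fit_meta_regression(
        y, v, x, tau2_method=spec.tau2_method, names=names, model=spec, level=level
    )


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    ci: tuple[float, float]
    p: float


def linear_contrast(
    fit: MetaRegressionFit, weights: Sequence[float], level: float = 0.95
) -> ContrastResult:
    """Estimate, CI and two-sided p-value for the combination ``c'beta``.

    A unit vector reproduces the corresponding coefficient's inference; e.g.
    ``(0, -1, +1)`` contrasts the SDD against the non-antimicrobial series.
    """
    c = np.asarray(weights, dtype=float)
    if c.shape != fit.beta.shape:
        raise ValueError(f"contrast length {c.shape} does not match beta {fit.beta.shape}")
    est = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    se = math.sqrt(max(var, 0.0))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(est) / se))
    return ContrastResult(estimate=est, se=se, ci=(est - z * se, est + z * se), p=p)


def fit_to_dataframe(fit: MetaRegressionFit) -> pd.DataFrame:
    """Coefficient table: factor, coefficient, CI bounds, P."""
    ci = fit.ci
    return pd.DataFrame(
        {
            "factor": list(fit.names),
            "coefficient": np.round(fit.beta, 4),
            "ci_low": np.round(ci[:, 0], 4),
            "ci_high": np.round(ci[:, 1], 4),
            "p": fit.p_values,
        }
    )
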