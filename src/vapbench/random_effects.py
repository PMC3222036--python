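"""Random-effects pooling of logit incidence proportions.

Groups are pooled with inverse-variance weights under an additive
between-group variance tau^2 (DerSimonian-Laird method of moments by
default; REML optional).  Besides the pooled mean and its confidence
interval, the module computes Cochran's Q, I^2, and the prediction
interval ``mu +/- z * sqrt(SE^2 + tau^2)`` which describes where the true
incidence of a *new* group is expected to fall — the benchmarking band.

tau^2 is estimated once from the data and plugged into the weights; no
iterative re-estimation of the pooled mean is performed (conventional
two-step practice).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .logit_core import LogitEstimate, invlogit

__all__ = [
    "PooledSummary",
    "cochran_q",
    "dl_tau2",
    "reml_tau2",
    "pool_random_effects",
    "prediction_interval",
    "summaries_to_csv",
]


@dataclass(frozen=True)
class PooledSummary:
    """Random-effects summary of ``k`` groups on the logit and % scales."""

    k: int
    mu_logit: float
    se: float
    tau2: float
    i2: float
    q: float
    ci_logit: tuple[float, float]
    pi_logit: tuple[float, float]
    level: float = 0.95
    tau2_method: str = "dl"
    stratum: str = ""

    @property
    def mean_pct(self) -> float:
        return 100.0 * invlogit(self.mu_logit)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (100.0 * invlogit(self.ci_logit[0]), 100.0 * invlogit(self.ci_logit[1]))

    @property
    def pi_pct(self) -> tuple[float, float]:
        return (100.0 * invlogit(self.pi_logit[0]), 100.0 * invlogit(self.pi_logit[1]))

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "k": self.k,
            "mu_logit": self.mu_logit,
            "se": self.se,
            "tau2": self.tau2,
            "i2": self.i2,
            "q": self.q,
            "level": self.level,
            "tau2_method": self.tau2_method,
            "ci_logit": list(self.ci_logit),
            "pi_logit": list(self.pi_logit),
            "mean_pct": self.mean_pct,
            "ci_pct": list(self.ci_pct),
            "pi_pct": list(self.pi_pct),
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


def _arrays(estimates: Sequence[LogitEstimate]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.logit_value for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    return y, v


def cochran_q(estimates: Sequence[LogitEstimate]) -> tuple[float, int]:
    """Cochran's heterogeneity statistic Q and its degrees of freedom k-1.

    ``Q = sum w_i (y_i - y_FE)^2`` with fixed-effect weights ``w_i = 1/v_i``
    and ``y_FE`` the inverse-variance weighted mean.
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q requires at least 2 groups")
    y, v = _arrays(estimates)
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    return q, len(estimates) - 1


def dl_tau2(estimates: Sequence[LogitEstimate]) -> float:
    """DerSimonian-Laird method-of-moments between-group variance.

    ``tau^2 = max(0, (Q - df) / (S1 - S2/S1))`` with ``S1 = sum w_i`` and
    ``S2 = sum w_i^2``; truncated at zero.
    """
    q, df = cochran_q(estimates)
    _, v = _arrays(estimates)
    w = 1.0 / v
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    denom = s1 - s2 / s1
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def reml_tau2(
    y: np.ndarray,
    v: np.ndarray,
    design: np.ndarray | None = None,
    *,
    max_tau2: float | None = None,
    tol: float = 1e-10,
) -> float:
    """Restricted maximum-likelihood tau^2 for a weighted linear model.

    With ``design`` omitted, an intercept-only model (plain random-effects
    pooling).  The restricted log-likelihood is profiled over tau^2 on a
    bounded interval by scalar minimization; the default upper bound is ten
    times the sample variance of ``y`` (generous for log-odds data).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    x = np.ones((len(y), 1)) if design is None else np.asarray(design, dtype=float)
    if len(y) <= x.shape[1]:
        raise ValueError("REML requires more groups than design columns")
    if max_tau2 is None:
        max_tau2 = max(10.0 * float(np.var(y)), 1.0)

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        xtwx = x.T @ (x * wi[:, None])
        beta = np.linalg.solve(xtwx, x.T @ (wi * y))
        resid = y - x @ beta
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        return 0.5 * (
            -float(np.sum(np.log(wi))) + logdet + float(np.sum(wi * resid**2))
        )

    result = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, max_tau2), method="bounded",
        options={"xatol": tol},
    )
    if not result.success:
        raise RuntimeError(f"REML tau^2 estimation did not converge: {result.message}")
    tau2 = float(result.x)
    # boundary solution: prefer exact zero when the likelihood is flat there
    if tau2 < 10 * tol and neg_restricted_ll(0.0) <= result.fun + tol:
        tau2 = 0.0
    return tau2


def pool_random_effects(
    estimates: Sequence[LogitEstimate],
    level: float = 0.95,
    tau2_method: str = "dl",
    stratum: str = "",
) -> PooledSummary:
    """Random-effects pooled mean, CI, I^2 and prediction interval.

    Weights are ``1 / (v_i + tau^2)``; the confidence interval uses the
    standard-normal quantile for ``level`` (1.96 at 95%), as does the
    prediction interval ``mu +/- z * sqrt(SE^2 + tau^2)``.
    """
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 groups")
    if tau2_method not in ("dl", "reml"):
        raise ValueError(f"unknown tau2_method {tau2_method!r}")
    y, v = _arrays(estimates)
    q, df = cochran_q(estimates)
    if tau2_method == "dl":
        tau2 = dl_tau2(estimates)
    else:
        tau2 = reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    ci = (mu - z * se, mu + z * se)
    pi_half = z * math.sqrt(se**2 + tau2)
    pi = (mu - pi_half, mu + pi_half)
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return PooledSummary(
        k=len(estimates), mu_logit=mu, se=se, tau2=tau2, i2=i2, q=q,
        ci_logit=ci, pi_logit=pi, level=level, tau2_method=tau2_method,
        stratum=stratum,
    )


def prediction_interval(
    summary: PooledSummary, z: float = 1.96
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Prediction interval ``mu +/- z * sqrt(SE^2 + tau^2)``.

    Returns the interval on the logit scale and back-transformed to the
    percentage scale.  ``z`` defaults to the 1.96 multiplier of a 95% band.
    """
    half = z * math.sqrt(summary.se**2 + summary.tau2)
    lo, hi = summary.mu_logit - half, summary.mu_logit + half
    return (lo, hi), (100.0 * invlogit(lo), 100.0 * invlogit(hi))


def summaries_to_csv(
    summaries: Iterable[PooledSummary], destination: str | IO[str]
) -> pd.DataFrame:
    """One-row-per-stratum CSV: mean %, 95% CI, N, SE, tau^2 (+ PI columns)."""
    rows = []
    for s in summaries:
        ci = s.ci_pct
        pi = s.pi_pct
        rows.append(
            {
                "stratum": s.stratum,
                "mean_pct": round(s.mean_pct, 1),
                "ci_low_pct": round(ci[0], 1),
                "ci_high_pct": round(ci[1], 1),
                "n": s.k,
                "se": round(s.se, 4),
                "tau2": round(s.tau2, 4),
                "i2_pct": round(s.i2, 1),
                "pi_low_pct": round(pi[0], 1),
                "pi_high_pct": round(pi[1], 1),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(destination, index=False)
    return frame
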