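"""Logit transformation of incidence proportions.

The incidence proportion of a patient group with ``N`` events among ``D``
patients is analysed on the log-odds scale: ``logit = log(N / (D - N))``
with large-sample sampling variance ``1 / (D * R * (1 - R))`` where
``R = N / D``.  Boundary counts (``N == 0`` or ``N == D``) receive an
empirical-logit continuity correction (``N + 0.5`` over ``D + 1``) and are
flagged via :attr:`LogitEstimate.corrected`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import special, stats

__all__ = ["LogitEstimate", "logit_proportion", "logit", "invlogit", "group_ci"]


@dataclass(frozen=True)
class LogitEstimate:
    """A group's logit incidence proportion and its sampling variance."""

    logit_value: float
    variance: float
    source_events: int
    source_denominator: int
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def proportion(self) -> float:
        """Back-transformed point estimate in (0, 1)."""
        return invlogit(self.logit_value)


def logit(p: float) -> float:
    """Log-odds of a proportion ``p`` in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"proportion must lie strictly in (0, 1), got {p}")
    return float(special.logit(p))


def invlogit(x: float) -> float:
    """Inverse logit ``1 / (1 + exp(-x))``; strictly increasing."""
    return float(special.expit(x))


def logit_proportion(events: int, denominator: int) -> LogitEstimate:
    """Empirical logit and sampling variance for ``events`` out of ``denominator``.

    Interior counts use ``log(N/(D-N))`` and ``1/(D*R*(1-R))`` directly.  For
    ``N == 0`` or ``N == D`` the continuity correction replaces ``N`` by
    ``N + 0.5`` and ``D`` by ``D + 1`` in both formulas and sets
    ``corrected=True``.
    """
    if denominator < 1:
        raise ValueError(f"denominator must be >= 1, got {denominator}")
    if not 0 <= events <= denominator:
        raise ValueError(
            f"events must lie in [0, denominator], got {events}/{denominator}"
        )
    n, d = float(events), float(denominator)
    corrected = events == 0 or events == denominator
    if corrected:
        n += 0.5
        d += 1.0
    r = n / d
    value = math.log(n / (d - n))
    variance = 1.0 / (d * r * (1.0 - r))
    return LogitEstimate(
        logit_value=value,
        variance=variance,
        source_events=int(events),
        source_denominator=int(denominator),
        corrected=corrected,
    )


def group_ci(estimate: LogitEstimate, level: float = 0.95) -> tuple[float, float]:
    """Back-transformed confidence interval for a single group's proportion.

    Normal interval on the logit scale, ``logit +/- z * sqrt(variance)``,
    mapped through the inverse logit.  Endpoints are returned ordered.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(estimate.variance)
    lo = invlogit(estimate.logit_value - half)
    hi = invlogit(estimate.logit_value + half)
    return (lo, hi)
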