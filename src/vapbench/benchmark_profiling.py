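"""Profiling component groups against the benchmark prediction band.

Given the 95% prediction interval of the benchmark incidence distribution,
each control or intervention group is classified by whether its raw
incidence percentage falls above, within or below the band.  Because only
2.5% of a well-behaved population should exceed the upper limit, an excess
of above-band groups implies unreported ("missing") groups; the
publication-deficit estimator quantifies that implied shortfall.  A
ventilation-equivalence diagnostic converts a percentage-point incidence
gap into the equivalent difference in mean days of ventilation, and a skew
indicator contrasts the median of raw group percentages with the pooled
mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .group_data import GroupRecord, filter_groups
from .logit_core import logit_proportion
from .random_effects import PooledSummary, pool_random_effects

__all__ = [
    "ProfileReport",
    "classify_vs_band",
    "publication_deficit",
    "ventilation_equivalent",
    "stratum_summaries",
    "skew_indicator",
]

logger = logging.getLogger(__name__)

#: Default strata, mirroring the summary-table layout:
#: (series, arm_role) pairs for the benchmark and the four prevention strata.
DEFAULT_STRATA = (
    ("benchmark", "benchmark"),
    ("non_antimicrobial", "control"),
    ("non_antimicrobial", "intervention"),
    ("sdd", "control"),
    ("sdd", "intervention"),
)


@dataclass(frozen=True)
class ProfileReport:
    """Classification of groups against a percentage-scale prediction band."""

    band: tuple[float, float]
    per_group: tuple[tuple[str, float, str], ...]  # (group id, VAP-IP %, class)
    n_above: int
    n_within: int
    n_below: int
    deficit: float
    stratum: str = ""

    @property
    def n_total(self) -> int:
        return self.n_above + self.n_within + self.n_below

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "band_pct": list(self.band),
            "n_above": self.n_above,
            "n_within": self.n_within,
            "n_below": self.n_below,
            "deficit": self.deficit,
            "per_group": [
                {"group": gid, "vap_pct": pct, "classification": cls}
                for gid, pct, cls in self.per_group
            ],
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

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.per_group), columns=["group", "vap_pct", "classification"]
        )


def classify_vs_band(
    groups: Sequence[GroupRecord],
    band: tuple[float, float],
    stratum: str = "",
) -> ProfileReport:
    """Classify each group's raw incidence percentage against ``band``.

    The comparison uses the raw point estimate ``100 * N / D`` (not the
    group's confidence interval).  A value exactly equal to a band endpoint
    counts as "within" — conservative for outlier claims.  The report
    includes the publication-deficit estimate derived from the above/not-
    above split.
    """
    lo, hi = band
    if not (0.0 < lo < hi < 100.0):
        raise ValueError(f"band endpoints must be ordered and in (0, 100), got {band}")
    per_group = []
    for g in groups:
        pct = g.vap_pct
        if pct > hi:
            cls = "above"
        elif pct < lo:
            cls = "below"
        else:
            cls = "within"
        label = g.group_label or f"{g.study_id}/{g.arm_role}"
        per_group.append((label, pct, cls))
    n_above = sum(1 for _, _, c in per_group if c == "above")
    n_below = sum(1 for _, _, c in per_group if c == "below")
    n_within = len(per_group) - n_above - n_below
    return ProfileReport(
        band=(lo, hi),
        per_group=tuple(per_group),
        n_above=n_above,
        n_within=n_within,
        n_below=n_below,
        deficit=publication_deficit(n_above, len(per_group) - n_above),
        stratum=stratum,
    )


def publication_deficit(n_above: int, n_not_above: int) -> float:
    """Implied count of unreported groups below the band's upper limit.

    Only 2.5% of a well-behaved population lies above the upper limit of a
    95% prediction interval, so ``n_above`` observed outliers imply
    ``n_above * 97.5 / 2.5`` inliers; the deficit is that count minus the
    ``n_not_above`` groups actually observed at or below the limit.
    """
    if n_above < 0 or n_not_above < 0:
        raise ValueError("counts must be non-negative")
    return n_above * (97.5 / 2.5) - n_not_above


def ventilation_equivalent(delta_pp: float, risk_per_day: float = 2.0) -> float:
    """Days of extra ventilation equivalent to an incidence-percentage gap.

    Duration of mechanical ventilation is the strongest patient-level VAP
    risk factor, adding roughly 2 cases per 100 patients per ventilated day
    in the second week.  A gap of ``delta_pp`` percentage points therefore
    corresponds to ``delta_pp / risk_per_day`` days of mean ventilation.
    """
    if risk_per_day <= 0:
        raise ValueError(f"risk_per_day must be positive, got {risk_per_day}")
    return delta_pp / risk_per_day


def stratum_summaries(
    groups: Sequence[GroupRecord],
    strata: Iterable[tuple[str, str]] = DEFAULT_STRATA,
    quality_restricted: bool = False,
    level: float = 0.95,
    tau2_method: str = "dl",
) -> list[PooledSummary]:
    """Random-effects summary per (series, arm_role) stratum.

    Under ``quality_restricted``, prevention arms require a majority quality
    score while benchmark groups are always retained in full.  Strata with
    fewer than 2 groups are skipped with a logged warning.
    """
    pool = list(groups)
    if quality_restricted:
        pool = filter_groups(pool, {"quality_only": True})
    summaries = []
    for series, arm_role in strata:
        members = filter_groups(pool, {"series": series, "arm_role": arm_role})
        name = f"{series}/{arm_role}" + ("/quality" if quality_restricted else "")
        if len(members) < 2:
            logger.warning("stratum %s has %d group(s); skipped", name, len(members))
            continue
        estimates = [logit_proportion(g.events, g.denominator) for g in members]
        summaries.append(
            pool_random_effects(
                estimates, level=level, tau2_method=tau2_method, stratum=name
            )
        )
    return summaries


def skew_indicator(
    groups: Sequence[GroupRecord], summary: PooledSummary
) -> tuple[float, float, float]:
    """Median raw percentage, pooled mean percentage, and their difference.

    A median several points above the back-transformed pooled mean signals
    positive skew in the group-level incidence distribution (as produced,
    for example, by selective non-reporting of low-incidence groups).
    """
    if not groups:
        raise ValueError("skew_indicator requires at least one group")
    median_pct = float(np.median([g.vap_pct for g in groups]))
    mean_pct = summary.mean_pct
    return median_pct, mean_pct, median_pct - mean_pct
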