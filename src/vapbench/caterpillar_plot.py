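"""Rank-ordered caterpillar (forest-style) plots of group incidences.

Groups are listed in rank order of increasing incidence, each with its
point estimate and 95% CI, drawn on a logit-scaled x axis with percentage
tick labels.  The pooled mean is a vertical line, the pooled CI a diamond,
and the benchmark prediction interval a horizontal band line, so the
symmetry of the group results and their deviation from the benchmark are
visible at a glance.

Ties in the point estimate are broken by CI width ascending (a proxy for
the sampling variance) and then label, so the ordering is total and the
rendering deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .group_data import GroupRecord
from .logit_core import group_ci, logit, logit_proportion
from .random_effects import PooledSummary

__all__ = ["PlotSpec", "make_plot_spec", "render_caterpillar"]

#: Default percentage tick positions on the logit axis.
DEFAULT_TICKS_PCT = (5.0, 10.0, 20.0, 30.0, 50.0, 70.0, 90.0)


@dataclass(frozen=True)
class PlotSpec:
    """Everything needed to render one caterpillar plot.

    ``groups`` holds (label, estimate %, CI low %, CI high %) tuples;
    annotations (duplex ``*``, non-concurrent ``NC``) are already folded
    into the labels.  ``summary`` carries the pooled mean/CI as percentages,
    ``band`` the benchmark prediction interval as percentages.
    """

    groups: tuple[tuple[str, float, float, float], ...]
    summary: tuple[float, float, float] | None = None  # (mean, ci_lo, ci_hi) %
    band: tuple[float, float] | None = None  # prediction interval %
    title: str = ""
    ticks_pct: tuple[float, ...] = DEFAULT_TICKS_PCT

    def sorted_groups(self) -> list[tuple[str, float, float, float]]:
        """Ascending by estimate, then CI width, then label."""
        return sorted(self.groups, key=lambda g: (g[1], g[3] - g[2], g[0]))

    def to_json(self, destination: str | IO[str] | None = None) -> str:
        payload = {
            "groups": [list(g) for g in self.groups],
            "summary": None if self.summary is None else list(self.summary),
            "band": None if self.band is None else list(self.band),
            "title": self.title,
            "ticks_pct": list(self.ticks_pct),
        }
        text = json.dumps(payload, indent=2)
        if destination is not None:
            if hasattr(destination, "write"):
                destination.write(text)
            else:
                with open(destination, "w") as fh:
                    fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str | IO[str]) -> "PlotSpec":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            groups=tuple(tuple(g) for g in payload["groups"]),
            summary=None if payload["summary"] is None else tuple(payload["summary"]),
            band=None if payload["band"] is None else tuple(payload["band"]),
            title=payload.get("title", ""),
            ticks_pct=tuple(payload.get("ticks_pct", DEFAULT_TICKS_PCT)),
        )


def make_plot_spec(
    groups: Sequence[GroupRecord],
    summary: PooledSummary | None = None,
    band: tuple[float, float] | None = None,
    title: str = "",
    level: float = 0.95,
) -> PlotSpec:
    """Build a :class:`PlotSpec` from arm-level records.

    Duplex arms (control patients routinely on systemic antibiotics) get a
    ``*`` suffix on the label; non-concurrent arms get ``NC``.
    """
    if not groups:
        raise ValueError("caterpillar plot requires at least one group")
    rows = []
    for g in groups:
        est = logit_proportion(g.events, g.denominator)
        lo, hi = group_ci(est, level=level)
        label = g.group_label or g.study_id
        if g.duplex:
            label += " *"
        if not g.concurrent:
            label += " NC"
        rows.append((label, 100.0 * est.proportion, 100.0 * lo, 100.0 * hi))
    summary_tuple = None
    if summary is not None:
        ci = summary.ci_pct
        summary_tuple = (summary.mean_pct, ci[0], ci[1])
    return PlotSpec(groups=tuple(rows), summary=summary_tuple, band=band, title=title)


def _to_logit(pct: float) -> float:
    return logit(min(max(pct / 100.0, 1e-6), 1 - 1e-6))


def render_caterpillar(
    spec: PlotSpec, destination: str, fmt: str = "svg"
) -> str:
    """Render ``spec`` to ``destination`` as SVG (default) or PNG.

    Rendering is deterministic: an identical spec yields a byte-identical
    SVG file.  Zero-width CIs are drawn as points.
    """
    if fmt not in ("svg", "png"):
        raise ValueError(f"format must be svg|png, got {fmt!r}")
    ordered = spec.sorted_groups()
    n = len(ordered)
    with plt.rc_context({"svg.hashsalt": "vapbench"}):
        fig, ax = plt.subplots(figsize=(7.0, max(3.0, 0.28 * n + 1.8)))
        for i, (label, est, lo, hi) in enumerate(ordered):
            y = i + 1
            if hi > lo:
                ax.plot(
                    [_to_logit(lo), _to_logit(hi)], [y, y],
                    color="0.35", lw=1.0, zorder=2,
                )
            ax.plot(
                [_to_logit(est)], [y], marker="D", ms=4,
                color="tab:blue", zorder=3,
            )
        if spec.band is not None:
            blo, bhi = spec.band
            ax.plot(
                [_to_logit(blo), _to_logit(bhi)], [0.0, 0.0],
                color="tab:green", lw=2.5, solid_capstyle="butt", zorder=2,
                label="benchmark 95% prediction interval",
            )
        if spec.summary is not None:
            mean, ci_lo, ci_hi = spec.summary
            ax.axvline(
                _to_logit(mean), color="tab:green", ls=":", lw=1.2, zorder=1,
                label="pooled mean",
            )
            ax.plot(
                [_to_logit(ci_lo), _to_logit(mean), _to_logit(ci_hi), _to_logit(mean),
                 _to_logit(ci_lo)],
                [0.0, 0.35, 0.0, -0.35, 0.0],
                color="tab:green", lw=1.0, zorder=3,
            )
        ax.set_yticks(range(1, n + 1))
        ax.set_yticklabels([g[0] for g in ordered], fontsize=7)
        ax.set_ylim(-1.0, n + 1)
        ax.set_xticks([_to_logit(t) for t in spec.ticks_pct])
        ax.set_xticklabels([f"{t:g}" for t in spec.ticks_pct])
        ax.set_xlabel("VAP incidence proportion (%), logit scale")
        if spec.title:
            ax.set_title(spec.title)
        fig.tight_layout()
        save_kwargs = {"metadata": {"Date": None}} if fmt == "svg" else {}
        try:
            fig.savefig(destination, format=fmt, **save_kwargs)
        except OSError as exc:
            raise OSError(f"cannot write plot to {destination!r}: {exc}") from exc
        finally:
            plt.close(fig)
    return destination
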