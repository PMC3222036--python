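"""Domain types, tabular I/O and filtering for arm-level incidence data.

The unit of analysis is the component patient group (one study arm): an
observational *benchmark* group, or a *control* / *intervention* arm of a
prevention study.  Arms of multi-arm studies are independent rows that share
a ``study_id``; no within-study correlation is modelled.

Exchange format is UTF-8 CSV with a mandatory header row; missing covariate
values are empty cells.  A JSON schema describing the columns ships with the
package (``vapbench/schemas/groups_schema.json``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARM_ROLES",
    "SERIES",
    "GroupRecord",
    "read_groups",
    "write_groups",
    "filter_groups",
    "summarize_characteristics",
]

ARM_ROLES = ("benchmark", "control", "intervention")
SERIES = ("benchmark", "sdd", "non_antimicrobial")

#: CSV column order; every field of :class:`GroupRecord`.
COLUMNS = (
    "study_id",
    "group_label",
    "arm_role",
    "series",
    "events",
    "denominator",
    "bronchoscopic_diagnosis",
    "trauma_proportion",
    "mv_lt90",
    "quality_majority",
    "duplex",
    "concurrent",
    "european",
    "publication_year",
    "source_review",
)


@dataclass(frozen=True)
class GroupRecord:
    """One study arm: counts, role, series and group-level covariates.

    ``events``/``denominator`` are the VAP count N and the number of
    ventilated patients D; the incidence proportion is ``N / D``.  Optional
    covariates are ``None`` when unknown — missingness is preserved, never
    imputed.
    """

    study_id: str
    arm_role: str
    series: str
    events: int
    denominator: int
    group_label: str = ""
    bronchoscopic_diagnosis: bool | None = None
    trauma_proportion: float | None = None
    mv_lt90: bool | None = None
    quality_majority: bool | None = None
    duplex: bool = False
    concurrent: bool = True
    european: bool | None = None
    publication_year: int | None = None
    source_review: str = ""

    def __post_init__(self) -> None:
        if self.arm_role not in ARM_ROLES:
            raise ValueError(f"unknown arm_role {self.arm_role!r}")
        if self.series not in SERIES:
            raise ValueError(f"unknown series {self.series!r}")
        if (self.arm_role == "benchmark") != (self.series == "benchmark"):
            raise ValueError(
                f"arm_role 'benchmark' and series 'benchmark' must coincide "
                f"(got arm_role={self.arm_role!r}, series={self.series!r})"
            )
        if self.denominator < 1:
            raise ValueError(f"denominator must be >= 1, got {self.denominator}")
        if not 0 <= self.events <= self.denominator:
            raise ValueError(
                f"events must lie in [0, denominator], "
                f"got {self.events}/{self.denominator}"
            )
        if self.trauma_proportion is not None and not (
            0.0 <= self.trauma_proportion <= 1.0
        ):
            raise ValueError(
                f"trauma_proportion must lie in [0, 1], got {self.trauma_proportion}"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.denominator

    @property
    def vap_pct(self) -> float:
        """Raw incidence proportion per 100 patients."""
        return 100.0 * self.events / self.denominator


_BOOL_TOKENS = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(value: object, column: str, row_id: str) -> bool | None:
    if value is None:
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token == "":
        return None
    if token not in _BOOL_TOKENS:
        raise ValueError(f"row {row_id}: cannot parse boolean {value!r} in {column}")
    return _BOOL_TOKENS[token]


def _parse_int(value: object, column: str, row_id: str) -> int:
    f = float(value)
    if not float(f).is_integer():
        raise ValueError(f"row {row_id}: non-integer {column} value {value!r}")
    return int(f)


def read_groups(
    source: str | IO[str],
    schema: Mapping[str, str] | None = None,
) -> list[GroupRecord]:
    """Read arm-level records from a delimited table.

    Parameters
    ----------
    source
        Path or open text stream of a CSV table with a header row.
    schema
        Optional mapping from canonical column names (``study_id``,
        ``events``, ...) to the names used in the file.

    The table must provide at least ``study_id``, ``arm_role``, ``series``,
    ``events`` and ``denominator``.  A row violating an invariant (events
    exceeding the denominator, fractional counts, unknown enum values) is
    rejected with an error naming the row.
    """
    rename = {v: k for k, v in (schema or {}).items()}
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    frame = frame.rename(columns=rename)
    required = ("study_id", "arm_role", "series", "events", "denominator")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    records: list[GroupRecord] = []
    for idx, row in frame.iterrows():
        row_id = str(row.get("study_id", "")) or f"#{idx}"

        def get(col: str) -> str | None:
            val = row.get(col)
            if val is None or str(val).strip() == "":
                return None
            return str(val).strip()

        try:
            trauma = get("trauma_proportion")
            year = get("publication_year")
            record = GroupRecord(
                study_id=str(row["study_id"]).strip(),
                group_label=get("group_label") or "",
                arm_role=str(row["arm_role"]).strip(),
                series=str(row["series"]).strip(),
                events=_parse_int(row["events"], "events", row_id),
                denominator=_parse_int(row["denominator"], "denominator", row_id),
                bronchoscopic_diagnosis=_parse_bool(
                    get("bronchoscopic_diagnosis"), "bronchoscopic_diagnosis", row_id
                ),
                trauma_proportion=None if trauma is None else float(trauma),
                mv_lt90=_parse_bool(get("mv_lt90"), "mv_lt90", row_id),
                quality_majority=_parse_bool(
                    get("quality_majority"), "quality_majority", row_id
                ),
                duplex=_parse_bool(get("duplex"), "duplex", row_id) or False,
                concurrent=(
                    parsed
                    if (parsed := _parse_bool(get("concurrent"), "concurrent", row_id))
                    is not None
                    else True
                ),
                european=_parse_bool(get("european"), "european", row_id),
                publication_year=None if year is None else _parse_int(
                    year, "publication_year", row_id
                ),
                source_review=get("source_review") or "",
            )
        except ValueError as exc:
            if str(exc).startswith("row "):
                raise
            raise ValueError(f"row {row_id}: {exc}") from exc
        records.append(record)
    return records


def write_groups(groups: Iterable[GroupRecord], destination: str | IO[str]) -> None:
    """Write records as CSV; missing values become empty cells.

    Round-trips bit-for-bit through :func:`read_groups` for integer and
    boolean fields and to full precision for fractions (``repr`` formatting).
    """
    rows = []
    for g in groups:
        d = dataclasses.asdict(g)
        row = {}
        for col in COLUMNS:
            val = d[col]
            if val is None:
                row[col] = ""
            elif isinstance(val, bool):
                row[col] = "true" if val else "false"
            elif isinstance(val, float):
                row[col] = repr(val)
            else:
                row[col] = str(val)
        rows.append(row)
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(destination, index=False)


# Named predicates beyond plain field equality.  "quality_only" keeps
# majority-quality prevention arms (benchmark arms are always retained, as in
# the quality-restricted strata where all 45 benchmark groups appear).
_NAMED_CRITERIA: dict[str, Callable[[GroupRecord], bool]] = {
    "quality_only": lambda g: g.arm_role == "benchmark" or g.quality_majority is True,
    "exclude_mv_lt90_or_unknown": lambda g: g.mv_lt90 is False,
    "exclude_duplex": lambda g: not g.duplex,
    "concurrent_only": lambda g: g.concurrent,
}

_FIELD_NAMES = frozenset(f.name for f in dataclasses.fields(GroupRecord))


def filter_groups(
    groups: Sequence[GroupRecord],
    criteria: Mapping[str, object] | None = None,
) -> list[GroupRecord]:
    """Order-preserving subset of ``groups`` satisfying every criterion.

    ``criteria`` maps either a :class:`GroupRecord` field name to a required
    value (scalar equality, a set for membership, or a one-argument predicate
    on the field value), or one of the named criteria ``quality_only``,
    ``exclude_mv_lt90_or_unknown`` (drops arms where the <90%-ventilated flag
    is true *or unknown*), ``exclude_duplex``, ``concurrent_only`` to
    ``True``.  Empty criteria are the identity.  Criteria compose:
    filtering by ``c1 ∧ c2`` equals filtering by ``c1`` then ``c2``.
    """
    if not criteria:
        return list(groups)
    predicates: list[Callable[[GroupRecord], bool]] = []
    for key, want in criteria.items():
        if key in _NAMED_CRITERIA:
            if want:
                predicates.append(_NAMED_CRITERIA[key])
            continue
        if key not in _FIELD_NAMES:
            raise KeyError(f"unknown filter criterion {key!r}")
        if callable(want):
            predicates.append(
                lambda g, k=key, fn=want: bool(fn(getattr(g, k)))
            )
        elif isinstance(want, (set, frozenset, list, tuple)):
            predicates.append(lambda g, k=key, w=frozenset(want): getattr(g, k) in w)
        else:
            predicates.append(lambda g, k=key, w=want: getattr(g, k) == w)
    return [g for g in groups if all(p(g) for p in predicates)]


def summarize_characteristics(groups: Sequence[GroupRecord]) -> pd.DataFrame:
    """Stratified descriptive table, one row per non-empty (series, arm_role).

    Reports the group count, median and IQR of denominators, median and IQR
    of raw incidence percentages, and counts of bronchoscopic-diagnosis and
    <90%-ventilated groups.  Quartiles use linear interpolation between order
    statistics (numpy's default, the "type 7" rule).  Empty strata are
    absent from the table, not zero-filled.
    """
    rows = []
    for series in SERIES:
        for arm_role in ARM_ROLES:
            members = [g for g in groups if g.series == series and g.arm_role == arm_role]
            if not members:
                continue
            denoms = np.array([g.denominator for g in members], dtype=float)
            pcts = np.array([g.vap_pct for g in members])
            rows.append(
                {
                    "series": series,
                    "arm_role": arm_role,
                    "n_groups": len(members),
                    "denominator_median": float(np.median(denoms)),
                    "denominator_q1": float(np.percentile(denoms, 25)),
                    "denominator_q3": float(np.percentile(denoms, 75)),
                    "vap_pct_median": float(np.median(pcts)),
                    "vap_pct_q1": float(np.percentile(pcts, 25)),
                    "vap_pct_q3": float(np.percentile(pcts, 75)),
                    "n_bronchoscopic": sum(
                        1 for g in members if g.bronchoscopic_diagnosis is True
                    ),
                    "n_mv_lt90": sum(1 for g in members if g.mv_lt90 is True),
                }
            )
    if not rows:
        raise ValueError("no groups to summarize")
    return pd.DataFrame(rows).set_index(["series", "arm_role"])
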