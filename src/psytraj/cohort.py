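"""Core cohort data types, validation, long-format file I/O and monthly-to-annual
aggregation.

The observational unit is a subject followed from first presentation, with a
month-by-month record of whether psychotic symptoms were present, absent, or
could not be rated (missing).  The analysis outcome is the number of months
with symptoms present per follow-up year, on a 0--12 scale, with partially
rated years rescaled to a 12-month basis and years with insufficient
information treated as missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Status",
    "MonthlyTimeline",
    "AnnualSeries",
    "BaselineRecord",
    "OutcomeRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "read_cohort_bundle",
    "write_cohort_bundle",
    "aggregate_to_annual",
    "aggregate_cohort",
    "annual_matrix",
]


class Status(IntEnum):
    """Monthly symptom rating."""

    ABSENT = 0
    PRESENT = 1
    MISSING = -1


#: single-letter file codes for the three ratings
STATUS_TO_CODE = {Status.PRESENT: "P", Status.ABSENT: "A", Status.MISSING: "M"}
CODE_TO_STATUS = {v: k for k, v in STATUS_TO_CODE.items()}

CENTRES = ("London", "Nottingham")
ETHNICITIES = ("white_british", "black_caribbean", "other")
EDUCATION_LEVELS = ("no_qualifications", "school", "university")
IQ_QUARTILES = ("q1_lowest", "q2", "q3", "q4_highest")
DIAGNOSES = ("affective", "non_affective")
MODES_OF_ONSET = ("acute", "insidious")


@dataclass
class MonthlyTimeline:
    """Month-indexed symptom status sequence for one subject.

    Months are 0-based from first presentation; the pre-presentation period is
    not represented.
    """

    subject_id: str
    statuses: np.ndarray

    def __post_init__(self) -> None:
        self.statuses = np.asarray(self.statuses, dtype=np.int8)
        if self.statuses.ndim != 1 or self.statuses.size == 0:
            raise ValueError(
                f"subject {self.subject_id!r}: statuses must be a non-empty 1-d sequence"
            )
        valid = np.isin(self.statuses, [int(s) for s in Status])
        if not valid.all():
            bad = int(np.argmin(valid))
            raise ValueError(
                f"subject {self.subject_id!r}: invalid status code "
                f"{self.statuses[bad]} at month {bad}"
            )

    @property
    def followup_months(self) -> int:
        return int(self.statuses.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MonthlyTimeline):
            return NotImplemented
        return self.subject_id == other.subject_id and np.array_equal(
            self.statuses, other.statuses
        )


@dataclass
class AnnualSeries:
    """Months symptomatic per year, ``y[t-1]`` for years t = 1..T.

    Observed entries lie in [0, 12]; missing years are NaN.
    """

    subject_id: str
    y: np.ndarray
    T: int = 10

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.T,):
            raise ValueError(
                f"subject {self.subject_id!r}: y must have length T={self.T}"
            )
        obs = self.y[~np.isnan(self.y)]
        if obs.size and (obs.min() < 0.0 or obs.max() > 12.0):
            raise ValueError(
                f"subject {self.subject_id!r}: observed annual values must lie in [0, 12]"
            )

    @property
    def n_observed(self) -> int:
        return int((~np.isnan(self.y)).sum())


@dataclass
class BaselineRecord:
    """Baseline socio-demographic and clinical characteristics."""

    subject_id: str
    centre: str
    sex: str  # "male" / "female"
    age_at_onset: float
    ethnicity: str
    education: str
    disadvantage_index: int
    premorbid_iq_quartile: str
    diagnosis: str
    dup_months: float
    mode_of_onset: str

    def __post_init__(self) -> None:
        if self.disadvantage_index not in (0, 1, 2, 3, 4):
            raise ValueError(
                f"subject {self.subject_id!r}: disadvantage_index must be in 0..4, "
                f"got {self.disadvantage_index}"
            )
        if self.dup_months < 0:
            raise ValueError(
                f"subject {self.subject_id!r}: dup_months must be >= 0"
            )


@dataclass
class OutcomeRecord:
    """Follow-up functional and social outcomes; NaN / None encode missing."""

    subject_id: str
    gaf_d: float = float("nan")
    in_relationship: bool | None = None
    employed: bool | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.gaf_d) and not (1.0 <= self.gaf_d <= 100.0):
            raise ValueError(
                f"subject {self.subject_id!r}: gaf_d must lie in [1, 100] when observed"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OutcomeRecord):
            return NotImplemented

        def _g(a, b):
            return (np.isnan(a) and np.isnan(b)) or a == b

        return (
            self.subject_id == other.subject_id
            and _g(self.gaf_d, other.gaf_d)
            and self.in_relationship == other.in_relationship
            and self.employed == other.employed
        )


@dataclass
class Cohort:
    """Joined timelines, baseline and outcome records, keyed by subject_id."""

    timelines: dict[str, MonthlyTimeline] = field(default_factory=dict)
    baselines: dict[str, BaselineRecord] = field(default_factory=dict)
    outcomes: dict[str, OutcomeRecord] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.timelines)

    @property
    def n_subjects(self) -> int:
        return len(self.timelines)

    def baseline_frame(self) -> pd.DataFrame:
        rows = [asdict(self.baselines[s]) for s in self.subject_ids if s in self.baselines]
        return pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame()

    def outcome_frame(self) -> pd.DataFrame:
        rows = [asdict(self.outcomes[s]) for s in self.subject_ids if s in self.outcomes]
        return pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_to_annual(tl: MonthlyTimeline, T: int = 10) -> AnnualSeries:
    """Aggregate a monthly timeline to months-symptomatic-per-year over T years.

    Year t (1-based) covers months 12(t-1)..12t-1.  Months beyond the
    follow-up horizon count as unrated.  A year with more than 6 unrated
    months is missing; otherwise the observed present fraction is rescaled to
    a 12-month basis: ``y_t = 12 * n_present / n_observed``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    y = np.full(T, np.nan)
    s = tl.statuses
    for t in range(1, T + 1):
        chunk = s[12 * (t - 1): 12 * t]
        n_missing = 12 - chunk.size + int((chunk == Status.MISSING).sum())
        if n_missing > 6:
            continue
        n_obs = 12 - n_missing
        n_present = int((chunk == Status.PRESENT).sum())
        y[t - 1] = 12.0 * n_present / n_obs
    return AnnualSeries(subject_id=tl.subject_id, y=y, T=T)


def aggregate_cohort(cohort: Cohort, T: int = 10) -> list[AnnualSeries]:
    """Aggregate every timeline; drop subjects with no observed year."""
    out = []
    for sid in cohort.subject_ids:
        ann = aggregate_to_annual(cohort.timelines[sid], T=T)
        if ann.n_observed == 0:
            logger.warning("subject %r has no observed year; excluded from analysis", sid)
            continue
        out.append(ann)
    return out


def annual_matrix(series: Sequence[AnnualSeries]) -> tuple[list[str], np.ndarray]:
    """Stack annual series into an (ids, n x T NaN-coded matrix) pair."""
    if not series:
        raise ValueError("empty collection of annual series")
    T = series[0].T
    if any(s.T != T for s in series):
        raise ValueError("annual series have inconsistent horizons")
    ids = [s.subject_id for s in series]
    Y = np.vstack([s.y for s in series])
    return ids, Y


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_BOOL_TO_STR = {True: "1", False: "0", None: ""}


def _bool_from_field(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return bool(int(v))


def read_cohort(
    timeline_path: str | Path,
    baseline_path: str | Path,
    outcome_path: str | Path,
) -> Cohort:
    """Read a cohort from three delimited long-format files.

    Subjects present in the baseline or outcome tables but absent from the
    timeline table are excluded (and logged), mirroring the inclusion of only
    subjects with a completed symptom timeline.
    """
    tl_df = pd.read_csv(timeline_path, dtype={"subject_id": str})
    required = {"subject_id", "month", "status"}
    if not required.issubset(tl_df.columns):
        raise ValueError(f"timeline file must have columns {sorted(required)}")

    dup = tl_df.duplicated(subset=["subject_id", "month"])
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        row = tl_df.iloc[i]
        raise ValueError(
            f"duplicate (subject, month) at row {i}: "
            f"subject {row['subject_id']!r} month {row['month']}"
        )
    bad = ~tl_df["status"].isin(CODE_TO_STATUS)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        row = tl_df.iloc[i]
        raise ValueError(
            f"unknown status code {row['status']!r} at row {i} "
            f"(subject {row['subject_id']!r}, month {row['month']})"
        )

    timelines: dict[str, MonthlyTimeline] = {}
    for sid, grp in tl_df.groupby("subject_id", sort=False):
        months = grp["month"].to_numpy(dtype=int)
        order = np.argsort(months)
        months = months[order]
        if months[0] != 0 or not np.array_equal(months, np.arange(months.size)):
            raise ValueError(
                f"subject {sid!r}: months must be contiguous starting at 0"
            )
        codes = grp["status"].to_numpy()[order]
        statuses = np.array([int(CODE_TO_STATUS[c]) for c in codes], dtype=np.int8)
        timelines[str(sid)] = MonthlyTimeline(subject_id=str(sid), statuses=statuses)

    cohort = Cohort(timelines=timelines)

    bl_df = pd.read_csv(baseline_path, dtype={"subject_id": str}, float_precision="round_trip")
    for _, row in bl_df.iterrows():
        sid = str(row["subject_id"])
        if sid not in timelines:
            logger.warning("baseline subject %r has no timeline; excluded", sid)
            continue
        cohort.baselines[sid] = BaselineRecord(
            subject_id=sid,
            centre=row["centre"],
            sex=row["sex"],
            age_at_onset=float(row["age_at_onset"]),
            ethnicity=row["ethnicity"],
            education=row["education"],
            disadvantage_index=int(row["disadvantage_index"]),
            premorbid_iq_quartile=row["premorbid_iq_quartile"],
            diagnosis=row["diagnosis"],
            dup_months=float(row["dup_months"]),
            mode_of_onset=row["mode_of_onset"],
        )

    oc_df = pd.read_csv(outcome_path, dtype={"subject_id": str}, float_precision="round_trip")
    for _, row in oc_df.iterrows():
        sid = str(row["subject_id"])
        if sid not in timelines:
            logger.warning("outcome subject %r has no timeline; excluded", sid)
            continue
        gaf = row.get("gaf_d", np.nan)
        cohort.outcomes[sid] = OutcomeRecord(
            subject_id=sid,
            gaf_d=float(gaf) if pd.notna(gaf) else float("nan"),
            in_relationship=_bool_from_field(row.get("in_relationship")),
            employed=_bool_from_field(row.get("employed")),
        )
    return cohort


def write_cohort(
    cohort: Cohort,
    timeline_path: str | Path,
    baseline_path: str | Path,
    outcome_path: str | Path,
) -> None:
    """Write a cohort as three delimited files (inverse of :func:`read_cohort`)."""
    tl_rows = []
    for sid in cohort.subject_ids:
        tl = cohort.timelines[sid]
        for m, st in enumerate(tl.statuses):
            tl_rows.append((sid, m, STATUS_TO_CODE[Status(int(st))]))
    pd.DataFrame(tl_rows, columns=["subject_id", "month", "status"]).to_csv(
        timeline_path, index=False
    )

    bl_rows = [asdict(cohort.baselines[s]) for s in cohort.subject_ids if s in cohort.baselines]
    bl_cols = [f.name for f in BaselineRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    pd.DataFrame(bl_rows, columns=bl_cols).to_csv(
        baseline_path, index=False, float_format="%.17g"
    )

    oc_rows = []
    for sid in cohort.subject_ids:
        if sid not in cohort.outcomes:
            continue
        oc = cohort.outcomes[sid]
        oc_rows.append(
            {
                "subject_id": sid,
                "gaf_d": "" if np.isnan(oc.gaf_d) else oc.gaf_d,
                "in_relationship": _BOOL_TO_STR[oc.in_relationship],
                "employed": _BOOL_TO_STR[oc.employed],
            }
        )
    pd.DataFrame(oc_rows, columns=["subject_id", "gaf_d", "in_relationship", "employed"]).to_csv(
        outcome_path, index=False, float_format="%.17g"
    )


def write_cohort_bundle(cohort: Cohort, path: str | Path) -> None:
    """Write the whole cohort to a single structured-text (JSON) file."""
    payload = {
        "timelines": {
            sid: "".join(STATUS_TO_CODE[Status(int(s))] for s in tl.statuses)
            for sid, tl in cohort.timelines.items()
        },
        "baselines": {sid: asdict(b) for sid, b in cohort.baselines.items()},
        "outcomes": {
            sid: {
                "subject_id": o.subject_id,
                "gaf_d": None if np.isnan(o.gaf_d) else o.gaf_d,
                "in_relationship": o.in_relationship,
                "employed": o.employed,
            }
            for sid, o in cohort.outcomes.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_cohort_bundle(path: str | Path) -> Cohort:
    payload = json.loads(Path(path).read_text())
    cohort = Cohort()
    for sid, codes in payload["timelines"].items():
        statuses = np.array([int(CODE_TO_STATUS[c]) for c in codes], dtype=np.int8)
        cohort.timelines[sid] = MonthlyTimeline(subject_id=sid, statuses=statuses)
    for sid, b in payload["baselines"].items():
        cohort.baselines[sid] = BaselineRecord(**b)
    for sid, o in payload["outcomes"].items():
        cohort.outcomes[sid] = OutcomeRecord(
            subject_id=o["subject_id"],
            gaf_d=float("nan") if o["gaf_d"] is None else o["gaf_d"],
            in_relationship=o["in_relationship"],
            employed=o["employed"],
        )
    return cohort
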