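"""Classical course typology (episodic / continuous / neither), the 2-year
symptom-recovery rule, and trajectory-by-outcome cross-tabulations."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import MonthlyTimeline, Status

__all__ = [
    "EpisodeRun",
    "CourseCategory",
    "extract_runs",
    "classify_course",
    "classify_timeline",
    "assess_recovery",
    "crosstab_class_by",
    "CrosstabResult",
]

#: longest missing gap (months) bridged when both flanks share a state
BRIDGE_MAX_GAP = 2
#: episode/remission length cut-point in months
SPELL_CUTOFF = 6


@dataclass(frozen=True)
class EpisodeRun:
    state: Status  # PRESENT or ABSENT
    start_month: int
    length_months: int


class CourseCategory(str, Enum):
    EPISODIC = "episodic"
    CONTINUOUS = "continuous"
    NEITHER = "neither"
    UNCLASSIFIABLE = "unclassifiable"


def _segments(statuses: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal (state, start, length) segments of a status sequence."""
    segs = []
    start = 0
    for i in range(1, len(statuses) + 1):
        if i == len(statuses) or statuses[i] != statuses[start]:
            segs.append((int(statuses[start]), start, i - start))
            start = i
    return segs


def extract_runs(tl: MonthlyTimeline) -> list[EpisodeRun]:
    """Maximal runs of consecutive equal non-missing statuses.

    Missing gaps of up to ``BRIDGE_MAX_GAP`` months are bridged by the
    surrounding state when both flanks agree (the gap's months count towards
    the bridged run); longer or unmatched gaps split runs, and their months
    belong to no run.
    """
    segs = _segments(tl.statuses)
    merged: list[list[int]] = []  # [state, start, length]
    i = 0
    while i < len(segs):
        state, start, length = segs[i]
        if state == int(Status.MISSING):
            prev = merged[-1] if merged else None
            nxt = segs[i + 1] if i + 1 < len(segs) else None
            if (
                length <= BRIDGE_MAX_GAP
                and prev is not None
                and nxt is not None
                and prev[0] == nxt[0]
            ):
                # absorb the gap and the following run into the previous run
                prev[2] += length + nxt[2]
                i += 2
                continue
            i += 1
            continue
        if merged and merged[-1][0] == state and merged[-1][1] + merged[-1][2] == start:
            merged[-1][2] += length
        else:
            merged.append([state, start, length])
        i += 1
    return [
        EpisodeRun(state=Status(s), start_month=st, length_months=ln)
        for s, st, ln in merged
    ]


def classify_course(runs: Sequence[EpisodeRun]) -> CourseCategory:
    """Classify a run sequence by the 6-month episode/remission cut-points.

    Episodic: no symptomatic run of 6 months or more.  Otherwise continuous
    if no remission of 6 months or more; otherwise neither.  A record with no
    long episode and no long remission is episodic by precedence.  Empty run
    sequences are unclassifiable.
    """
    if not runs:
        return CourseCategory.UNCLASSIFIABLE
    longest_present = max(
        (r.length_months for r in runs if r.state == Status.PRESENT), default=0
    )
    longest_absent = max(
        (r.length_months for r in runs if r.state == Status.ABSENT), default=0
    )
    if longest_present < SPELL_CUTOFF:
        return CourseCategory.EPISODIC
    if longest_absent < SPELL_CUTOFF:
        return CourseCategory.CONTINUOUS
    return CourseCategory.NEITHER


def classify_timeline(tl: MonthlyTimeline) -> CourseCategory:
    """Convenience composition of :func:`extract_runs` and :func:`classify_course`."""
    return classify_course(extract_runs(tl))


def assess_recovery(tl: MonthlyTimeline) -> bool | None:
    """Symptom recovery: no symptomatic month in the final 2 years.

    Requires at least 12 rated months among the final 24 to declare recovery;
    fewer observed months yields False (insufficient evidence).  Follow-up
    shorter than 24 months is unclassifiable (None).
    """
    if tl.followup_months < 24:
        return None
    window = tl.statuses[-24:]
    if (window == Status.PRESENT).any():
        return False
    n_observed = int((window != Status.MISSING).sum())
    return n_observed >= 12


@dataclass
class CrosstabResult:
    counts: pd.DataFrame | None = None
    row_pct: pd.DataFrame | None = None
    col_pct: pd.DataFrame | None = None
    numeric_summary: pd.DataFrame | None = None

    @property
    def is_numeric(self) -> bool:
        return self.numeric_summary is not None


def crosstab_class_by(
    labels: Mapping[str, str] | pd.Series,
    factor: Mapping[str, object] | pd.Series,
) -> CrosstabResult:
    """Cross-tabulate trajectory class labels against a per-subject factor.

    Categorical factors yield counts with row/column percentages; numeric
    factors yield per-class mean, SD and n (missing values excluded).  No
    test statistics are computed here.
    """
    lab = pd.Series(labels, name="trajectory_class")
    fac = pd.Series(dict(factor) if not isinstance(factor, pd.Series) else factor)
    common = lab.index.intersection(fac.index)
    if len(common) == 0:
        raise ValueError("labels and factor share no subject ids")
    lab, fac = lab.loc[common], fac.loc[common]

    if pd.api.types.is_numeric_dtype(fac) and not pd.api.types.is_bool_dtype(fac):
        df = pd.DataFrame({"class": lab, "value": fac.astype(float)}).dropna()
        grp = df.groupby("class")["value"]
        summary = grp.agg(mean="mean", sd="std", n="count")
        summary.loc[summary["n"] < 2, "sd"] = np.nan
        return CrosstabResult(numeric_summary=summary)

    fac = fac.map(lambda v: v.value if isinstance(v, Enum) else v)
    df = pd.DataFrame({"class": lab, "factor": fac}).dropna()
    counts = pd.crosstab(df["class"], df["factor"])
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return CrosstabResult(counts=counts, row_pct=row_pct, col_pct=col_pct)
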