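"""Clinical-change trajectories: per-visit change scores, maximum-change
phase assignment, responder classification and change-magnitude grouping.

Change at visit week w is dQIDS_w = total(baseline) - total(week w), so a
*positive* value is an improvement.  Each subject's trajectory is summarised
by the change largest in absolute value (dQIDS); the visit attaining it is
the *post-change* phase and the scheduled visit immediately preceding it is
the *change* phase (max at week 6 -> change phase week 4; max at week 4 ->
change phase is baseline).  Subjects are grouped into eight two-unit dQIDS
bins, with changes of 16 or more merged into a single top bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCHEDULE",
    "TrajectoryError",
    "PhaseAssignment",
    "GroupBin",
    "compute_deltas",
    "find_max_change",
    "assign_phases",
    "classify_responder",
    "assign_subject_phases",
    "bin_groups",
    "group_mean_delta",
    "DEFAULT_BIN_EDGES",
]

#: Visit schedule in weeks: baseline plus four follow-up visits.
SCHEDULE: tuple[int, ...] = (0, 4, 6, 9, 12)


class TrajectoryError(ValueError):
    """Trajectory input violates the schedule or is insufficient."""


@dataclass(frozen=True)
class PhaseAssignment:
    """Per-subject change summary and phase labelling."""

    subject_id: object
    deltas: Mapping[int, float]  # week -> signed change (positive = improvement)
    max_delta: float  # signed change at the max-|change| week
    max_week: int
    change_week: int  # schedule predecessor of max_week
    postchange_week: int  # == max_week
    responder: bool | None  # None when baseline == 0 (undefined)


def compute_deltas(
    scores_by_week: Mapping[int, float], schedule: Sequence[int] = SCHEDULE
) -> dict[int, float]:
    """Signed change from baseline at each available follow-up visit.

    ``scores_by_week`` maps week -> QIDS total; entries may be absent.
    Raises :class:`TrajectoryError` if baseline (week 0) is missing or no
    follow-up visit is available.
    """
    if schedule[0] not in scores_by_week or _isnan(scores_by_week[schedule[0]]):
        raise TrajectoryError("baseline score missing")
    base = float(scores_by_week[schedule[0]])
    deltas = {
        w: base - float(scores_by_week[w])
        for w in schedule[1:]
        if w in scores_by_week and not _isnan(scores_by_week[w])
    }
    if not deltas:
        raise TrajectoryError("no post-baseline visit available")
    return deltas


def _isnan(x: object) -> bool:
    return isinstance(x, float) and np.isnan(x)


def find_max_change(deltas: Mapping[int, float]) -> tuple[float, int]:
    """Week with the largest absolute change; ties broken toward the
    earliest week.  Returns the *signed* change at that week."""
    if not deltas:
        raise TrajectoryError("empty delta set")
    best_w = min(deltas, key=lambda w: (-abs(deltas[w]), w))
    return float(deltas[best_w]), int(best_w)


def assign_phases(
    max_week: int, schedule: Sequence[int] = SCHEDULE
) -> tuple[int, int]:
    """(change_week, postchange_week) for a given maximum-change week.

    The change phase is the schedule visit immediately preceding the
    maximum-change visit (4 -> 0, 6 -> 4, 9 -> 6, 12 -> 9); the post-change
    phase is the maximum-change visit itself.
    """
    if max_week not in schedule[1:]:
        raise TrajectoryError(f"week {max_week} not in schedule {schedule}")
    i = list(schedule).index(max_week)
    return int(schedule[i - 1]), int(max_week)


def classify_responder(scores_by_week: Mapping[int, float]) -> bool | None:
    """True iff some available visit achieves a >= 50% reduction from
    baseline; ``None`` (undefined) when baseline is 0."""
    base = scores_by_week.get(0)
    if base is None or _isnan(base):
        raise TrajectoryError("baseline score missing")
    if base == 0:
        return None
    visits = [
        v
        for w, v in scores_by_week.items()
        if w != 0 and v is not None and not _isnan(v)
    ]
    if not visits:
        raise TrajectoryError("no post-baseline visit available")
    return bool(min(visits) <= 0.5 * float(base))


def assign_subject_phases(
    visits: pd.DataFrame, schedule: Sequence[int] = SCHEDULE
) -> tuple[list[PhaseAssignment], pd.DataFrame]:
    """Phase-assign every subject in a scored long-format visit table.

    ``visits`` needs columns ``subject_id``, ``week``, ``qids_total``.
    Subjects without a usable baseline or any follow-up visit, or lacking
    QIDS data at their change week, are excluded; the second return value
    lists each exclusion with its reason.
    """
    assignments: list[PhaseAssignment] = []
    excluded: list[tuple[object, str]] = []
    for sid, grp in visits.groupby("subject_id", sort=True):
        scores = {
            int(w): float(t)
            for w, t in zip(grp["week"], grp["qids_total"])
            if not np.isnan(t)
        }
        try:
            deltas = compute_deltas(scores, schedule)
        except TrajectoryError as e:
            excluded.append((sid, str(e)))
            continue
        max_delta, max_week = find_max_change(deltas)
        change_week, post_week = assign_phases(max_week, schedule)
        if change_week not in scores:
            excluded.append((sid, f"no QIDS data at change week {change_week}"))
            continue
        responder = None if scores[0] == 0 else classify_responder(scores)
        assignments.append(
            PhaseAssignment(
                subject_id=sid,
                deltas=deltas,
                max_delta=max_delta,
                max_week=max_week,
                change_week=change_week,
                postchange_week=post_week,
                responder=responder,
            )
        )
    excl = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    return assignments, excl


#: Two-unit bin edges: [0-1], [2-3], ..., [14-15], with >=16 merged on top.
DEFAULT_BIN_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1),
    (2, 3),
    (4, 5),
    (6, 7),
    (8, 9),
    (10, 11),
    (12, 13),
    (14, 15),
    (16, 27),
)


@dataclass
class GroupBin:
    """A change-magnitude group: its range, members and phase material."""

    label: str
    lo: int
    hi: int
    members: list[PhaseAssignment]

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def subject_ids(self) -> list[object]:
        return [a.subject_id for a in self.members]

    @property
    def mean_delta(self) -> float:
        return group_mean_delta(self)


def bin_groups(
    assignments: Iterable[PhaseAssignment],
    edges: Sequence[tuple[int, int]] = DEFAULT_BIN_EDGES,
    improvement_only: bool = False,
) -> list[GroupBin]:
    """Partition subjects into dQIDS bins by the magnitude of maximum change.

    The top two default edges merge into the single [16-24]-style bin at the
    caller's discretion — with the defaults this yields eight bins because
    the last edge already spans 16-27.  Worsening subjects (negative max
    change) are binned by |dQIDS| unless ``improvement_only`` drops them.
    """
    bins = [
        GroupBin(label=f"[{lo}-{hi}]", lo=lo, hi=hi, members=[]) for lo, hi in edges
    ]
    for a in assignments:
        if improvement_only and a.max_delta < 0:
            continue
        mag = abs(a.max_delta)
        if mag > 27:
            raise TrajectoryError(f"dQIDS {a.max_delta} outside [-27, 27]")
        for b in bins:
            if b.lo <= mag <= b.hi:
                b.members.append(a)
                break
    return bins


def group_mean_delta(bin_: GroupBin) -> float:
    """Arithmetic mean of members' signed maximum change."""
    if bin_.n == 0:
        raise TrajectoryError(f"bin {bin_.label} is empty")
    return float(np.mean([a.max_delta for a in bin_.members]))


def group_summary(
    bins: Sequence[GroupBin],
    visits: pd.DataFrame | None = None,
    sex_by_subject: Mapping[object, str] | None = None,
) -> pd.DataFrame:
    """Group-characteristics table: one row per bin with n and mean change;
    baseline severity mean/SD when a scored visit table is supplied, and the
    female fraction when a subject->sex ("F"/"M") map is supplied."""
    rows = []
    base = None
    if visits is not None:
        base = (
            visits[visits["week"] == 0]
            .set_index("subject_id")["qids_total"]
            .to_dict()
        )
    for b in bins:
        row: dict[str, object] = {
            "group": b.label,
            "range_lo": b.lo,
            "range_hi": b.hi,
            "n": b.n,
            "mean_delta": b.mean_delta if b.n else np.nan,
        }
        if base is not None:
            bq = [base[s] for s in b.subject_ids if s in base]
            row["baseline_qids_mean"] = float(np.mean(bq)) if bq else np.nan
            row["baseline_qids_sd"] = float(np.std(bq, ddof=1)) if len(bq) > 1 else np.nan
        if sex_by_subject is not None and b.n:
            sexes = [sex_by_subject.get(s) for s in b.subject_ids]
            known = [s for s in sexes if s in ("F", "M")]
            row["female_fraction"] = (
                sum(s == "F" for s in known) / len(known) if known else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
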