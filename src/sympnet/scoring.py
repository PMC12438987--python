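"""Scoring of the QIDS 16-item depression instrument and the Q-LES-Q-SF
quality-of-life ("context") questionnaire.

The QIDS (clinician-rated QIDS-C or self-report QIDS-SR16 — identical
arithmetic) asks 16 questions, each scored 0-3, that map onto the nine DSM
criterion symptom domains of major depression.  Three domains — sleep,
appetite/weight and restlessness/agitation — are probed by several items and
take the *maximum* of their items; the other six domains are single items.
The total severity score is the sum of the nine domain scores, 0 (not
depressed) to 27 (most depressed).

The Q-LES-Q-SF has 16 items rated 1-5; two items about general aspects of
life are excluded, so the total over the 14 scored items ranges 14-70.  A
median-style cut (default 45) splits subjects into a "poor" and a "good"
perceived context class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemMap",
    "DEFAULT_ITEM_MAP",
    "ScoringError",
    "MissingItemError",
    "consolidate_domains",
    "qids_total",
    "qlesq_total",
    "classify_context",
    "score_visits",
    "DOMAIN_NAMES",
]


class ScoringError(ValueError):
    """An item or domain value violates the instrument's range."""


class MissingItemError(ScoringError):
    """A constituent item is missing, so the visit's domain set is unavailable."""


DOMAIN_NAMES: tuple[str, ...] = (
    "sleep",
    "sad_mood",
    "appetite_weight",
    "concentration",
    "self_criticism",
    "suicidal_ideation",
    "interest",
    "energy_fatigue",
    "restlessness_agitation",
)


@dataclass(frozen=True)
class ItemMap:
    """Assignment of the 16 QIDS items (1-based positions) to 9 domains.

    Multi-item domains are consolidated by the maximum of their items;
    single-item domains take their item verbatim.
    """

    domains: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if len(self.domains) != 9:
            raise ScoringError(f"expected 9 domains, got {len(self.domains)}")
        seen: list[int] = []
        for name, items in self.domains.items():
            if not items:
                raise ScoringError(f"domain {name!r} lists no items")
            seen.extend(items)
        if sorted(seen) != list(range(1, 17)):
            raise ScoringError(
                "every one of the 16 items must appear in exactly one domain"
            )
        multi = [n for n, it in self.domains.items() if len(it) >= 2]
        if len(multi) != 3:
            raise ScoringError(
                f"exactly three domains must list >=2 items, got {multi}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.domains)


#: Standard QIDS layout: sleep = items 1-4, appetite/weight = items 6-9,
#: restlessness/agitation = items 15-16; the remaining domains are single items.
DEFAULT_ITEM_MAP = ItemMap(
    {
        "sleep": (1, 2, 3, 4),
        "sad_mood": (5,),
        "appetite_weight": (6, 7, 8, 9),
        "concentration": (10,),
        "self_criticism": (11,),
        "suicidal_ideation": (12,),
        "interest": (13,),
        "energy_fatigue": (14,),
        "restlessness_agitation": (15, 16),
    }
)


def _check_item(value: object, index: int, lo: int, hi: int) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise MissingItemError(f"item {index} is missing")
    v = int(value)  # type: ignore[arg-type]
    if v != value or not lo <= v <= hi:
        raise ScoringError(f"item {index} value {value!r} outside {lo}-{hi}")
    return v


def consolidate_domains(
    items16: Sequence[int], item_map: ItemMap = DEFAULT_ITEM_MAP
) -> tuple[int, ...]:
    """Collapse 16 item scores (each 0-3) into the nine domain scores.

    Each multi-item domain receives the maximum of its items; each
    single-item domain receives its item verbatim.

    Raises
    ------
    MissingItemError
        If any item is missing (NaN/None) — the visit's domains are unavailable.
    ScoringError
        If an item value lies outside {0, 1, 2, 3}.
    """
    if len(items16) != 16:
        raise ScoringError(f"expected 16 items, got {len(items16)}")
    vals = {i + 1: _check_item(v, i + 1, 0, 3) for i, v in enumerate(items16)}
    return tuple(max(vals[i] for i in items) for items in item_map.domains.values())


def qids_total(domains: Sequence[int]) -> int:
    """Sum of the nine domain scores; ranges 0 (not depressed) to 27."""
    if len(domains) != 9:
        raise ScoringError(f"expected 9 domain scores, got {len(domains)}")
    vals = [_check_item(v, i + 1, 0, 3) for i, v in enumerate(domains)]
    return int(sum(vals))


def qlesq_total(
    items16: Sequence[int], general_item_indices: tuple[int, int] = (15, 16)
) -> int:
    """Q-LES-Q-SF total: sum of the 14 scored items (each 1-5), range 14-70.

    ``general_item_indices`` are the two 1-based items about general aspects
    of life that are excluded from the total (default: the last two).
    """
    if len(items16) != 16:
        raise ScoringError(f"expected 16 items, got {len(items16)}")
    excl = set(general_item_indices)
    if len(excl) != 2:
        raise ScoringError("exactly two general-life items must be excluded")
    vals = [_check_item(v, i + 1, 1, 5) for i, v in enumerate(items16)]
    return int(sum(v for i, v in enumerate(vals, start=1) if i not in excl))


def classify_context(total: int, threshold: int = 45) -> str:
    """Classify a Q-LES-Q-SF total as ``"poor"`` (< threshold) or ``"good"``."""
    if not 14 <= total <= 70:
        raise ScoringError(f"Q-LES-Q-SF total {total} outside 14-70")
    return "poor" if total < threshold else "good"


QIDS_ITEM_COLS = [f"item{i:02d}" for i in range(1, 17)]
QLESQ_ITEM_COLS = [f"qlesq{i:02d}" for i in range(1, 17)]
DOMAIN_COLS = [f"domain{i}" for i in range(1, 10)]


@dataclass
class ScoredVisits:
    """Long-format scored visit table plus per-subject context scores."""

    visits: pd.DataFrame  # subject_id, week, 9 domain cols, qids_total
    context: pd.DataFrame  # subject_id, qlesq_total, context_class
    item_map: ItemMap = field(default=DEFAULT_ITEM_MAP)


def score_visits(
    records: pd.DataFrame,
    item_map: ItemMap = DEFAULT_ITEM_MAP,
    general_item_indices: tuple[int, int] = (15, 16),
    context_threshold: int | None = 45,
) -> ScoredVisits:
    """Score a long-format visit table into domain scores, totals and context.

    ``records`` must carry ``subject_id`` and ``week`` plus either the 16
    QIDS item columns (``item01``..``item16``) or pre-consolidated domain
    columns (``domain1``..``domain9``).  Q-LES-Q-SF columns
    (``qlesq01``..``qlesq16``) are read from baseline (week 0) rows when
    present.  A visit with any missing constituent item yields missing
    domains/total (no imputation).

    ``context_threshold=None`` recomputes the threshold as the sample median
    of the Q-LES-Q-SF totals instead of the fixed default 45.
    """
    df = records.copy()
    has_items = all(c in df.columns for c in QIDS_ITEM_COLS)
    has_domains = all(c in df.columns for c in DOMAIN_COLS)
    if not (has_items or has_domains):
        raise ScoringError(
            "input must carry item01..item16 or domain1..domain9 columns"
        )

    names = list(item_map.names)
    if has_items:
        items = df[QIDS_ITEM_COLS].to_numpy(dtype=float)
        bad = ~(np.isnan(items) | np.isin(items, [0, 1, 2, 3]))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ScoringError(
                f"row {df.index[r]}: {QIDS_ITEM_COLS[c]} value "
                f"{items[r, c]!r} outside 0-3"
            )
        complete = ~np.isnan(items).any(axis=1)
        dom = np.full((len(df), 9), np.nan)
        for j, idxs in enumerate(item_map.domains.values()):
            dom[complete, j] = items[complete][:, [i - 1 for i in idxs]].max(axis=1)
    else:
        dom = df[DOMAIN_COLS].to_numpy(dtype=float)
        bad = ~(np.isnan(dom) | np.isin(dom, [0, 1, 2, 3]))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ScoringError(
                f"row {df.index[r]}: {DOMAIN_COLS[c]} value {dom[r, c]!r} outside 0-3"
            )
        dom = np.where(np.isnan(dom).any(axis=1)[:, None], np.nan, dom)

    visits = pd.DataFrame(dom, columns=names)
    visits.insert(0, "week", df["week"].to_numpy())
    visits.insert(0, "subject_id", df["subject_id"].to_numpy())
    visits["qids_total"] = visits[names].sum(axis=1, skipna=False)

    context = pd.DataFrame(columns=["subject_id", "qlesq_total", "context_class"])
    if all(c in df.columns for c in QLESQ_ITEM_COLS):
        base = df[df["week"] == 0]
        q = base[QLESQ_ITEM_COLS].to_numpy(dtype=float)
        ok = ~np.isnan(q).any(axis=1)
        if ok.any():
            totals = np.array(
                [
                    qlesq_total([int(v) for v in row], general_item_indices)
                    for row in q[ok]
                ]
            )
            thr = (
                int(np.median(totals))
                if context_threshold is None
                else context_threshold
            )
            context = pd.DataFrame(
                {
                    "subject_id": base.loc[ok, "subject_id"].to_numpy(),
                    "qlesq_total": totals,
                    "context_class": np.where(totals < thr, "poor", "good"),
                }
            )
    return ScoredVisits(visits=visits, context=context, item_map=item_map)
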