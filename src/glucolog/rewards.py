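"""Point engine, leaderboard, and upload-frequency engagement classification.

The app awards points for four behaviours: taking readings (capped per
day), getting readings in target, keeping a day free of active out-of-range
trends, and resolving detected trends.  The point magnitudes are
configuration — the app's emphasis on resolving trends is mirrored by the
largest default bonus — and the engine itemizes every award so ledger
totals are auditable.

Engagement is classified from the fraction of trial days with at least one
wireless upload, cut at 1/14, 1/7 and 3/7 days; boundaries are
lower-inclusive, so exactly 1 upload every 7 days is "moderate" and 3 of 7
is "high".
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import DataError, ReadingWindow, TargetRange, ValidationError, percent
from .trends import GlycemicClass, TrendEvent, classify, resolve_trend

__all__ = [
    "RewardRules",
    "LedgerEntry",
    "PointLedger",
    "EngagementLevel",
    "award_points",
    "leaderboard",
    "classify_engagement",
    "engagement_marginals",
]


class EngagementLevel(str, Enum):
    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


#: Upload-frequency cutpoints (fraction of days with an upload).
ENGAGEMENT_CUTS: Tuple[float, float, float] = (1 / 14, 1 / 7, 3 / 7)


@dataclass(frozen=True)
class RewardRules:
    points_per_reading: int = 1
    daily_reading_cap: int = 5
    points_in_target: int = 1
    points_trend_free_day: int = 2
    points_trend_resolved: int = 10

    def __post_init__(self) -> None:
        if min(
            self.points_per_reading,
            self.points_in_target,
            self.points_trend_free_day,
            self.points_trend_resolved,
        ) < 0:
            raise ValidationError("point values must be >= 0")
        if self.daily_reading_cap < 1:
            raise ValidationError("daily_reading_cap must be >= 1")


@dataclass(frozen=True)
class LedgerEntry:
    day: date
    rule: str  # reading | in_target | trend_free_day | trend_resolved
    points: int
    reference: str = ""


@dataclass
class PointLedger:
    participant_id: str
    entries: List[LedgerEntry] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(e.points for e in self.entries)

    def subtotal(self, rule: str) -> int:
        return sum(e.points for e in self.entries if e.rule == rule)

    def subtotals(self) -> Dict[str, int]:
        out: Dict[str, int] = defaultdict(int)
        for e in self.entries:
            out[e.rule] += e.points
        return dict(out)


def _trend_active_days(event: TrendEvent, window: ReadingWindow) -> Tuple[date, date]:
    """Closed day interval over which a trend counts as active.

    A trend is active from its detection day through the day it was
    resolved or expired (inclusive — resolving a trend the day it appears
    does not retroactively make that a trend-free day), or through the
    window end when still open.
    """
    start = event.detected_at.date()
    if event.status == "resolved" and event.resolved_at is not None:
        return start, event.resolved_at.date()
    if event.status == "expired" and event.expired_at is not None:
        return start, event.expired_at.date()
    return start, window.end_date.date()


def award_points(
    window: ReadingWindow,
    target: TargetRange,
    trends: Sequence[TrendEvent],
    resolutions: Optional[Mapping[int, Tuple[str, Sequence[str]]]] = None,
    rules: Optional[RewardRules] = None,
    participant_id: str = "",
) -> PointLedger:
    """Compute the itemized point ledger for one reading window.

    ``resolutions`` maps indices into ``trends`` to ``(cause, fixes)``; the
    referenced trends are resolved (state-checked) before scoring.  Per
    calendar day the engine awards ``min(n_readings, cap) ×
    points_per_reading``, plus ``points_in_target`` per in-target reading
    (uncapped), plus ``points_trend_free_day`` on days with at least one
    reading and no active trend, plus ``points_trend_resolved`` per
    resolution.
    """
    rules = rules or RewardRules()
    resolutions = resolutions or {}
    trends = list(trends)
    for idx, (cause, fixes) in resolutions.items():
        if not 0 <= idx < len(trends):
            raise DataError(f"resolution references unknown trend index {idx}")
        trends[idx] = resolve_trend(trends[idx], cause, fixes)

    ledger = PointLedger(participant_id=participant_id)

    by_day: Dict[date, List] = defaultdict(list)
    for r in window.readings:
        by_day[r.timestamp.date()].append(r)

    active_spans = [_trend_active_days(ev, window) for ev in trends]

    for day in sorted(by_day):
        readings = by_day[day]
        n_pts = min(len(readings), rules.daily_reading_cap) * rules.points_per_reading
        if n_pts:
            ledger.entries.append(LedgerEntry(day, "reading", n_pts, f"{len(readings)} readings"))
        n_in_target = sum(
            1 for r in readings if classify(r.value, r.context, target) is GlycemicClass.IN_TARGET
        )
        if n_in_target and rules.points_in_target:
            ledger.entries.append(
                LedgerEntry(day, "in_target", n_in_target * rules.points_in_target, f"{n_in_target} in target")
            )
        trend_active = any(a <= day <= b for a, b in active_spans)
        if not trend_active and rules.points_trend_free_day:
            ledger.entries.append(LedgerEntry(day, "trend_free_day", rules.points_trend_free_day))

    for idx, ev in enumerate(trends):
        if ev.status == "resolved" and idx in resolutions:
            ledger.entries.append(
                LedgerEntry(
                    ev.resolved_at.date() if ev.resolved_at else ev.detected_at.date(),
                    "trend_resolved",
                    rules.points_trend_resolved,
                    f"{ev.direction} {ev.context} trend",
                )
            )
    return ledger


def _pseudonym(participant_id: str) -> str:
    return "anon-" + hashlib.sha1(participant_id.encode()).hexdigest()[:8]


def leaderboard(ledgers: Sequence[PointLedger]) -> List[Tuple[int, str, int]]:
    """Rank ledgers by total, competition style (ties share rank: 1, 1, 3).

    Participant ids are pseudonymized in the output, as peers see the board.
    """
    if not ledgers:
        raise ValidationError("leaderboard requires at least one ledger")
    ordered = sorted(ledgers, key=lambda l: (-l.total, l.participant_id))
    out: List[Tuple[int, str, int]] = []
    rank = 0
    prev_total = None
    for pos, ledger in enumerate(ordered, start=1):
        if ledger.total != prev_total:
            rank = pos
            prev_total = ledger.total
        out.append((rank, _pseudonym(ledger.participant_id), ledger.total))
    return out


def classify_engagement(upload_days: int, total_days: int) -> EngagementLevel:
    """Classify upload frequency ``f = upload_days / total_days``.

    very_low: f < 1/14; low: 1/14 <= f < 1/7; moderate: 1/7 <= f < 3/7;
    high: f >= 3/7.  The four levels partition [0, 1].
    """
    if total_days < 1:
        raise ValidationError(f"total_days must be >= 1, got {total_days}")
    if not 0 <= upload_days <= total_days:
        raise ValidationError(f"upload_days {upload_days} outside [0, total_days={total_days}]")
    f = upload_days / total_days
    if f < ENGAGEMENT_CUTS[0]:
        return EngagementLevel.VERY_LOW
    if f < ENGAGEMENT_CUTS[1]:
        return EngagementLevel.LOW
    if f < ENGAGEMENT_CUTS[2]:
        return EngagementLevel.MODERATE
    return EngagementLevel.HIGH


def engagement_marginals(counts: Mapping[EngagementLevel, int]) -> Dict[str, int]:
    """Marginal percentages of an engagement count table.

    Returns integer percentages per level plus the combined
    moderate-or-high share (users uploading on average >= 1 day a week).
    """
    total = sum(counts.values())
    out = {level.value: percent(counts.get(level, 0), total) for level in EngagementLevel}
    out["moderate_or_high"] = percent(
        counts.get(EngagementLevel.MODERATE, 0) + counts.get(EngagementLevel.HIGH, 0), total
    )
    return out
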