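"""Clinical outcome measures computed from downloaded reading windows.

Mild hypoglycemia: every reading below 3.4 mmol/L counts as an event,
except that lows falling in the same or consecutive clock-hour timeslots
are grouped into a single episode, so one prolonged low (with repeated
confirmation sticks) is not multi-counted.  Slot chaining is transitive by
default — lows at 02:10, 03:40 and 04:15 occupy the 02:00, 03:00 and 04:00
slots and form one chained episode — with a non-transitive variant behind
a flag.

SMBG frequency: each reading counts individually except (a) readings taken
in apparent response to an initial low (<4.1) or high (>17.9), which are
absorbed into the anchor's group over the following 2 hours, and (b)
remaining readings sharing a clock hour, which form one group.  The daily
frequency is groups per day, corrected for the participant-estimated
fraction of readings available at download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    NumericalError,
    Reading,
    ReadingWindow,
    SevereHypoReport,
    Thresholds,
    ValidationError,
)

__all__ = [
    "HypoEpisode",
    "SMBGGroup",
    "AdjustmentTally",
    "OutcomeSummary",
    "count_mild_hypo",
    "count_severe_hypo",
    "group_smbg",
    "mean_daily_smbg",
    "tally_adjustments",
]


def _hour_slot(ts: datetime) -> datetime:
    return ts.replace(minute=0, second=0, microsecond=0)


@dataclass(frozen=True)
class HypoEpisode:
    """A chain of below-threshold readings in same/consecutive hour slots."""

    start_slot: datetime
    end_slot: datetime
    reading_indices: Tuple[int, ...]
    min_value: float


@dataclass(frozen=True)
class SMBGGroup:
    """One counted SMBG event: an hour-slot group or a response group."""

    reading_indices: Tuple[int, ...]
    anchor: datetime
    kind: str  # "hour_group" | "response_group"


@dataclass(frozen=True)
class AdjustmentTally:
    """Self-initiated regimen adjustments by initiator, clinic changes excluded."""

    by_initiator: Dict[str, int]
    team_contacted: int

    @property
    def total(self) -> int:
        return sum(self.by_initiator.values())


@dataclass
class OutcomeSummary:
    """Per-visit secondary outcomes for one participant."""

    participant_id: str
    visit_month: int  # 0 | 3 | 6 | 9 | 12
    mild_hypo_events: int
    severe_hypo_events: int
    mean_daily_smbg: float
    n_self_adjustments: int = 0
    instrument_scores: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.mild_hypo_events, self.severe_hypo_events, self.n_self_adjustments) < 0:
            raise ValidationError("outcome counts must be >= 0")
        if self.mean_daily_smbg < 0:
            raise ValidationError("mean_daily_smbg must be >= 0")


def count_mild_hypo(
    window: ReadingWindow,
    thresholds: Optional[Thresholds] = None,
    *,
    transitive: bool = True,
) -> Tuple[int, List[HypoEpisode]]:
    """Count mild hypoglycemic episodes in a window.

    Readings below ``thresholds.mild_hypo`` are mapped to clock-hour slots;
    slots that are identical or adjacent are linked, and each connected
    chain is one episode.  With ``transitive=False`` chaining is anchored:
    an episode only spans the first low's slot and the next hour, and a low
    beyond that starts a new episode.
    """
    thresholds = thresholds or Thresholds()
    lows = [(i, r) for i, r in enumerate(window.readings) if r.value < thresholds.mild_hypo]
    if not lows:
        return 0, []

    episodes: List[HypoEpisode] = []
    hour = timedelta(hours=1)
    current: List[Tuple[int, Reading]] = []
    anchor_slot: Optional[datetime] = None  # non-transitive mode only

    def close() -> None:
        slots = [_hour_slot(r.timestamp) for _, r in current]
        episodes.append(
            HypoEpisode(
                start_slot=min(slots),
                end_slot=max(slots),
                reading_indices=tuple(i for i, _ in current),
                min_value=min(r.value for _, r in current),
            )
        )

    for i, r in lows:
        slot = _hour_slot(r.timestamp)
        if not current:
            current = [(i, r)]
            anchor_slot = slot
            continue
        prev_slot = _hour_slot(current[-1][1].timestamp)
        if transitive:
            linked = slot - prev_slot <= hour
        else:
            linked = slot - anchor_slot <= hour
        if linked:
            current.append((i, r))
        else:
            close()
            current = [(i, r)]
            anchor_slot = slot
    close()
    return len(episodes), episodes


def count_severe_hypo(reports: Sequence[SevereHypoReport]) -> int:
    """Count interview reports qualifying as severe hypoglycemia."""
    return sum(1 for rep in reports if rep.is_severe)


def group_smbg(window: ReadingWindow, thresholds: Optional[Thresholds] = None) -> List[SMBGGroup]:
    """Partition a window's readings into counted SMBG groups.

    Pass 1 (takes precedence): each reading below ``response_low`` or above
    ``response_high`` that is not already absorbed anchors a response group
    greedily absorbing all readings in the following
    ``response_window_hours``; absorbed readings cannot anchor.  Pass 2:
    remaining readings sharing a clock-hour slot merge into one hour group.
    Every reading belongs to exactly one group.
    """
    thresholds = thresholds or Thresholds()
    n = len(window.readings)
    window_td = timedelta(hours=thresholds.response_window_hours)
    assigned = [False] * n
    groups: List[SMBGGroup] = []

    # pass 1: greedy response groups, earliest anchor wins
    for i, r in enumerate(window.readings):
        if assigned[i]:
            continue
        if r.value < thresholds.response_low or r.value > thresholds.response_high:
            members = [i]
            assigned[i] = True
            for j in range(i + 1, n):
                dt = window.readings[j].timestamp - r.timestamp
                if dt > window_td:
                    break
                if not assigned[j]:
                    members.append(j)
                    assigned[j] = True
            groups.append(SMBGGroup(tuple(members), anchor=r.timestamp, kind="response_group"))

    # pass 2: hour-slot groups among the rest
    slot_members: Dict[datetime, List[int]] = {}
    for i, r in enumerate(window.readings):
        if not assigned[i]:
            slot_members.setdefault(_hour_slot(r.timestamp), []).append(i)
    for slot in sorted(slot_members):
        groups.append(SMBGGroup(tuple(slot_members[slot]), anchor=slot, kind="hour_group"))

    groups.sort(key=lambda g: g.anchor)
    return groups


def mean_daily_smbg(window: ReadingWindow, thresholds: Optional[Thresholds] = None) -> float:
    """Availability-corrected mean counted SMBG per day.

    ``(number of groups / window span in days) / availability_fraction``.
    An empty window yields 0.0; a zero-length window is an error.
    """
    if window.span_days <= 0:
        raise ValidationError("mean_daily_smbg requires a window spanning >= 1 day")
    n_groups = len(group_smbg(window, thresholds))
    return (n_groups / window.span_days) / window.availability_fraction


VALID_INITIATORS = ("participant", "guardian", "joint")


def tally_adjustments(records: Sequence[Dict]) -> AdjustmentTally:
    """Tally self-initiated regimen adjustments from interview records.

    Each record carries ``initiator`` (participant | guardian | joint |
    clinic) and an optional ``team_contacted`` flag.  Clinic-made changes
    are excluded from the tally; an unknown initiator is a validation
    error.
    """
    by_initiator = {k: 0 for k in VALID_INITIATORS}
    team = 0
    for rec in records:
        initiator = rec.get("initiator")
        if initiator == "clinic":
            continue
        if initiator not in VALID_INITIATORS:
            raise ValidationError(
                f"unknown initiator {initiator!r}; expected one of {VALID_INITIATORS + ('clinic',)}"
            )
        by_initiator[initiator] += 1
        if rec.get("team_contacted"):
            team += 1
    return AdjustmentTally(by_initiator=by_initiator, team_contacted=team)
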