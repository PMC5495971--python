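"""Logbook summaries and the out-of-range trend detector.

The trend detector scans each meal context's chronological reading sequence
independently: a run of at least ``trend_length`` (default 3) consecutive
readings that are all out of range in the same direction — e.g. three high
dinner readings, possibly on different days — is one actionable trend.
Runs are maximal, so five straight highs yield one event, not three
overlapping ones.  A detected trend stays *active* until the user resolves
it with a cause (and optional fixes) or a later in-target reading in the
same context *expires* it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from enum import Enum
from typing import List, Optional, Sequence, Tuple

from .core import (
    CONTEXTS,
    Reading,
    ReadingWindow,
    StateError,
    TargetRange,
    Thresholds,
    ValidationError,
)

__all__ = [
    "GlycemicClass",
    "ContextSummary",
    "TrendEvent",
    "classify",
    "summarize_context",
    "detect_trends",
    "resolve_trend",
]


class GlycemicClass(str, Enum):
    LOW = "low"
    IN_TARGET = "in_target"
    HIGH = "high"


@dataclass(frozen=True)
class ContextSummary:
    """Percent low / in-target / high for one context over a display span.

    With no readings the percentages are ``None`` (undefined), never 0.
    """

    context: str
    window_days: float
    n_readings: int
    pct_low: Optional[float]
    pct_in_target: Optional[float]
    pct_high: Optional[float]


@dataclass(frozen=True)
class TrendEvent:
    """A maximal run of same-direction out-of-range readings in one context."""

    context: str
    direction: str  # "high" | "low"
    reading_indices: Tuple[int, ...]  # indices into the window's reading list
    detected_at: datetime  # timestamp of the trend_length-th reading
    status: str = "active"  # active | resolved | expired
    cause: Optional[str] = None
    fixes: Tuple[str, ...] = ()
    resolved_at: Optional[datetime] = None
    expired_at: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.direction not in ("high", "low"):
            raise ValidationError(f"trend direction must be high|low, got {self.direction!r}")
        if self.status not in ("active", "resolved", "expired"):
            raise ValidationError(f"unknown trend status {self.status!r}")
        if self.status == "resolved" and not self.cause:
            raise ValidationError("a resolved trend requires a non-empty cause")


def classify(value: float, context: str, target: TargetRange) -> GlycemicClass:
    """Three-way classification against the (context-specific) target band.

    The band is closed: boundary values count as in target.
    """
    if value <= 0:
        raise ValidationError(f"glucose value must be positive, got {value}")
    low, high = target.band_for(context)
    if value < low:
        return GlycemicClass.LOW
    if value > high:
        return GlycemicClass.HIGH
    return GlycemicClass.IN_TARGET


def summarize_context(
    window: ReadingWindow,
    context: str,
    target: TargetRange,
    span_days: float,
) -> ContextSummary:
    """Percentages of in/out-of-target readings for one context.

    Only readings in the trailing ``span_days`` of the window contribute
    (calendar-day semantics, half-open like the window cut itself).
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    if span_days <= 0:
        raise ValidationError(f"span_days must be > 0, got {span_days}")
    from datetime import timedelta

    span_start = window.end_date - timedelta(days=span_days)
    counts = {GlycemicClass.LOW: 0, GlycemicClass.IN_TARGET: 0, GlycemicClass.HIGH: 0}
    for r in window.readings:
        if r.context == context and r.timestamp > span_start:
            counts[classify(r.value, context, target)] += 1
    n = sum(counts.values())
    if n == 0:
        return ContextSummary(context, span_days, 0, None, None, None)
    return ContextSummary(
        context=context,
        window_days=span_days,
        n_readings=n,
        pct_low=100.0 * counts[GlycemicClass.LOW] / n,
        pct_in_target=100.0 * counts[GlycemicClass.IN_TARGET] / n,
        pct_high=100.0 * counts[GlycemicClass.HIGH] / n,
    )


def detect_trends(
    window: ReadingWindow,
    target: TargetRange,
    thresholds: Optional[Thresholds] = None,
) -> List[TrendEvent]:
    """Find every maximal same-direction out-of-range run per context.

    Consecutiveness is within the per-context subsequence: three successive
    dinner readings on three different days form a run.  An in-target or
    opposite-direction reading breaks the run.  Events whose run is followed
    by a later in-target reading in the same context are returned already
    ``expired`` (the trend visibly ended); runs still open at the window end
    are ``active``.
    """
    thresholds = thresholds or Thresholds()
    k = thresholds.trend_length
    events: List[TrendEvent] = []
    for context in CONTEXTS:
        seq = [(i, r) for i, r in enumerate(window.readings) if r.context == context]
        run: List[int] = []
        run_dir: Optional[str] = None

        def flush(next_in_target_at: Optional[datetime]) -> None:
            if run_dir is not None and len(run) >= k:
                detected_at = window.readings[run[k - 1]].timestamp
                if next_in_target_at is not None:
                    events.append(
                        TrendEvent(
                            context=context,
                            direction=run_dir,
                            reading_indices=tuple(run),
                            detected_at=detected_at,
                            status="expired",
                            expired_at=next_in_target_at,
                        )
                    )
                else:
                    events.append(
                        TrendEvent(
                            context=context,
                            direction=run_dir,
                            reading_indices=tuple(run),
                            detected_at=detected_at,
                        )
                    )

        for i, r in seq:
            cls = classify(r.value, context, target)
            if cls is GlycemicClass.IN_TARGET:
                flush(next_in_target_at=r.timestamp)
                run, run_dir = [], None
            else:
                direction = "high" if cls is GlycemicClass.HIGH else "low"
                if direction != run_dir:
                    # an opposite-direction reading both breaks the old run
                    # and starts a new one; the old trend is not expired by
                    # it (only an in-target reading expires)
                    flush(next_in_target_at=None)
                    run, run_dir = [i], direction
                else:
                    run.append(i)
        flush(next_in_target_at=None)
    events.sort(key=lambda e: e.detected_at)
    return events


def resolve_trend(event: TrendEvent, cause: str, fixes: Sequence[str] = (), *, at: Optional[datetime] = None) -> TrendEvent:
    """Mark an active trend resolved with the user's cause and fixes.

    Resolving a non-active (already resolved or expired) event is a state
    error; an empty cause is a precondition error.
    """
    if not cause or not str(cause).strip():
        raise ValidationError("resolving a trend requires a non-empty cause")
    if event.status != "active":
        raise StateError(f"cannot resolve a trend with status {event.status!r}")
    return replace(
        event,
        status="resolved",
        cause=str(cause),
        fixes=tuple(fixes),
        resolved_at=at or event.detected_at,
    )
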