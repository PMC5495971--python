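"""Domain types shared by every other module.

All glucose values are in mmol/L (the Canadian clinical convention); a
helper converts mg/dL inputs.  Timestamps are naive ``datetime`` objects at
minute resolution — the data model assumes a single locale and performs no
time-zone arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple, Union

__all__ = [
    "CONTEXTS",
    "MGDL_PER_MMOL",
    "Source",
    "Reading",
    "TargetRange",
    "Participant",
    "ReadingWindow",
    "SevereHypoReport",
    "Thresholds",
    "Rejection",
    "GlucologError",
    "ValidationError",
    "DataError",
    "NumericalError",
    "StateError",
    "validate_reading",
    "mgdl_to_mmol",
    "percent",
]

#: Fixed context vocabulary.  Meal contexts are named by example in the app's
#: logbook; unknown labels fall back to ``"other"``.
CONTEXTS: Tuple[str, ...] = ("breakfast", "lunch", "dinner", "bedtime", "snack", "other")

MGDL_PER_MMOL = 18.016

#: Physiologically plausible open interval for a meter reading, mmol/L.
GLUCOSE_MIN = 0.0
GLUCOSE_MAX = 40.0


class GlucologError(Exception):
    """Base class for package errors."""


class ValidationError(GlucologError, ValueError):
    """An input violates a documented invariant."""


class DataError(GlucologError):
    """Malformed or inconsistent input data (bad file, unknown reference)."""


class NumericalError(GlucologError):
    """A computation is undefined for the given data (e.g. zero variance)."""


class StateError(GlucologError):
    """An operation was applied to an object in the wrong lifecycle state."""


class Source(str, Enum):
    METER = "meter"
    PUMP = "pump"
    MANUAL = "manual"


def mgdl_to_mmol(value: float) -> float:
    """Convert a glucose value from mg/dL to mmol/L."""
    return value / MGDL_PER_MMOL


def percent(numerator: float, denominator: float, digits: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to *digits*."""
    if denominator == 0:
        raise NumericalError("percentage undefined for zero denominator")
    out = round(100.0 * numerator / denominator, digits)
    return int(out) if digits == 0 else out


@dataclass(frozen=True)
class Reading:
    """One timestamped self-monitored blood glucose measurement.

    ``value`` must lie in the open interval (0, 40) mmol/L; anything outside
    is physiologically impossible for a meter and is rejected rather than
    stored.
    """

    timestamp: datetime
    value: float
    context: str = "other"
    device_id: str = ""
    source: Source = Source.METER

    def __post_init__(self) -> None:
        if not isinstance(self.timestamp, datetime):
            raise ValidationError(f"timestamp must be a datetime, got {type(self.timestamp).__name__}")
        if not (GLUCOSE_MIN < self.value < GLUCOSE_MAX):
            raise ValidationError(
                f"glucose value {self.value!r} outside plausible range ({GLUCOSE_MIN}, {GLUCOSE_MAX}) mmol/L"
            )
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}; expected one of {CONTEXTS}")
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", Source(self.source))
        # minute resolution: truncate seconds/microseconds
        if self.timestamp.second or self.timestamp.microsecond:
            object.__setattr__(self, "timestamp", self.timestamp.replace(second=0, microsecond=0))


@dataclass(frozen=True)
class TargetRange:
    """Per-participant in-range glucose band, optionally overridden per context.

    The band is closed: a value exactly on either boundary counts as in
    target (the patient-positive reading of an otherwise ambiguous boundary).
    """

    low: float
    high: float
    context_overrides: Optional[Mapping[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"target band requires low < high, got [{self.low}, {self.high}]")
        if self.context_overrides:
            for ctx, (lo, hi) in self.context_overrides.items():
                if ctx not in CONTEXTS:
                    raise ValidationError(f"override for unknown context {ctx!r}")
                if not lo < hi:
                    raise ValidationError(f"override band for {ctx!r} requires low < high")

    def band_for(self, context: str) -> Tuple[float, float]:
        if self.context_overrides and context in self.context_overrides:
            return tuple(self.context_overrides[context])
        return (self.low, self.high)


@dataclass(frozen=True)
class Participant:
    """Trial participant with stratification variables.

    ``age_years`` follows the adolescent cohort definition (11–16 inclusive)
    and ``baseline_hba1c`` the screening band used by the generator.
    """

    id: str
    arm: str  # "intervention" | "control"
    regimen: str  # "pump" | "injection"
    site: str  # "A" | "B"
    age_years: float
    baseline_hba1c: float

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "control"):
            raise ValidationError(f"arm must be intervention|control, got {self.arm!r}")
        if self.regimen not in ("pump", "injection"):
            raise ValidationError(f"regimen must be pump|injection, got {self.regimen!r}")
        if self.site not in ("A", "B"):
            raise ValidationError(f"site must be A|B, got {self.site!r}")
        if not 4.0 <= self.baseline_hba1c <= 20.0:
            raise ValidationError(f"baseline HbA1c {self.baseline_hba1c} outside [4, 20]%")


@dataclass(frozen=True)
class ReadingWindow:
    """A time-ordered slice of a participant's readings.

    ``availability_fraction`` is the participant-estimated proportion of
    their total readings present on the devices actually downloaded; it is
    carried here so downstream frequency estimates can correct for missing
    hardware.
    """

    readings: Tuple[Reading, ...]
    start_date: datetime
    end_date: datetime
    availability_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(self.readings))
        if not 0.0 < self.availability_fraction <= 1.0:
            raise ValidationError(
                f"availability_fraction must be in (0, 1], got {self.availability_fraction}"
            )
        if self.end_date < self.start_date:
            raise ValidationError("window end_date precedes start_date")
        prev = None
        for r in self.readings:
            if not (self.start_date < r.timestamp <= self.end_date):
                raise ValidationError(
                    f"reading at {r.timestamp} outside window ({self.start_date}, {self.end_date}]"
                )
            if prev is not None and r.timestamp < prev:
                raise ValidationError("readings must be sorted ascending by timestamp")
            prev = r.timestamp

    @property
    def span_days(self) -> float:
        return (self.end_date - self.start_date) / timedelta(days=1)

    def __len__(self) -> int:
        return len(self.readings)


@dataclass(frozen=True)
class SevereHypoReport:
    """Interview-reported candidate severe hypoglycemic episode.

    Counts as severe only when third-party assistance was required AND
    either a confirmed reading below 2.8 mmol/L or symptom reversal after
    carbohydrate/glucagon/IV glucose was reported.
    """

    date: date
    assisted_by_other: bool
    glucose_below_2_8: Optional[bool] = None
    symptom_reversal_with_treatment: Optional[bool] = None

    @property
    def is_severe(self) -> bool:
        return bool(
            self.assisted_by_other
            and (self.glucose_below_2_8 or self.symptom_reversal_with_treatment)
        )


@dataclass(frozen=True)
class Thresholds:
    """Clinical constants used throughout episode grouping and SMBG counting.

    Defaults are the study constants: mild hypoglycemia below 3.4 mmol/L,
    severe below 2.8 mmol/L, response-group triggers below 4.1 or above
    17.9 mmol/L with a 2-hour absorption window, 3-reading trends, a
    5-reading daily reward cap, and a 50-day download window.
    """

    mild_hypo: float = 3.4
    severe_hypo: float = 2.8
    response_low: float = 4.1
    response_high: float = 17.9
    response_window_hours: float = 2.0
    trend_length: int = 3
    daily_reading_cap: int = 5
    window_days: int = 50

    def __post_init__(self) -> None:
        if not self.severe_hypo < self.mild_hypo < self.response_low < self.response_high:
            raise ValidationError(
                "thresholds must satisfy severe_hypo < mild_hypo < response_low < response_high"
            )
        if self.response_window_hours <= 0:
            raise ValidationError("response_window_hours must be positive")
        if self.trend_length < 1 or self.daily_reading_cap < 1 or self.window_days < 1:
            raise ValidationError("trend_length, daily_reading_cap and window_days must be >= 1")


@dataclass(frozen=True)
class Rejection:
    """A quarantined raw record with the invariants it violated.

    Invalid rows are retained for audit rather than silently dropped.
    """

    record: Mapping
    reasons: Tuple[str, ...]
    line_number: Optional[int] = None


def _parse_timestamp(raw) -> datetime:
    if isinstance(raw, datetime):
        return raw
    if isinstance(raw, str):
        try:
            return datetime.fromisoformat(raw.strip())
        except ValueError:
            raise ValidationError(f"non-parseable timestamp {raw!r}") from None
    raise ValidationError(f"non-parseable timestamp {raw!r}")


def validate_reading(
    record: Mapping,
    *,
    unit: str = "mmol",
    default_device: str = "",
    default_source: Union[str, Source] = Source.METER,
) -> Union[Reading, Rejection]:
    """Normalize a raw record into a :class:`Reading` or a typed :class:`Rejection`.

    The record must carry ``timestamp`` and a numeric value under
    ``value_mmol_L`` (or ``value``).  ``unit="mgdl"`` converts the value to
    mmol/L on the way in.  Unknown or missing contexts fall back to
    ``"other"``.
    """
    reasons = []
    ts = None
    try:
        ts = _parse_timestamp(record.get("timestamp"))
    except ValidationError as exc:
        reasons.append(f"format: {exc}")

    raw_value = record.get("value_mmol_L", record.get("value"))
    value = None
    try:
        value = float(raw_value)
        if math.isnan(value):
            raise ValueError
    except (TypeError, ValueError):
        reasons.append(f"format: non-numeric glucose value {raw_value!r}")
    else:
        if unit == "mgdl":
            value = mgdl_to_mmol(value)
        elif unit != "mmol":
            raise ValidationError(f"unknown unit {unit!r}; expected 'mmol' or 'mgdl'")
        if not (GLUCOSE_MIN < value < GLUCOSE_MAX):
            reasons.append(f"range: glucose {value} outside ({GLUCOSE_MIN}, {GLUCOSE_MAX}) mmol/L")

    if reasons:
        return Rejection(record=dict(record), reasons=tuple(reasons))

    context = record.get("context") or "other"
    if context not in CONTEXTS:
        context = "other"
    source = record.get("source") or default_source
    try:
        source = Source(source)
    except ValueError:
        source = Source(default_source)
    return Reading(
        timestamp=ts,
        value=value,
        context=context,
        device_id=str(record.get("device_id") or default_device),
        source=source,
    )
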