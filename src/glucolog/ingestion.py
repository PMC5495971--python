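"""Parsing device exports, merging multiple devices, and cutting analysis windows.

A clinic download pools every available meter and pump.  The same finger
stick can therefore appear on two devices (a pump often mirrors the meter
it is linked to), so merging applies a tolerance-based deduplication with a
fixed source preference: meter over pump over manual entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import IO, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .core import (
    DataError,
    Reading,
    ReadingWindow,
    Rejection,
    Source,
    ValidationError,
    validate_reading,
)

__all__ = [
    "MergePolicy",
    "ParseResult",
    "parse_export",
    "merge_devices",
    "cut_window",
    "window_to_dict",
    "window_from_dict",
    "save_window",
    "load_window",
]

REQUIRED_COLUMNS = ("timestamp", "value_mmol_L")
OPTIONAL_COLUMNS = ("context", "device_id", "source")

_SOURCE_PRIORITY = {Source.METER: 0, Source.PUMP: 1, Source.MANUAL: 2}


@dataclass(frozen=True)
class MergePolicy:
    """Tolerances deciding when two cross-device readings are the same event."""

    duplicate_tolerance_minutes: float = 1.0
    duplicate_value_tolerance: float = 0.1  # mmol/L

    def __post_init__(self) -> None:
        if self.duplicate_tolerance_minutes < 0 or self.duplicate_value_tolerance < 0:
            raise ValidationError("merge tolerances must be >= 0")


@dataclass
class ParseResult:
    """Valid readings plus the quarantined rows (with 1-based data line numbers)."""

    readings: List[Reading] = field(default_factory=list)
    quarantined: List[Rejection] = field(default_factory=list)

    def __iter__(self):
        return iter(self.readings)

    def __len__(self) -> int:
        return len(self.readings)


def parse_export(
    file: Union[str, IO],
    device_id: str = "",
    source: Union[str, Source] = Source.METER,
    *,
    unit: str = "mmol",
) -> ParseResult:
    """Parse a delimited export into readings, quarantining invalid rows.

    The file must be CSV with a header containing at least ``timestamp`` and
    ``value_mmol_L``; ``context``, ``device_id`` and ``source`` columns are
    optional and fall back to the arguments.  Rows failing validation are
    returned in ``quarantined`` with their line numbers, never dropped.
    """
    try:
        frame = pd.read_csv(file, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        warnings.warn("empty export file: no readings parsed", stacklevel=2)
        return ParseResult()

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(
            f"export is missing required header column(s) {missing}; "
            f"expected at least {list(REQUIRED_COLUMNS)}"
        )
    if frame.empty:
        warnings.warn("export file has a header but no data rows", stacklevel=2)
        return ParseResult()

    result = ParseResult()
    for pos, row in enumerate(frame.itertuples(index=False)):
        record = {k: getattr(row, k, None) for k in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if hasattr(row, k)}
        record = {k: (None if pd.isna(v) else v) for k, v in record.items()}
        out = validate_reading(record, unit=unit, default_device=device_id, default_source=source)
        if isinstance(out, Rejection):
            # +2: one for the header line, one for 1-based numbering
            result.quarantined.append(Rejection(out.record, out.reasons, line_number=pos + 2))
        else:
            result.readings.append(out)
    return result


def _is_duplicate(a: Reading, b: Reading, policy: MergePolicy) -> bool:
    dt = abs((a.timestamp - b.timestamp).total_seconds()) / 60.0
    return dt <= policy.duplicate_tolerance_minutes and abs(a.value - b.value) <= policy.duplicate_value_tolerance


def merge_devices(
    device_lists: Sequence[Iterable[Reading]],
    policy: Optional[MergePolicy] = None,
) -> List[Reading]:
    """Merge per-device reading lists into one deduplicated, time-sorted list.

    Readings within both tolerances of an already-kept reading collapse onto
    it; when the duplicate comes from a preferred source (meter > pump >
    manual) it replaces the kept copy.  Merging a merged list with itself is
    a no-op under an exact-duplicate policy.
    """
    policy = policy or MergePolicy()
    pooled = sorted(
        (r for lst in device_lists for r in lst),
        key=lambda r: (r.timestamp, _SOURCE_PRIORITY[r.source], r.value, r.device_id),
    )
    kept: List[Reading] = []
    for r in pooled:
        matched = False
        # only recent keeps can be within the time tolerance
        for i in range(len(kept) - 1, -1, -1):
            gap_min = (r.timestamp - kept[i].timestamp).total_seconds() / 60.0
            if gap_min > policy.duplicate_tolerance_minutes:
                break
            if _is_duplicate(r, kept[i], policy):
                if _SOURCE_PRIORITY[r.source] < _SOURCE_PRIORITY[kept[i].source]:
                    kept[i] = r
                matched = True
                break
        if not matched:
            kept.append(r)
    kept.sort(key=lambda r: r.timestamp)
    return kept


def cut_window(
    readings: Iterable[Reading],
    end_date: datetime,
    days: float = 50,
    availability_fraction: float = 1.0,
) -> ReadingWindow:
    """Cut the trailing analysis window ending at a clinic date.

    The interval is half-open: ``end_date - days < timestamp <= end_date``,
    so "the previous 50 days" anchored at the download date keeps the
    download-day readings and excludes the reading exactly 50 days before.
    """
    if days <= 0:
        raise ValidationError(f"window days must be > 0, got {days}")
    if not 0.0 < availability_fraction <= 1.0:
        raise ValidationError(f"availability_fraction must be in (0, 1], got {availability_fraction}")
    start = end_date - timedelta(days=days)
    selected = sorted(
        (r for r in readings if start < r.timestamp <= end_date), key=lambda r: r.timestamp
    )
    return ReadingWindow(
        readings=tuple(selected),
        start_date=start,
        end_date=end_date,
        availability_fraction=availability_fraction,
    )


# --- window (de)serialization: JSON with ISO-8601 timestamps ---------------


def window_to_dict(window: ReadingWindow) -> dict:
    return {
        "start_date": window.start_date.isoformat(),
        "end_date": window.end_date.isoformat(),
        "availability_fraction": window.availability_fraction,
        "readings": [
            {
                "timestamp": r.timestamp.isoformat(),
                "value_mmol_L": r.value,
                "context": r.context,
                "device_id": r.device_id,
                "source": r.source.value,
            }
            for r in window.readings
        ],
    }


def window_from_dict(payload: dict) -> ReadingWindow:
    try:
        readings = tuple(
            Reading(
                timestamp=datetime.fromisoformat(r["timestamp"]),
                value=float(r["value_mmol_L"]),
                context=r.get("context", "other"),
                device_id=r.get("device_id", ""),
                source=Source(r.get("source", "meter")),
            )
            for r in payload["readings"]
        )
        return ReadingWindow(
            readings=readings,
            start_date=datetime.fromisoformat(payload["start_date"]),
            end_date=datetime.fromisoformat(payload["end_date"]),
            availability_fraction=float(payload.get("availability_fraction", 1.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DataError(f"malformed window payload: {exc}") from exc


def save_window(window: ReadingWindow, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(window_to_dict(window), fh, indent=1)


def load_window(path) -> ReadingWindow:
    import json

    with open(path) as fh:
        return window_from_dict(json.load(fh))
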