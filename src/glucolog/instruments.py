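"""Scoring arithmetic for the validated questionnaires.

Only item ids, scales and scoring rules are shipped — the instruments are
licensed, so no item wording appears here.

* SCI (Self-Care Inventory): 14 items rated 1–5 with a not-applicable
  option; the overall score is the mean of the answered items times 10,
  mapping the 1–5 item scale onto the published 10–50 range.
* DQOLY (Diabetes Quality of Life for Youth, short form): 22 items across
  6 subscales, each a reverse-coded 0–4 scale except the single-item
  Health Perception subscale (reverse-coded 1–4).  Subscale scores are
  sums of the reverse-coded items; higher means poorer quality of life.
* DFRQ (Diabetes Family Responsibility Questionnaire): 17 items rated
  1–3, summed into 3 subscales and a 17–51 total; higher scores mean more
  adolescent involvement in care.

The exact DQOLY item-to-subscale mapping is not public in the sources we
work from; the default spec derives the item counts per subscale from the
published subscale ranges and users can supply their own mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, Union

from .core import NumericalError, ValidationError

__all__ = [
    "SubscaleSpec",
    "InstrumentSpec",
    "ResponseSet",
    "InstrumentScores",
    "sci_spec",
    "dqoly_spec",
    "dfrq_spec",
    "default_spec",
    "score",
]

NA = "NA"


@dataclass(frozen=True)
class SubscaleSpec:
    name: str
    item_ids: Tuple[str, ...]
    scale_min: int
    scale_max: int
    invert: bool = False

    @property
    def min_score(self) -> int:
        return self.scale_min * len(self.item_ids)

    @property
    def max_score(self) -> int:
        return self.scale_max * len(self.item_ids)


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    subscales: Tuple[SubscaleSpec, ...]
    allows_na: bool = False

    @property
    def item_ids(self) -> Tuple[str, ...]:
        return tuple(i for s in self.subscales for i in s.item_ids)

    def item_scale(self, item_id: str) -> Tuple[int, int]:
        for s in self.subscales:
            if item_id in s.item_ids:
                return s.scale_min, s.scale_max
        raise ValidationError(f"unknown item {item_id!r} for instrument {self.name}")


def sci_spec() -> InstrumentSpec:
    """Self-Care Inventory: 14 items, 1–5 plus NA, overall 10–50."""
    return InstrumentSpec(
        name="SCI",
        subscales=(
            SubscaleSpec("overall", tuple(f"SCI{i:02d}" for i in range(1, 15)), 1, 5),
        ),
        allows_na=True,
    )


#: Items per DQOLY subscale, derived from the published subscale ranges
#: (e.g. Worries About Diabetes: 0–28 on a 0–4 scale means 7 items).
_DQOLY_LAYOUT = (
    ("impact_of_symptoms", 3, 0, 4),
    ("impact_of_treatment", 3, 0, 4),
    ("impact_on_activities", 5, 0, 4),
    ("parental_issues", 3, 0, 4),
    ("worries_about_diabetes", 7, 0, 4),
    ("health_perception", 1, 1, 4),
)


def dqoly_spec() -> InstrumentSpec:
    """DQOLY short form: 22 reverse-coded items across 6 subscales."""
    subscales = []
    n = 0
    for name, count, lo, hi in _DQOLY_LAYOUT:
        ids = tuple(f"DQOLY{n + i + 1:02d}" for i in range(count))
        n += count
        subscales.append(SubscaleSpec(name, ids, lo, hi, invert=True))
    return InstrumentSpec(name="DQOLY", subscales=tuple(subscales), allows_na=False)


def dfrq_spec() -> InstrumentSpec:
    """DFRQ: 17 items on a 1–3 scale, 3 subscales, total 17–51."""
    layouts = (("general_health", 7), ("social_presentation", 4), ("regimen", 6))
    subscales = []
    n = 0
    for name, count in layouts:
        ids = tuple(f"DFRQ{n + i + 1:02d}" for i in range(count))
        n += count
        subscales.append(SubscaleSpec(name, ids, 1, 3))
    return InstrumentSpec(name="DFRQ", subscales=tuple(subscales), allows_na=False)


_SPECS = {"SCI": sci_spec, "DQOLY": dqoly_spec, "DFRQ": dfrq_spec}


def default_spec(name: str) -> InstrumentSpec:
    try:
        return _SPECS[name.upper()]()
    except KeyError:
        raise ValidationError(f"unknown instrument {name!r}; expected one of {sorted(_SPECS)}") from None


@dataclass(frozen=True)
class ResponseSet:
    """A participant's item responses for one instrument."""

    instrument: str
    responses: Mapping[str, Union[int, str]]  # item id -> value or "NA"

    def validated(self, spec: InstrumentSpec) -> Dict[str, Union[int, str]]:
        if self.instrument.upper() != spec.name:
            raise ValidationError(
                f"response set is for {self.instrument!r}, spec is {spec.name!r}"
            )
        out: Dict[str, Union[int, str]] = {}
        for item in spec.item_ids:
            if item not in self.responses:
                raise ValidationError(f"missing response for item {item}")
            v = self.responses[item]
            if isinstance(v, str) and v.upper() == NA:
                if not spec.allows_na:
                    raise ValidationError(f"instrument {spec.name} does not allow NA (item {item})")
                out[item] = NA
                continue
            lo, hi = spec.item_scale(item)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValidationError(f"non-integer response {v!r} for item {item}") from None
            if not lo <= iv <= hi:
                raise ValidationError(f"response {iv} for item {item} outside scale [{lo}, {hi}]")
            out[item] = iv
        extra = set(self.responses) - set(spec.item_ids)
        if extra:
            raise ValidationError(f"responses for unknown items: {sorted(extra)}")
        return out


@dataclass(frozen=True)
class InstrumentScores:
    instrument: str
    overall: Optional[float]
    subscales: Dict[str, float]


def _invert(value: int, lo: int, hi: int) -> int:
    # reverse-code within the item scale: lo<->hi
    return hi + lo - value


def score(responses: ResponseSet, spec: Optional[InstrumentSpec] = None) -> InstrumentScores:
    """Score a response set; every output lies within the published ranges.

    SCI: overall = mean of non-NA items × 10 (an all-NA form is an error).
    DQOLY: subscale sums of reverse-coded items; no overall score is
    defined.  DFRQ: plain subscale sums plus their total.
    """
    spec = spec or default_spec(responses.instrument)
    values = responses.validated(spec)

    if spec.name == "SCI":
        answered = [v for v in values.values() if v != NA]
        if not answered:
            raise NumericalError("SCI score undefined: all items not applicable")
        overall = 10.0 * sum(answered) / len(answered)
        return InstrumentScores("SCI", overall, {"overall": overall})

    subscale_scores: Dict[str, float] = {}
    for sub in spec.subscales:
        items = [values[i] for i in sub.item_ids]
        if sub.invert:
            items = [_invert(v, sub.scale_min, sub.scale_max) for v in items]
        subscale_scores[sub.name] = float(sum(items))

    overall = sum(subscale_scores.values()) if spec.name == "DFRQ" else None
    return InstrumentScores(spec.name, overall, subscale_scores)
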