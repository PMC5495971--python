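"""Synthetic adolescent T1D cohorts: glucose traces, upload behaviour, trials.

The generator is behavioural, not physiological: it emulates *how the data
look* — per-context testing habits, right-skewed glucose values, injected
out-of-range trends, adherence drift over 12 months, and a quarterly visit
schedule with 50-day meter downloads — rather than insulin–glucose
dynamics.

Glucose values are drawn from a log-normal distribution (strictly positive
and right-skewed, like real meter data) whose two parameters are solved
numerically so that the fraction of readings in the default 4–10 mmol/L
band matches ``p_in_target`` and the fraction below 3.4 mmol/L matches
``p_mild_low``.  Each participant's distribution is then shifted so their
long-run mean glucose is consistent with their screening HbA1c through the
standard estimated-average-glucose (eAG) linearization
``HbA1c = (mean_bg + 2.59) / 1.59`` (mmol/L, %).

Everything is deterministic under a fixed seed: the cohort seed spawns one
named substream per participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .core import (
    CONTEXTS,
    Participant,
    Reading,
    ReadingWindow,
    Source,
    TargetRange,
    Thresholds,
    ValidationError,
)
from .ingestion import cut_window
from .instruments import ResponseSet, score, sci_spec
from .outcomes import OutcomeSummary, count_mild_hypo, mean_daily_smbg

__all__ = [
    "BehaviorParams",
    "ArmEffect",
    "CohortConfig",
    "TrialDataset",
    "simulate_trace",
    "glucose_to_hba1c",
    "hba1c_to_glucose",
    "simulate_cohort",
    "solve_lognormal",
    "default_control_behavior",
    "default_intervention_behavior",
]

#: Typical testing hour per context, chosen >= 2.5 h apart so that distinct
#: contexts never fall in the same clock-hour slot or response window.
CONTEXT_HOURS: Dict[str, float] = {
    "breakfast": 7.5,
    "other": 10.0,
    "lunch": 12.5,
    "snack": 15.0,
    "dinner": 17.5,
    "bedtime": 21.5,
}

DEFAULT_BAND = (4.0, 10.0)
EAG_SLOPE = 1.59
EAG_OFFSET = 2.59


@dataclass(frozen=True)
class BehaviorParams:
    """Testing and upload behaviour of one simulated participant.

    Defaults emulate the study cohort: roughly 4 tests/day at enrollment
    (each day every context is tested independently with probability
    ``smbg_rate × mix``), ~45% of readings in the 4–10 band and ~4% below
    3.4 mmol/L (consistent with a screening HbA1c near 9%), about two
    injected out-of-range trends a month, and a slow adherence drift (the
    observed ~12% decline in daily SMBG over 12 months corresponds to a
    half-life near 1900 days).
    """

    smbg_rate: float = 4.0
    context_mix: Tuple[float, ...] = (1 / 6,) * 6  # over CONTEXTS order
    p_in_target: float = 0.45
    p_mild_low: float = 0.04
    trend_injection_rate: float = 2.0  # trends per 30 days
    adherence_halflife_days: float = 1900.0
    upload_prob: float = 0.08  # median daily probability of syncing the meter
    upload_sd_log: float = 1.2  # between-participant log-SD of upload propensity

    def __post_init__(self) -> None:
        if self.smbg_rate < 0 or self.trend_injection_rate < 0:
            raise ValidationError("rates must be >= 0")
        if len(self.context_mix) != len(CONTEXTS):
            raise ValidationError(f"context_mix must have {len(CONTEXTS)} entries")
        if abs(sum(self.context_mix) - 1.0) > 1e-9 or min(self.context_mix) < 0:
            raise ValidationError("context_mix must be non-negative and sum to 1")
        for p, name in ((self.p_in_target, "p_in_target"), (self.p_mild_low, "p_mild_low"), (self.upload_prob, "upload_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.upload_sd_log < 0:
            raise ValidationError("upload_sd_log must be >= 0")
        if self.adherence_halflife_days <= 0:
            raise ValidationError("adherence_halflife_days must be > 0 (use math.inf for no drift)")


@dataclass(frozen=True)
class ArmEffect:
    """Generative intervention effect, for parameter-recovery experiments.

    ``delta_hba1c_slope`` is defined on the *measured* HbA1c scale: because
    a visit HbA1c reflects the trailing 90-day mean glucose, the underlying
    glucose ramp is led by half that averaging window so that the measured
    12-month effect equals ``delta_hba1c_slope`` (in %/year) rather than a
    lagged, attenuated version of it.
    """

    delta_hba1c_slope: float = 0.0  # % per year on measured HbA1c, negative = improvement
    delta_smbg: float = 0.0  # additional tests/day after onset
    effect_onset_days: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_hba1c_slope) and math.isfinite(self.delta_smbg)):
            raise ValidationError("arm effect deltas must be finite")
        if self.effect_onset_days < 0:
            raise ValidationError("effect_onset_days must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Two-arm cohort layout mirroring the trial design.

    92 participants (46 per arm) screened into the 8.0–10.5% HbA1c band,
    block-randomized (blocks of 4 or 6) within regimen × site strata, with
    quarterly visits over 12 months.
    """

    n_per_arm: int = 46
    hba1c_range: Tuple[float, float] = (8.0, 10.5)
    visit_months: Tuple[int, ...] = (0, 3, 6, 9, 12)
    seed: int = 0
    availability_fraction: float = 1.0
    hba1c_noise_sd: float = 0.3  # assay + biological visit-level noise, %

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValidationError("n_per_arm must be >= 1")
        if not self.hba1c_range[0] < self.hba1c_range[1]:
            raise ValidationError("hba1c_range low must be < high")
        if not 0.0 < self.availability_fraction <= 1.0:
            raise ValidationError("availability_fraction must be in (0, 1]")


@dataclass
class TrialDataset:
    """Simulated two-arm cohort with per-visit outcomes in long format."""

    participants: List[Participant]
    outcomes: pd.DataFrame  # one row per participant-visit
    uploads: pd.DataFrame  # one row per (participant, upload day); intervention arm only
    windows: Dict[str, ReadingWindow] = field(default_factory=dict)
    trial_days: int = 365


def glucose_to_hba1c(mean_bg: float) -> float:
    """HbA1c (%) from mean glucose (mmol/L) via the eAG linearization."""
    if not 2.0 < mean_bg < 35.0:
        raise ValidationError(f"mean glucose {mean_bg} outside plausible (2, 35) mmol/L")
    return (mean_bg + EAG_OFFSET) / EAG_SLOPE


def hba1c_to_glucose(hba1c: float) -> float:
    """Inverse eAG mapping: mean glucose (mmol/L) from HbA1c (%)."""
    return EAG_SLOPE * hba1c - EAG_OFFSET


def solve_lognormal(
    p_in_target: float,
    p_mild_low: float,
    band: Tuple[float, float] = DEFAULT_BAND,
    mild_threshold: float = 3.4,
) -> Optional[Tuple[float, float]]:
    """Solve log-normal (mu, sigma) for the target in-band and low fractions.

    Constraints: ``P(X < mild_threshold) = p_mild_low`` and
    ``P(band_low <= X <= band_high) = p_in_target``.  Of the (up to) two
    solutions the wider one is returned — glucose in poorly controlled T1D
    has a large coefficient of variation, and the narrow solution would put
    the whole distribution just above the hypoglycemia threshold.

    Returns ``None`` for the degenerate request ``p_in_target ~ 1`` (the
    caller should then sample uniformly inside the band).
    """
    if p_in_target >= 0.999:
        return None
    p_ml = min(max(p_mild_low, 1e-9), 0.5)
    z_ml = norm.ppf(p_ml)
    lo, hi = math.log(band[0]), math.log(band[1])
    lmild = math.log(mild_threshold)

    def in_band(sigma: float) -> float:
        mu = lmild - sigma * z_ml
        return norm.cdf((hi - mu) / sigma) - norm.cdf((lo - mu) / sigma)

    def g(sigma: float) -> float:
        return in_band(sigma) - p_in_target

    grid = np.linspace(0.05, 3.0, 120)
    vals = np.array([g(s) for s in grid])
    # pick the widest bracket where the curve crosses zero
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        best = grid[int(np.argmin(np.abs(vals)))]
        sigma = float(best)
    else:
        k = sign_change[-1]
        sigma = float(brentq(g, grid[k], grid[k + 1], xtol=1e-10))
    mu = lmild - sigma * z_ml
    return mu, sigma


def _decay(day_index: np.ndarray, halflife: float) -> np.ndarray:
    if math.isinf(halflife):
        return np.ones_like(day_index, dtype=float)
    return 0.5 ** (day_index / halflife)


def _generate_readings(
    rng: np.random.Generator,
    start_date: datetime,
    n_days: int,
    rate_per_day: np.ndarray,
    behavior: BehaviorParams,
    mu_per_day: Optional[np.ndarray],
    sigma: Optional[float],
    band: Tuple[float, float],
) -> List[Reading]:
    """Draw one participant's readings; order of rng use is fixed for determinism."""
    cells: Dict[Tuple[int, str], Tuple[float, float]] = {}  # (day, context) -> (value, minute jitter)
    for ci, context in enumerate(CONTEXTS):
        p = np.clip(rate_per_day * behavior.context_mix[ci], 0.0, 1.0)
        present = rng.random(n_days) < p
        days = np.nonzero(present)[0]
        if mu_per_day is None:
            values = rng.uniform(band[0], band[1], size=len(days))
        else:
            values = np.exp(rng.standard_normal(len(days)) * sigma + mu_per_day[days])
        values = np.clip(values, 0.3, 39.5)
        jitter = rng.uniform(-10.0, 10.0, size=len(days))
        for d, v, j in zip(days, values, jitter):
            cells[(int(d), context)] = (float(v), float(j))

    if behavior.trend_injection_rate > 0 and n_days >= 3:
        n_trends = rng.poisson(behavior.trend_injection_rate * n_days / 30.0)
        for _ in range(n_trends):
            ci = int(rng.integers(0, len(CONTEXTS)))
            length = int(rng.integers(3, 6))
            length = min(length, n_days)
            d0 = int(rng.integers(0, n_days - length + 1))
            context = CONTEXTS[ci]
            u = rng.uniform(0.0, 1.0, size=length)
            for k in range(length):
                day = d0 + k
                if mu_per_day is None:
                    high = band[1] + 1.0 + 5.0 * u[k]
                else:
                    # a run of unusually high draws from the participant's
                    # own (possibly time-varying) distribution: truncated
                    # log-normal above the target band
                    a = (math.log(band[1]) - mu_per_day[day]) / sigma
                    z = norm.ppf(norm.cdf(a) + u[k] * (1.0 - norm.cdf(a)) * 0.9999)
                    high = math.exp(mu_per_day[day] + sigma * z)
                high = min(max(high, band[1] + 0.1), 39.5)
                key = (day, context)
                j = cells[key][1] if key in cells else 0.0
                cells[key] = (float(high), j)

    readings = []
    for (d, context), (value, jit) in sorted(cells.items(), key=lambda kv: (kv[0][0], CONTEXT_HOURS[kv[0][1]])):
        ts = start_date + timedelta(days=d, hours=CONTEXT_HOURS[context], minutes=jit)
        readings.append(
            Reading(timestamp=ts, value=value, context=context, device_id="sim-meter", source=Source.METER)
        )
    readings.sort(key=lambda r: r.timestamp)
    return readings


def simulate_trace(
    behavior: BehaviorParams,
    days: int,
    seed,
    *,
    start_date: datetime = datetime(2014, 1, 1),
    band: Tuple[float, float] = DEFAULT_BAND,
    availability_fraction: float = 1.0,
) -> Tuple[ReadingWindow, List[date]]:
    """Simulate one participant's readings and upload-day log over *days*.

    Identical seed gives identical output.  When
    ``availability_fraction < 1`` a random complement of readings is hidden
    (emulating a meter left at home on clinic day) and the fraction is
    recorded on the window so downstream counts can correct for it.
    """
    if days < 1:
        raise ValidationError(f"days must be >= 1, got {days}")
    rng = np.random.default_rng(seed)
    day_idx = np.arange(days, dtype=float)
    rate = behavior.smbg_rate * _decay(day_idx, behavior.adherence_halflife_days)

    solved = solve_lognormal(behavior.p_in_target, behavior.p_mild_low, band)
    if solved is None:
        mu_per_day, sigma = None, None
    else:
        mu, sigma = solved
        mu_per_day = np.full(days, mu)

    readings = _generate_readings(rng, start_date, days, rate, behavior, mu_per_day, sigma, band)

    upload_p = np.clip(behavior.upload_prob * _decay(day_idx, behavior.adherence_halflife_days), 0, 1)
    uploaded = rng.random(days) < upload_p
    upload_days = [(start_date + timedelta(days=int(d))).date() for d in np.nonzero(uploaded)[0]]

    if availability_fraction < 1.0:
        keep = rng.random(len(readings)) < availability_fraction
        readings = [r for r, k in zip(readings, keep) if k]

    window = ReadingWindow(
        readings=tuple(readings),
        start_date=start_date,
        end_date=start_date + timedelta(days=days),
        availability_fraction=availability_fraction,
    )
    return window, upload_days


def default_control_behavior() -> BehaviorParams:
    """Usual-care arm: ~3.6 tests/day at enrollment, no app uploads."""
    return BehaviorParams(smbg_rate=3.6, upload_prob=0.0)


def default_intervention_behavior() -> BehaviorParams:
    """App arm: ~4 tests/day at enrollment.

    The median daily sync probability of 0.08 with a between-participant
    log-SD of 1.2 reproduces the heavily skewed engagement profile real
    usage data show: roughly 40% of users below one upload a fortnight and
    under 10% uploading three or more days a week.
    """
    return BehaviorParams(smbg_rate=4.0, upload_prob=0.08)


def _block_randomize(rng: np.random.Generator, n: int) -> List[str]:
    """Arm labels for n participants in one stratum, blocks of 4 or 6."""
    arms: List[str] = []
    while len(arms) < n:
        size = int(rng.choice([4, 6]))
        block = ["intervention"] * (size // 2) + ["control"] * (size // 2)
        rng.shuffle(block)
        arms.extend(block)
    return arms[:n]


def _sci_scores(rng: np.random.Generator) -> float:
    """Draw a plausible SCI response set and score it through the instruments module."""
    spec = sci_spec()
    items = rng.choice([1, 2, 3, 4, 5], size=14, p=[0.05, 0.10, 0.25, 0.35, 0.25])
    responses = ResponseSet("SCI", {iid: int(v) for iid, v in zip(spec.item_ids, items)})
    return score(responses, spec).overall


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    control_behavior: Optional[BehaviorParams] = None,
    intervention_behavior: Optional[BehaviorParams] = None,
    arm_effect: Optional[ArmEffect] = None,
) -> TrialDataset:
    """Simulate a stratified block-randomized two-arm 12-month trial.

    Each participant gets a glucose trace from 50 days before enrollment to
    the 12-month visit; at every scheduled visit the trailing 50-day window
    is cut and the clinical outcome battery (mild hypoglycemia episodes,
    availability-corrected daily SMBG, interview tallies, SCI score) is
    computed by the outcomes machinery — the same code a real download
    would go through.  Visit HbA1c is the eAG mapping of the trailing
    90-day mean glucose plus visit-level noise.

    A per-participant activity multiplier (log-normal, CV ~0.3) scales both
    the testing rate and the upload probability, giving the engagement–SMBG
    coupling seen in real usage data.  ``arm_effect`` perturbs the
    intervention arm generatively (HbA1c slope and/or extra SMBG after
    onset) for parameter-recovery experiments.
    """
    config = config or CohortConfig()
    control_behavior = control_behavior or default_control_behavior()
    intervention_behavior = intervention_behavior or default_intervention_behavior()
    arm_effect = arm_effect or ArmEffect()

    root = np.random.default_rng(config.seed)
    n_total = 2 * config.n_per_arm

    regimens = np.where(root.random(n_total) < 0.5, "pump", "injection")
    sites = np.where(root.random(n_total) < 0.5, "A", "B")
    ages = root.uniform(11.0, 16.0, n_total).round(1)
    hba1c0 = root.uniform(*config.hba1c_range, size=n_total).round(2)

    arms = [""] * n_total
    for regimen in ("pump", "injection"):
        for site in ("A", "B"):
            members = [i for i in range(n_total) if regimens[i] == regimen and sites[i] == site]
            labels = _block_randomize(root, len(members))
            for i, arm in zip(members, labels):
                arms[i] = arm

    participants = [
        Participant(
            id=f"P{i + 1:03d}",
            arm=arms[i],
            regimen=str(regimens[i]),
            site=str(sites[i]),
            age_years=float(ages[i]),
            baseline_hba1c=float(hba1c0[i]),
        )
        for i in range(n_total)
    ]

    lead_in = 50
    trial_days = int(round(max(config.visit_months) * 365 / 12))
    n_days = lead_in + trial_days
    enroll_date = datetime(2014, 1, 1)
    start_date = enroll_date - timedelta(days=lead_in)
    visit_days = {m: int(round(m * 365 / 12)) for m in config.visit_months}
    thresholds = Thresholds()
    band = DEFAULT_BAND

    rows = []
    upload_rows = []
    windows: Dict[str, ReadingWindow] = {}

    for idx, person in enumerate(participants):
        rng = np.random.default_rng([config.seed, idx])
        behavior = intervention_behavior if person.arm == "intervention" else control_behavior

        solved = solve_lognormal(behavior.p_in_target, behavior.p_mild_low, band)
        day_idx = np.arange(n_days, dtype=float)
        activity = float(np.exp(rng.normal(0.0, 0.3)))
        upload_propensity = activity * float(np.exp(rng.normal(0.0, behavior.upload_sd_log)))
        rate = behavior.smbg_rate * activity * _decay(day_idx, behavior.adherence_halflife_days)

        if solved is None:
            mu_per_day, sigma = None, None
        else:
            mu, sigma = solved
            base_mean = math.exp(mu + sigma**2 / 2)
            target_mean0 = hba1c_to_glucose(person.baseline_hba1c)
            mu_i = mu + math.log(target_mean0 / base_mean)
            mu_per_day = np.full(n_days, mu_i)
            if person.arm == "intervention" and arm_effect.delta_hba1c_slope != 0.0:
                # the instantaneous glucose target leads the desired
                # *measured* ramp by half the 90-day averaging window
                # (starting exactly at onset, so baseline is untouched and
                # the measured 12-month change equals the injected slope)
                t_rel = day_idx - lead_in - arm_effect.effect_onset_days
                t_since_onset = np.where(t_rel > 0, t_rel + 45.0, 0.0)
                target_h = person.baseline_hba1c + arm_effect.delta_hba1c_slope * t_since_onset / 365.0
                target_mean = np.maximum(EAG_SLOPE * target_h - EAG_OFFSET, 2.5)
                mu_per_day = mu_i + np.log(target_mean / target_mean0)

        if person.arm == "intervention" and arm_effect.delta_smbg != 0.0:
            onset_mask = day_idx >= lead_in + arm_effect.effect_onset_days
            rate = rate + arm_effect.delta_smbg * onset_mask

        readings = _generate_readings(rng, start_date, n_days, rate, behavior, mu_per_day, sigma, band)

        # upload log (app arm only), over the on-trial days
        if behavior.upload_prob > 0:
            p_up = np.clip(
                behavior.upload_prob * upload_propensity * _decay(np.arange(trial_days, dtype=float), behavior.adherence_halflife_days),
                0,
                1,
            )
            uploaded = rng.random(trial_days) < p_up
            for d in np.nonzero(uploaded)[0]:
                upload_rows.append({"participant": person.id, "date": (enroll_date + timedelta(days=int(d))).date()})

        full = ReadingWindow(tuple(readings), start_date, start_date + timedelta(days=n_days), config.availability_fraction)
        windows[person.id] = full

        values = np.array([r.value for r in readings])
        times = np.array([(r.timestamp - start_date) / timedelta(days=1) for r in readings])

        for month, vday in visit_days.items():
            t_end = lead_in + vday
            visit_window = cut_window(
                readings,
                end_date=start_date + timedelta(days=t_end),
                days=thresholds.window_days,
                availability_fraction=config.availability_fraction,
            )
            mild, _ = count_mild_hypo(visit_window, thresholds)
            smbg = mean_daily_smbg(visit_window, thresholds)
            mask = (times > t_end - 90) & (times <= t_end)
            mean_bg = float(values[mask].mean()) if mask.any() else hba1c_to_glucose(person.baseline_hba1c)
            hba1c = glucose_to_hba1c(min(max(mean_bg, 2.1), 34.9)) + rng.normal(0.0, config.hba1c_noise_sd)
            severe = int(rng.poisson(0.3))
            adjustments = int(rng.poisson(1.8))
            rows.append(
                {
                    "participant": person.id,
                    "arm": person.arm,
                    "regimen": person.regimen,
                    "site": person.site,
                    "age_years": person.age_years,
                    "baseline_hba1c": person.baseline_hba1c,
                    "visit_month": month,
                    "hba1c": round(float(hba1c), 2),
                    "mean_daily_smbg": round(float(smbg), 3),
                    "mild_hypo": mild,
                    "severe_hypo": severe,
                    "adjustments": adjustments,
                    "sci": round(_sci_scores(rng), 2),
                }
            )

    outcomes = pd.DataFrame(rows)
    uploads = pd.DataFrame(upload_rows, columns=["participant", "date"])
    return TrialDataset(
        participants=participants,
        outcomes=outcomes,
        uploads=uploads,
        windows=windows,
        trial_days=trial_days,
    )
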