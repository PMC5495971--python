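"""Design calculations and the trial's statistical analysis plan.

The longitudinal analysis is a linear mixed model with a single
per-participant random intercept, fixed effects for group, visit
(categorical) and their interaction, estimated by restricted maximum
likelihood.  With one variance ratio the REML profile is one-dimensional:
given lambda = sigma_b^2 / sigma_e^2 the fixed effects are closed-form
generalized least squares, so the fit reduces to a scalar optimization.
On complete balanced data this reproduces the classical split-plot
estimates, and Wald tests use containment degrees of freedom (between:
participants minus 2; within: observations minus participants minus the
within-effect count), which makes the group-by-time F test exact in the
balanced compound-symmetric case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .core import DataError, NumericalError, ValidationError
from .rewards import EngagementLevel, classify_engagement

__all__ = [
    "PowerConfig",
    "ModelFit",
    "RegressionResult",
    "SubgroupAnalysis",
    "AssociationResult",
    "required_sample_size",
    "simulated_power",
    "baseline_balance",
    "chi_square_balance",
    "fit_longitudinal",
    "fit_random_intercept",
    "smbg_hba1c_regression",
    "subgroup_high_smbg",
    "engagement_outcome_association",
]


# ---------------------------------------------------------------------------
# design calculations


@dataclass(frozen=True)
class PowerConfig:
    """Two-sample design parameters: 2-sided alpha, power, detectable HbA1c
    difference, outcome SD, and the dropout allowance used for inflation."""

    alpha: float = 0.05
    power: float = 0.80
    detectable_delta: float = 0.5
    sd: float = 0.75
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")
        if self.detectable_delta <= 0 or self.sd <= 0:
            raise ValidationError("detectable_delta and sd must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")


def required_sample_size(cfg: PowerConfig) -> Tuple[int, int]:
    """Per-group n for a two-sample comparison, and the dropout-inflated n.

    ``n = ceil(2 (z_{1-alpha/2} + z_{power})^2 (sd/delta)^2)`` per group;
    the inflated figure divides by ``1 - dropout``.
    """
    z = stats.norm.ppf(1 - cfg.alpha / 2) + stats.norm.ppf(cfg.power)
    n = math.ceil(2.0 * z**2 * (cfg.sd / cfg.detectable_delta) ** 2)
    n = max(n, 1)
    inflated = math.ceil(n / (1.0 - cfg.dropout))
    return n, inflated


def simulated_power(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    reps: int = 5000,
    seed: int = 0,
    test: str = "t",
) -> float:
    """Monte-Carlo power of a two-sample comparison at a given per-group n.

    ``test="t"`` runs the pooled-variance t-test; ``test="z"`` runs the
    known-variance z-test, which is the exact assumption set of the
    normal-quantile design formula (at small n the t-test's power falls a
    fraction of a point below the formula's nominal target).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sd, size=(reps, n_per_group))
    y = rng.normal(delta, sd, size=(reps, n_per_group))
    mx, my = x.mean(axis=1), y.mean(axis=1)
    if test == "z":
        z = (my - mx) / (sd * math.sqrt(2.0 / n_per_group))
        crit = stats.norm.ppf(1 - alpha / 2)
        return float(np.mean(np.abs(z) > crit))
    if test != "t":
        raise ValidationError(f"test must be 't' or 'z', got {test!r}")
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    sp2 = (vx + vy) / 2.0
    t = (my - mx) / np.sqrt(sp2 * 2.0 / n_per_group)
    crit = stats.t.ppf(1 - alpha / 2, df=2 * n_per_group - 2)
    return float(np.mean(np.abs(t) > crit))


# ---------------------------------------------------------------------------
# baseline comparability


def chi_square_balance(table: Sequence[Sequence[int]], correction: bool = False) -> Tuple[float, float]:
    """Chi-square test of independence on a contingency table.

    Continuity correction is off by default (the plain Pearson statistic);
    pass ``correction=True`` for the Yates-corrected 2x2 variant.
    """
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(chi2), float(p)


def _dataset_frame(dataset) -> pd.DataFrame:
    frame = getattr(dataset, "outcomes", dataset)
    if not isinstance(frame, pd.DataFrame):
        raise DataError("expected a TrialDataset or a long-format outcome DataFrame")
    return frame


def baseline_balance(dataset, continuous: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Preliminary between-arm comparisons at the baseline visit.

    Continuous variables get a two-sample pooled t-test; the stratification
    factors (regimen, site) get Pearson chi-square tests without continuity
    correction.  Returns one row per variable with statistic and p-value.
    """
    frame = _dataset_frame(dataset)
    base = frame[frame["visit_month"] == 0]
    if base.empty:
        raise DataError("baseline visit (month 0) missing from dataset")
    groups = [g for _, g in base.groupby(base["arm"] == "intervention")]
    if len(groups) != 2 or min(len(g) for g in groups) < 2:
        raise DataError("baseline balance needs >= 2 participants per arm")
    ctrl = base[base["arm"] == "control"]
    trt = base[base["arm"] == "intervention"]

    if continuous is None:
        candidates = ["age_years", "baseline_hba1c", "hba1c", "mean_daily_smbg", "mild_hypo", "severe_hypo", "adjustments", "sci"]
        continuous = [c for c in candidates if c in base.columns]

    rows = []
    for var in continuous:
        t, p = stats.ttest_ind(trt[var].dropna(), ctrl[var].dropna(), equal_var=True)
        rows.append({"variable": var, "kind": "continuous", "statistic": float(t), "p_value": float(p)})
    for var in ("regimen", "site"):
        if var in base.columns and base[var].nunique() > 1:
            table = pd.crosstab(base["arm"], base[var]).to_numpy()
            chi2, p = chi_square_balance(table, correction=False)
            rows.append({"variable": var, "kind": "categorical", "statistic": chi2, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept REML


@dataclass
class RandomInterceptFit:
    """Raw REML fit: GLS fixed effects plus the two variance components."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_residual: float
    sigma2_participant: float
    lam: float
    n_obs: int
    n_groups: int
    reml_criterion: float


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> RandomInterceptFit:
    """REML fit of ``y = X beta + b_group + e`` with scalar random intercepts.

    Profiles the variance ratio lambda = sigma_b^2/sigma_e^2: for fixed
    lambda the per-group inverse of ``I + lambda J`` is rank-one, so the
    GLS normal equations accumulate in O(n p^2) and the REML criterion is
    minimized over log-lambda with a bounded scalar search (the lambda = 0
    boundary is checked explicitly).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, _ = pd.factorize(groups)
    order = np.argsort(codes, kind="stable")
    X, y, codes = X[order], y[order], codes[order]
    n, p = X.shape
    if n <= p:
        raise NumericalError(f"need more observations ({n}) than fixed-effect columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise NumericalError("singular fixed-effect design matrix")

    starts = np.concatenate(([0], np.nonzero(np.diff(codes))[0] + 1))
    counts = np.diff(np.concatenate((starts, [n]))).astype(float)
    m = len(starts)
    Sx = np.add.reduceat(X, starts, axis=0)  # (m, p) per-group column sums
    Sy = np.add.reduceat(y, starts)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def solve(lam: float):
        c = lam / (1.0 + lam * counts)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        cho = cho_factor(A)
        beta = cho_solve(cho, b)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        yVy = yty - float(np.sum(c * Sy**2))
        rss = max(yVy - float(beta @ b), 1e-300)
        crit = float(np.sum(np.log1p(lam * counts))) + (n - p) * math.log(rss) + logdet_A
        return crit, beta, A, rss

    def criterion(u: float) -> float:
        return solve(math.exp(u))[0]

    res = minimize_scalar(criterion, bounds=(-12.0, 8.0), method="bounded", options={"xatol": 1e-8})
    lam_hat = math.exp(res.x)
    crit_hat = res.fun
    crit0 = solve(0.0)[0]
    if crit0 <= crit_hat:
        lam_hat, crit_hat = 0.0, crit0

    _, beta, A, rss = solve(lam_hat)
    sigma2_e = rss / (n - p)
    cov_beta = sigma2_e * np.linalg.inv(A)
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_residual=sigma2_e,
        sigma2_participant=lam_hat * sigma2_e,
        lam=lam_hat,
        n_obs=n,
        n_groups=m,
        reml_criterion=crit_hat,
    )


@dataclass
class ModelFit:
    """Fitted longitudinal model for one outcome."""

    outcome: str
    terms: List[str]
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    p_values: Dict[str, float]
    sigma2_participant: float
    sigma2_residual: float
    n_obs: int
    n_participants: int
    interaction_f: float
    interaction_df: Tuple[int, int]
    interaction_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.standard_errors,
                "p": self.p_values,
            }
        ).loc[self.terms]


def _design(frame: pd.DataFrame, outcome: str):
    visits = sorted(frame["visit_month"].unique())
    if len(visits) < 2:
        raise DataError("fit_longitudinal needs >= 2 visits")
    group = (frame["arm"] == "intervention").to_numpy(dtype=float)
    for arm in ("intervention", "control"):
        if frame.loc[frame["arm"] == arm, "participant"].nunique() < 2:
            raise DataError(f"fit_longitudinal needs >= 2 participants in the {arm} arm")
    cols = [np.ones(len(frame)), group]
    names = ["intercept", "group"]
    for v in visits[1:]:
        cols.append((frame["visit_month"] == v).to_numpy(dtype=float))
        names.append(f"time[{v}]")
    for v in visits[1:]:
        cols.append(group * (frame["visit_month"] == v).to_numpy(dtype=float))
        names.append(f"group:time[{v}]")
    X = np.column_stack(cols)
    y = frame[outcome].to_numpy(dtype=float)
    return X, y, names, visits


def fit_longitudinal(dataset, outcome: str) -> ModelFit:
    """Random-intercept linear model of one outcome over the visit schedule.

    Fixed effects: group, visit (categorical, baseline reference) and
    group-by-visit interaction.  Missing participant-visits simply
    contribute no row.  The headline treatment test is the joint F on the
    interaction terms.
    """
    frame = _dataset_frame(dataset)
    needed = {"participant", "arm", "visit_month", outcome}
    missing = needed - set(frame.columns)
    if missing:
        raise DataError(f"dataset is missing columns {sorted(missing)}")
    frame = frame.dropna(subset=[outcome])

    X, y, names, visits = _design(frame, outcome)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        stds = X.std(axis=0)
        flat = [nm for nm, s in zip(names, stds) if s == 0 and nm != "intercept"]
        raise NumericalError(
            "singular design" + (f": constant column(s) {flat}" if flat else ": collinear visit/group terms")
        )
    fit = fit_random_intercept(X, y, frame["participant"].to_numpy())

    n, p = fit.n_obs, len(names)
    m = fit.n_groups
    q_within = 2 * (len(visits) - 1)
    df_within = max(n - m - q_within, 1)
    df_between = max(m - 2, 1)

    se = np.sqrt(np.diag(fit.cov_beta))
    estimates, ses, pvals = {}, {}, {}
    for j, nm in enumerate(names):
        df = df_within if "time" in nm else df_between
        tstat = fit.beta[j] / se[j]
        estimates[nm] = float(fit.beta[j])
        ses[nm] = float(se[j])
        pvals[nm] = float(2 * stats.t.sf(abs(tstat), df))

    ix = [j for j, nm in enumerate(names) if nm.startswith("group:time")]
    C = fit.beta[ix]
    covC = fit.cov_beta[np.ix_(ix, ix)]
    fstat = float(C @ np.linalg.solve(covC, C) / len(ix))
    pint = float(stats.f.sf(fstat, len(ix), df_within))

    return ModelFit(
        outcome=outcome,
        terms=names,
        estimates=estimates,
        standard_errors=ses,
        p_values=pvals,
        sigma2_participant=fit.sigma2_participant,
        sigma2_residual=fit.sigma2_residual,
        n_obs=n,
        n_participants=m,
        interaction_f=fstat,
        interaction_df=(len(ix), df_within),
        interaction_p=pint,
    )


# ---------------------------------------------------------------------------
# exploratory analyses


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    se: float
    p_value: float
    n: int


def smbg_hba1c_regression(dataset, arm: str, visit: int) -> RegressionResult:
    """Univariate least squares of HbA1c on daily SMBG in one arm-visit cell."""
    frame = _dataset_frame(dataset)
    cell = frame[(frame["arm"] == arm) & (frame["visit_month"] == visit)].dropna(
        subset=["hba1c", "mean_daily_smbg"]
    )
    if len(cell) < 3:
        raise DataError(f"need >= 3 participants with both measures in {arm}/{visit} mo, got {len(cell)}")
    x = cell["mean_daily_smbg"].to_numpy(dtype=float)
    y = cell["hba1c"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise NumericalError("slope undefined: zero variance in SMBG")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se=float(res.stderr),
        p_value=float(res.pvalue),
        n=len(cell),
    )


@dataclass
class SubgroupAnalysis:
    """Frequent-tester subgroup (daily SMBG >= threshold at the index visit)."""

    threshold: float
    visit: int
    intervention_ids: List[str]
    control_ids: List[str]
    # mean baseline-to-index change in HbA1c within each subgroup, with paired p
    intervention_change: Optional[float] = None
    intervention_change_p: Optional[float] = None
    control_change: Optional[float] = None
    control_change_p: Optional[float] = None
    per_visit_p: Dict[int, float] = field(default_factory=dict)


def _paired_change(frame: pd.DataFrame, ids: Sequence[str], visit: int):
    sub = frame[frame["participant"].isin(ids)]
    base = sub[sub["visit_month"] == 0].set_index("participant")["hba1c"]
    end = sub[sub["visit_month"] == visit].set_index("participant")["hba1c"]
    both = base.index.intersection(end.index)
    if len(both) < 2:
        return None, None
    diff = end.loc[both] - base.loc[both]
    if np.allclose(diff.std(ddof=1), 0):
        return float(diff.mean()), None
    t, p = stats.ttest_rel(end.loc[both], base.loc[both])
    return float(diff.mean()), float(p)


def subgroup_high_smbg(dataset, threshold: float = 5.0, visit: int = 12) -> SubgroupAnalysis:
    """Split out participants testing >= *threshold*/day at the index visit.

    The boundary is inclusive (5.0 exactly is in).  Within each subgroup a
    paired baseline-to-index comparison of HbA1c is run; between subgroups,
    a two-sample t-test per visit.  Empty subgroups are reported as empty.
    """
    frame = _dataset_frame(dataset)
    at_visit = frame[frame["visit_month"] == visit]
    if at_visit.empty:
        raise DataError(f"visit {visit} missing from dataset")
    keep = at_visit[at_visit["mean_daily_smbg"] >= threshold]
    ids_i = sorted(keep.loc[keep["arm"] == "intervention", "participant"])
    ids_c = sorted(keep.loc[keep["arm"] == "control", "participant"])
    out = SubgroupAnalysis(threshold=threshold, visit=visit, intervention_ids=ids_i, control_ids=ids_c)

    out.intervention_change, out.intervention_change_p = _paired_change(frame, ids_i, visit)
    out.control_change, out.control_change_p = _paired_change(frame, ids_c, visit)

    if ids_i and ids_c:
        for v in sorted(frame["visit_month"].unique()):
            a = frame[(frame["participant"].isin(ids_i)) & (frame["visit_month"] == v)]["hba1c"].dropna()
            b = frame[(frame["participant"].isin(ids_c)) & (frame["visit_month"] == v)]["hba1c"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                _, p = stats.ttest_ind(a, b, equal_var=True)
                out.per_visit_p[int(v)] = float(p)
    return out


@dataclass
class AssociationResult:
    crosstab: Dict[str, int]
    slope: Optional[float]
    p_value: Optional[float]
    n: int
    note: str = ""


_LEVEL_ORDER = [
    EngagementLevel.VERY_LOW,
    EngagementLevel.LOW,
    EngagementLevel.MODERATE,
    EngagementLevel.HIGH,
]


def engagement_outcome_association(dataset, uploads: Optional[pd.DataFrame] = None) -> AssociationResult:
    """Engagement level vs mean daily SMBG among app users.

    Classifies each intervention participant from their upload-day count
    over the trial, then tests for a monotone association by regressing the
    participant's mean SMBG on the ordinal engagement score.  With a single
    occupied level the association is undefined and reported as such.
    """
    frame = _dataset_frame(dataset)
    uploads = uploads if uploads is not None else getattr(dataset, "uploads", None)
    if uploads is None:
        raise DataError("no upload log available")
    total_days = int(getattr(dataset, "trial_days", 365))

    users = sorted(frame.loc[frame["arm"] == "intervention", "participant"].unique())
    counts = uploads.groupby("participant")["date"].nunique() if len(uploads) else pd.Series(dtype=int)

    levels, smbg = [], []
    tab = {lv.value: 0 for lv in _LEVEL_ORDER}
    for pid in users:
        lv = classify_engagement(int(counts.get(pid, 0)), total_days)
        tab[lv.value] += 1
        levels.append(_LEVEL_ORDER.index(lv))
        smbg.append(frame.loc[frame["participant"] == pid, "mean_daily_smbg"].mean())

    if len(set(levels)) < 2:
        return AssociationResult(tab, None, None, len(users), note="single engagement level: association undefined")
    res = stats.linregress(np.array(levels, dtype=float), np.array(smbg, dtype=float))
    return AssociationResult(tab, float(res.slope), float(res.pvalue), len(users))
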