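import math

import numpy as np
import pandas as pd
import pytest

from glucolog.core import DataError, NumericalError, ValidationError
from glucolog.synthetic import ArmEffect, CohortConfig, default_control_behavior, simulate_cohort
from glucolog.trial import (
    PowerConfig,
    baseline_balance,
    chi_square_balance,
    engagement_outcome_association,
    fit_longitudinal,
    fit_random_intercept,
    required_sample_size,
    simulated_power,
    smbg_hba1c_regression,
    subgroup_high_smbg,
)


def make_long(m_per_arm, visits=(0, 3, 6, 9, 12), seed=0, tau=0.6, sigma=0.4, group_effect=0.0):
    """Balanced complete null (or shifted) longitudinal dataset."""
    rng = np.random.default_rng(seed)
    ids = [f"P{i:03d}" for i in range(2 * m_per_arm)]
    arms = ["intervention"] * m_per_arm + ["control"] * m_per_arm
    rows = []
    for pid, arm in zip(ids, arms):
        b = rng.normal(0.0, tau)
        for v in visits:
            shift = group_effect * (v / 12) if arm == "intervention" else 0.0
            rows.append(
                {
                    "participant": pid,
                    "arm": arm,
                    "visit_month": v,
                    "hba1c": 9.0 + b + shift + rng.normal(0.0, sigma),
                }
            )
    return pd.DataFrame(rows)


class TestRequiredSampleSize:
    def test_sd_075_needs_36_per_group(self):
        n, inflated = required_sample_size(PowerConfig(sd=0.75))
        assert n == 36
        assert inflated == 48  # ceil(36 / 0.75)

    def test_sd_055_needs_19_per_group(self):
        n, _ = required_sample_size(PowerConfig(sd=0.55))
        assert n == 19

    def test_tiny_sd_floors_at_one(self):
        n, inflated = required_sample_size(PowerConfig(sd=1e-9))
        assert n == 1
        assert inflated >= n

    def test_monotonicity(self):
        n_by_sd = [required_sample_size(PowerConfig(sd=s))[0] for s in (0.5, 0.6, 0.7, 0.75)]
        assert n_by_sd == sorted(n_by_sd)
        n_by_delta = [required_sample_size(PowerConfig(detectable_delta=d))[0] for d in (0.3, 0.5, 0.8)]
        assert n_by_delta == sorted(n_by_delta, reverse=True)
        n_by_alpha = [required_sample_size(PowerConfig(alpha=a))[0] for a in (0.01, 0.05, 0.10)]
        assert n_by_alpha == sorted(n_by_alpha, reverse=True)

    def test_inflation_identity(self):
        for dropout in (0.0, 0.1, 0.25, 0.4):
            n, inflated = required_sample_size(PowerConfig(dropout=dropout))
            assert inflated * (1 - dropout) >= n - 1e-9

    def test_dropout_of_one_rejected(self):
        with pytest.raises(ValidationError):
            PowerConfig(dropout=1.0)

    def test_returned_n_achieves_nominal_power_in_simulation(self):
        cfg = PowerConfig(sd=0.75)
        n, _ = required_sample_size(cfg)
        emp = simulated_power(n, cfg.detectable_delta, cfg.sd, cfg.alpha, reps=4000, seed=0)
        assert emp >= cfg.power - 0.02


class TestBaselineBalance:
    def test_identical_groups_show_no_difference(self):
        ds = make_long(10, seed=1)
        # copy control outcomes onto intervention ids: exact balance
        base = ds[ds["visit_month"] == 0].copy()
        ctrl = base[base["arm"] == "control"]["hba1c"].to_numpy()
        base.loc[base["arm"] == "intervention", "hba1c"] = ctrl
        out = baseline_balance(base)
        t_row = out[out["variable"] == "hba1c"].iloc[0]
        assert t_row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert t_row["p_value"] == pytest.approx(1.0)

    def test_printed_sex_style_split_is_clearly_non_significant(self):
        chi2, p = chi_square_balance([[21, 25], [20, 26]], correction=False)
        assert p > 0.5
        chi2c, pc = chi_square_balance([[21, 25], [20, 26]], correction=True)
        assert pc > 0.99

    def test_missing_baseline_is_error(self):
        ds = make_long(5)
        with pytest.raises(DataError):
            baseline_balance(ds[ds["visit_month"] > 0])


class TestFitLongitudinal:
    def test_matches_dense_gls_oracle_on_balanced_data(self):
        ds = make_long(12, seed=3)
        fit = fit_longitudinal(ds, "hba1c")

        # oracle: dense GLS at the fitted variance components
        visits = sorted(ds["visit_month"].unique())
        group = (ds["arm"] == "intervention").to_numpy(float)
        cols = [np.ones(len(ds)), group]
        for v in visits[1:]:
            cols.append((ds["visit_month"] == v).to_numpy(float))
        for v in visits[1:]:
            cols.append(group * (ds["visit_month"] == v).to_numpy(float))
        X = np.column_stack(cols)
        y = ds["hba1c"].to_numpy(float)
        codes, _ = pd.factorize(ds["participant"])
        Z = np.eye(codes.max() + 1)[codes]
        V = fit.sigma2_residual * np.eye(len(ds)) + fit.sigma2_participant * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        got = np.array([fit.estimates[t] for t in fit.terms])
        assert np.allclose(got, beta, atol=1e-6)

    def test_matches_statsmodels_reml(self):
        sm = pytest.importorskip("statsmodels.api")
        ds = make_long(10, seed=4)
        fit = fit_longitudinal(ds, "hba1c")
        exog = pd.get_dummies(ds["visit_month"].astype("category"), prefix="t", drop_first=True).astype(float)
        exog.insert(0, "group", (ds["arm"] == "intervention").astype(float))
        exog.insert(0, "const", 1.0)
        for c in [c for c in exog.columns if c.startswith("t_")]:
            exog[f"g_{c}"] = exog[c] * exog["group"]
        m = sm.MixedLM(ds["hba1c"], exog, groups=ds["participant"]).fit(reml=True)
        assert m.fe_params["const"] == pytest.approx(fit.estimates["intercept"], abs=1e-4)
        assert m.fe_params["group"] == pytest.approx(fit.estimates["group"], abs=1e-4)
        assert float(m.cov_re.iloc[0, 0]) == pytest.approx(fit.sigma2_participant, rel=1e-3, abs=1e-5)
        assert m.scale == pytest.approx(fit.sigma2_residual, rel=1e-3)

    def test_recovers_injected_group_effect(self):
        # 0.58% decline by 12 months in the intervention arm
        est = []
        for seed in range(40):
            ds = make_long(8, seed=seed, group_effect=-0.58)
            fit = fit_longitudinal(ds, "hba1c")
            est.append(fit.estimates["group:time[12]"])
        se = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(np.mean(est) - (-0.58)) < 3 * se

    def test_handles_missing_visits(self):
        ds = make_long(8, seed=5)
        thinned = ds.drop(ds.sample(frac=0.2, random_state=0).index)
        fit = fit_longitudinal(thinned, "hba1c")
        assert fit.n_obs == len(thinned)

    def test_singular_design_is_diagnosed(self):
        ds = make_long(6, seed=6)
        ds["arm"] = "intervention"
        with pytest.raises((NumericalError, DataError)):
            fit_longitudinal(ds, "hba1c")

    def test_variances_are_nonnegative(self):
        fit = fit_longitudinal(make_long(8, seed=7), "hba1c")
        assert fit.sigma2_participant >= 0
        assert fit.sigma2_residual > 0


class TestRegression:
    def _cell(self, n, slope, seed=0):
        rng = np.random.default_rng(seed)
        smbg = rng.uniform(1, 8, n)
        hba1c = 10.0 + slope * smbg + rng.normal(0, 0.4, n)
        return pd.DataFrame(
            {
                "participant": [f"P{i}" for i in range(n)],
                "arm": "intervention",
                "visit_month": 12,
                "hba1c": hba1c,
                "mean_daily_smbg": smbg,
            }
        )

    def test_recovers_generative_slope(self):
        est = [
            smbg_hba1c_regression(self._cell(46, -0.2, seed=s), "intervention", 12).slope
            for s in range(100)
        ]
        se = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(np.mean(est) - (-0.2)) < 3 * se

    def test_null_p_values_roughly_uniform(self):
        ps = [
            smbg_hba1c_regression(self._cell(30, 0.0, seed=s), "intervention", 12).p_value
            for s in range(300)
        ]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_smbg_variance_is_undefined_slope(self):
        cell = self._cell(5, 0.0)
        cell["mean_daily_smbg"] = 4.0
        with pytest.raises(NumericalError):
            smbg_hba1c_regression(cell, "intervention", 12)

    def test_too_few_points_is_data_error(self):
        with pytest.raises(DataError):
            smbg_hba1c_regression(self._cell(2, 0.0), "intervention", 12)


class TestSubgroup:
    def _dataset(self, smbg):
        rows = []
        for i, s in enumerate(smbg):
            arm = "intervention" if i % 2 == 0 else "control"
            for v in (0, 12):
                rows.append(
                    {
                        "participant": f"P{i}",
                        "arm": arm,
                        "visit_month": v,
                        "hba1c": 9.0 - 0.01 * i + 0.1 * (v == 12),
                        "mean_daily_smbg": s,
                    }
                )
        return pd.DataFrame(rows)

    def test_all_frequent_testers_is_whole_arm(self):
        ds = self._dataset([6.0] * 10)
        sub = subgroup_high_smbg(ds)
        assert len(sub.intervention_ids) == 5
        assert len(sub.control_ids) == 5

    def test_no_frequent_testers_is_empty_not_error(self):
        sub = subgroup_high_smbg(self._dataset([3.0] * 10))
        assert sub.intervention_ids == [] and sub.control_ids == []

    def test_boundary_exactly_five_is_included(self):
        sub = subgroup_high_smbg(self._dataset([5.0, 3.0, 5.0, 3.0]))
        assert len(sub.intervention_ids) == 2


class TestEngagementAssociation:
    def test_uploads_proportional_to_smbg_detected(self):
        # upload frequency exactly proportional to testing rate: the ordinal
        # trend test must find a positive monotone association
        from datetime import date, timedelta

        rows, upload_rows = [], []
        smbg_values = [1 + 7 * i / 23 for i in range(24)]
        for i, s in enumerate(smbg_values):
            pid = f"P{i:02d}"
            for v in (0, 12):
                rows.append(
                    {"participant": pid, "arm": "intervention", "visit_month": v, "hba1c": 9.0, "mean_daily_smbg": s}
                )
            n_uploads = round(365 * s / 14)  # f = smbg/14 spans all four levels
            for d in range(n_uploads):
                upload_rows.append({"participant": pid, "date": date(2014, 1, 1) + timedelta(days=d)})
        res = engagement_outcome_association(pd.DataFrame(rows), pd.DataFrame(upload_rows))
        assert res.slope > 0
        assert res.p_value < 0.01

    def test_single_level_is_undefined(self):
        ds = simulate_cohort(CohortConfig(n_per_arm=4, seed=2))
        ds.uploads = ds.uploads.iloc[0:0]  # nobody ever uploads
        res = engagement_outcome_association(ds)
        assert res.slope is None
        assert "undefined" in res.note
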