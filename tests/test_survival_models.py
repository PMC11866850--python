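"""Cox fitting against brute-force oracles; splines, interaction, PH checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from actifrail.survival_models import (
    AnalysisSpec,
    HazardModelFit,
    fit_cox,
    fit_cox_design,
    joint_group_hrs,
    lrt_interaction,
    ph_check,
    rcs_basis,
    rcs_dose_response,
    reri,
    reri_point,
)
from actifrail.synthetic_cohort import CensoringSpec, GompertzBaseline, simulate_survival


def brute_force_cox_beta(x, time, event):
    """Direct maximisation of the hand-written (tie-free) partial likelihood."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)

    def neg_pl(beta):
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestCoxOracle:
    def test_six_record_fit_matches_brute_force(self):
        """On a tie-free toy dataset the Efron fit equals direct partial-
        likelihood maximisation (no ties, so all tie conventions agree)."""
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        time = np.array([3.0, 1.0, 5.0, 2.0, 7.0, 4.0])
        event = np.array([1, 1, 1, 1, 0, 1], dtype=bool)
        design = pd.DataFrame({"x": x})
        fit = fit_cox_design(design, pd.Series(time), pd.Series(event))
        expected = brute_force_cox_beta(x, time, event)
        assert fit.params["x"] == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_eight_record_random_datasets(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        time = rng.permutation(np.arange(1.0, 9.0))
        event = rng.uniform(size=8) < 0.8
        if event.sum() < 2:
            event[:2] = True
        fit = fit_cox_design(pd.DataFrame({"x": x}), pd.Series(time), pd.Series(event))
        assert fit.params["x"] == pytest.approx(brute_force_cox_beta(x, time, event), abs=1e-4)

    def test_binary_exposure_recovers_true_hr_two(self):
        rng = np.random.default_rng(21)
        x = (rng.uniform(size=20_000) < 0.5).astype(float)
        t, e = simulate_survival(
            np.log(2.0) * x,
            GompertzBaseline(shape=0.0, rate_at_50=0.05),
            CensoringSpec(admin_horizon_years=8.0),
            rng=rng,
        )
        fit = fit_cox_design(pd.DataFrame({"x": x}), pd.Series(t), pd.Series(e))
        assert fit.params["x"] == pytest.approx(np.log(2.0), abs=0.1)

    def test_null_exposure_gives_small_z(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=10_000)
        t, e = simulate_survival(
            np.zeros(10_000),
            GompertzBaseline(shape=0.0, rate_at_50=0.05),
            CensoringSpec(admin_horizon_years=5.0),
            rng=rng,
        )
        fit = fit_cox_design(pd.DataFrame({"x": x}), pd.Series(t), pd.Series(e))
        z = fit.params["x"] / np.sqrt(fit.cov.loc["x", "x"])
        assert abs(z) < 2.5

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox_design(
                pd.DataFrame({"x": [0.0, 1.0]}),
                pd.Series([1.0, 2.0]),
                pd.Series([False, False]),
            )

    def test_covariate_rescaling_leaves_exposure_hr_unchanged(self, small_cohort):
        _, cohort, _ = small_cohort
        spec = AnalysisSpec(exposure="tvpa_mg", adjustment=["age", "townsend"])
        fit1 = fit_cox(cohort, spec)
        rescaled = cohort.copy()
        rescaled["townsend"] = rescaled["townsend"] * 1000.0
        fit2 = fit_cox(rescaled, spec)
        for term in ("tvpa_mg_T2", "tvpa_mg_T3"):
            assert fit1.params[term] == pytest.approx(fit2.params[term], abs=1e-8)


class TestJointGroups:
    def test_table_structure_and_reference(self, small_cohort):
        _, cohort, _ = small_cohort
        table, fit = joint_group_hrs(cohort, AnalysisSpec(exposure="tvpa_mg", fi_form="joint", adjustment=["age"]))
        assert len(table) == 9
        ref = table[table["is_reference"]]
        assert len(ref) == 1
        assert ref.iloc[0]["group"] == "robust|T1"
        assert (ref.iloc[0][["hr", "ci_lo", "ci_hi"]] == 1.0).all()
        assert (table["ci_lo"] <= table["hr"]).all() and (table["hr"] <= table["ci_hi"]).all()

    def test_injected_hrs_inside_wald_cis_mostly(self, small_cohort):
        """Point check on one realisation: at least 7 of 8 injected non-
        reference HRs sit inside their 95% CIs (coverage is checked
        distributionally in the acceptance suite)."""
        _, cohort, truth = small_cohort
        table, _ = joint_group_hrs(cohort, AnalysisSpec(exposure="tvpa_mg", fi_form="joint", adjustment=["age"]))
        covered = 0
        for _, row in table[~table["is_reference"]].iterrows():
            hr = truth.group_hr[row["group"]]
            covered += row["ci_lo"] <= hr <= row["ci_hi"]
        assert covered >= 7

    def test_empty_group_is_named_in_error(self, small_cohort):
        _, cohort, _ = small_cohort
        broken = cohort[~((cohort["fi_category"] == "frail"))]
        with pytest.raises(ValueError, match="frail"):
            joint_group_hrs(broken, AnalysisSpec(exposure="tvpa_mg", fi_form="joint", adjustment=["age"]))

    def test_nine_group_model_fits_no_worse_than_main_effects(self, small_cohort):
        _, cohort, _ = small_cohort
        _, full = joint_group_hrs(cohort, AnalysisSpec(exposure="tvpa_mg", fi_form="joint", adjustment=["age"]))
        reduced = fit_cox(cohort, AnalysisSpec(exposure="tvpa_mg", fi_form="category", adjustment=["age"]))
        assert full.log_likelihood >= reduced.log_likelihood - 1e-9


class TestSplines:
    def test_basis_linear_beyond_boundary_knots(self):
        knots = [10.0, 30.0, 60.0, 90.0]
        beta = np.array([0.03, -0.4, 0.6])
        lo = np.linspace(0, 9, 40)
        hi = np.linspace(91, 130, 40)
        for grid in (lo, hi):
            y = rcs_basis(grid, knots) @ beta
            assert np.allclose(np.diff(y, 2), 0.0, atol=1e-10)

    def test_reference_hr_is_exactly_one(self, small_cohort):
        _, cohort, _ = small_cohort
        spec = AnalysisSpec(exposure="tvpa_mg", exposure_form="spline", adjustment=["age"])
        ref = np.percentile(cohort["tvpa_mg"], 5)
        curve = rcs_dose_response(cohort, spec, grid=np.array([ref, ref + 10.0]))
        assert curve.reference_x == ref
        assert curve.grid["hr"].iloc[0] == 1.0
        assert curve.grid["ci_lo"].iloc[0] == 1.0 and curve.grid["ci_hi"].iloc[0] == 1.0

    def test_log_linear_truth_recovered(self):
        """With a log-linear effect the spline reproduces beta * (x - x_ref)
        across the central mass of the exposure."""
        rng = np.random.default_rng(33)
        n = 20_000
        x = np.clip(rng.normal(38, 12, size=n), 1, None)
        beta = 0.02
        t, e = simulate_survival(
            beta * (x - x.mean()),
            GompertzBaseline(shape=0.0, rate_at_50=0.03),
            CensoringSpec(admin_horizon_years=8.0),
            rng=rng,
        )
        cohort = pd.DataFrame({"xpos": x, "time_months": t, "event": e})
        spec = AnalysisSpec(exposure="xpos", adjustment=[], exposure_form="spline",
                            mutual_adjustment=False)
        inner = np.linspace(np.percentile(x, 5), np.percentile(x, 95), 50)
        curve = rcs_dose_response(cohort, spec, grid=inner)
        expected = beta * (inner - curve.reference_x)
        assert np.max(np.abs(np.log(curve.grid["hr"]) - expected)) < 0.1

    def test_degenerate_exposure_rejected(self):
        cohort = pd.DataFrame(
            {"flat": np.ones(200), "time_months": np.arange(1.0, 201.0), "event": [True] * 200}
        )
        with pytest.raises(ValueError):
            rcs_dose_response(
                cohort,
                AnalysisSpec(exposure="flat", exposure_form="spline", adjustment=[], mutual_adjustment=False),
            )


def _toy_fit(params: dict, cov: np.ndarray | None = None) -> HazardModelFit:
    names = list(params)
    cov = np.zeros((len(names), len(names))) if cov is None else cov
    return HazardModelFit(
        params=pd.Series(params),
        cov=pd.DataFrame(cov, index=names, columns=names),
        log_likelihood=0.0,
        n_events=10,
    )


class TestInteraction:
    def test_lrt_self_comparison_is_null(self, small_cohort):
        _, cohort, _ = small_cohort
        fit = fit_cox(cohort, AnalysisSpec(exposure="tvpa_mg", adjustment=["age"]))
        assert lrt_interaction(fit, fit) == (0.0, 0, 1.0)

    def test_lrt_non_nested_rejected(self, small_cohort):
        _, cohort, _ = small_cohort
        fit_small = fit_cox(cohort, AnalysisSpec(exposure="tvpa_mg", adjustment=["age"]))
        fit_big = fit_cox(cohort, AnalysisSpec(exposure="tvpa_mg", adjustment=["age", "townsend"]))
        with pytest.raises(ValueError):
            lrt_interaction(fit_small, fit_big)

    def test_strong_interaction_detected(self):
        """A cross-product log-HR of 0.7 at n = 20,000 yields a decisive LRT."""
        rng = np.random.default_rng(44)
        n = 20_000
        x = (rng.uniform(size=n) < 0.5).astype(float)
        f = (rng.uniform(size=n) < 0.3).astype(float)
        lp = 0.3 * x + 0.4 * f + 0.7 * x * f
        t, e = simulate_survival(
            lp, GompertzBaseline(shape=0.0, rate_at_50=0.02),
            CensoringSpec(admin_horizon_years=8.0), rng=rng,
        )
        tt, ee = pd.Series(t), pd.Series(e)
        full = fit_cox_design(pd.DataFrame({"x": x, "f": f, "xf": x * f}), tt, ee)
        red = fit_cox_design(pd.DataFrame({"x": x, "f": f}), tt, ee)
        stat, df, p = lrt_interaction(full, red)
        assert df == 1 and p < 0.05

    @pytest.mark.parametrize(
        "hrs,expected",
        [((2.0, 1.5, 4.0), 1.5), ((1.0, 1.0, 1.0), 0.0), ((2.0, 1.5, 3.0), 0.5)],
    )
    def test_reri_arithmetic(self, hrs, expected):
        hr10, hr01, hr11 = hrs
        assert reri_point(hr10, hr01, hr11) == pytest.approx(expected, abs=1e-12)
        fit = _toy_fit({"e": np.log(hr10), "f": np.log(hr01), "ef": np.log(hr11)})
        res = reri(fit, "e", "f", "ef", n_boot=500, seed=0)
        assert res.reri == pytest.approx(expected, abs=1e-12)
        # zero coefficient covariance -> zero-width CI
        assert res.reri_ci_lo == pytest.approx(expected, abs=1e-12)
        assert res.reri_ci_hi == pytest.approx(expected, abs=1e-12)

    def test_reri_missing_term_rejected(self):
        fit = _toy_fit({"e": 0.1})
        with pytest.raises(KeyError):
            reri(fit, "e", "f", "ef")

    def test_reri_bootstrap_seeded(self, small_cohort):
        _, cohort, _ = small_cohort
        _, fit = joint_group_hrs(cohort, AnalysisSpec(exposure="tvpa_mg", fi_form="joint", adjustment=["age"]))
        args = ("jg_robust|T3", "jg_frail|T1", "jg_frail|T3")
        r1 = reri(fit, *args, n_boot=1_000, seed=5)
        r2 = reri(fit, *args, n_boot=1_000, seed=5)
        assert (r1.reri_ci_lo, r1.reri_ci_hi) == (r2.reri_ci_lo, r2.reri_ci_hi)
        assert r1.reri_ci_lo <= r1.reri <= r1.reri_ci_hi


class TestPHCheck:
    def test_p_values_in_unit_interval(self, small_cohort):
        _, cohort, _ = small_cohort
        fit = fit_cox(cohort, AnalysisSpec(exposure="tvpa_mg", adjustment=["age", "sex"]))
        diag = ph_check(fit)
        assert ((diag.per_term["p"] >= 0) & (diag.per_term["p"] <= 1)).all()
        assert 0 <= diag.global_p <= 1

    def test_reversing_effect_flagged(self):
        """A covariate whose effect flips sign over follow-up violates PH and
        the scaled-Schoenfeld test detects it."""
        n = 10_000
        rng = np.random.default_rng(55)
        x = (rng.uniform(size=n) < 0.5).astype(float)
        lp_early = 0.9 * x
        t1, e1 = simulate_survival(
            lp_early, GompertzBaseline(shape=0.0, rate_at_50=0.08),
            CensoringSpec(admin_horizon_years=4.0), rng=rng,
        )
        # survivors continue with the effect reversed
        alive = ~e1
        t2, e2 = simulate_survival(
            -0.9 * x[alive], GompertzBaseline(shape=0.0, rate_at_50=0.08),
            CensoringSpec(admin_horizon_years=4.0), rng=rng,
        )
        time = t1.copy()
        event = e1.copy()
        time[alive] = 48.0 + t2
        event[alive] = e2
        fit = fit_cox_design(pd.DataFrame({"x": x}), pd.Series(time), pd.Series(event))
        diag = ph_check(fit)
        assert diag.per_term.loc["x", "p"] < 0.05

    def test_too_few_events_rejected(self):
        fit = fit_cox_design(
            pd.DataFrame({"x": [0.0, 1.0, 0.5]}),
            pd.Series([1.0, 2.0, 3.0]),
            pd.Series([True, False, False]),
        )
        with pytest.raises(ValueError):
            ph_check(fit)
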