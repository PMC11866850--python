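"""Life-table construction, exactness identities and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from actifrail.life_expectancy import (
    AGES,
    GroupSpec,
    bootstrap_le_ci,
    build_life_tables,
    groups_from_cohort,
    le_difference,
    le_from_hrs,
    synthetic_population_rates,
    validate_population_rates,
)
from actifrail.survival_models import HazardModelFit


def constant_rate_pop(m: float, sex: str = "men") -> pd.DataFrame:
    return pd.DataFrame({"sex": sex, "age": AGES, "rate": m})


def toy_fit(params: dict, cov: np.ndarray) -> HazardModelFit:
    names = list(params)
    return HazardModelFit(
        params=pd.Series(params),
        cov=pd.DataFrame(cov, index=names, columns=names),
        log_likelihood=0.0,
        n_events=100,
    )


class TestGroupSpec:
    def test_prevalences_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            GroupSpec(["robust|T1", "b"], [0.6, 0.6], [1.0, 2.0])

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec(["robust|T1", "b"], [0.5, 0.5], [1.0, -2.0])

    def test_reference_must_have_unit_hr(self):
        with pytest.raises(ValueError):
            GroupSpec(["robust|T1", "b"], [0.5, 0.5], [1.5, 2.0])


class TestBuildLifeTables:
    def test_unit_hrs_reproduce_population_table(self):
        pop = synthetic_population_rates()
        groups = GroupSpec(["robust|T1", "g2", "g3"], [0.5, 0.3, 0.2], [1.0, 1.0, 1.0])
        tables = build_life_tables(pop, groups, "women")
        m_pop = pop[pop["sex"] == "women"].sort_values("age")["rate"].to_numpy()
        les = {k: t.le_at_50 for k, t in tables.items()}
        for t in tables.values():
            assert np.allclose(t.m, m_pop, rtol=0, atol=0)
        assert len(set(np.round(list(les.values()), 12))) == 1

    def test_reference_rate_backcalculation(self):
        pop = constant_rate_pop(0.01)
        groups = GroupSpec(["robust|T1", "g2"], [0.5, 0.5], [1.0, 2.0])
        tables = build_life_tables(pop, groups, "men")
        assert np.allclose(tables["robust|T1"].m, 0.01 / 1.5)
        assert np.allclose(tables["g2"].m, 0.02 / 1.5)

    def test_prevalence_weighted_rates_match_population_exactly(self):
        pop = synthetic_population_rates()
        rng = np.random.default_rng(8)
        hr = np.concatenate([[1.0], np.exp(rng.normal(0, 0.5, size=8))])
        p = rng.dirichlet(np.ones(9))
        groups = GroupSpec([f"g{i}" for i in range(9)], p, hr, reference="g0")
        tables = build_life_tables(pop, groups, "men")
        m_pop = pop[pop["sex"] == "men"].sort_values("age")["rate"].to_numpy()
        mixed = sum(p_g * tables[g].m for g, p_g in zip(groups.labels, p))
        assert np.max(np.abs(mixed - m_pop)) < 1e-15 * m_pop.max() * 10

    def test_constant_hazard_matches_geometric_series(self):
        """Closed-form oracle: with constant m and hr = 1 the LE at 50 is
        sum_{k=0..50} e^{-mk} (1 - (1 - e^{-m})/2), to 1e-10."""
        m = 0.02
        pop = constant_rate_pop(m)
        groups = GroupSpec(["robust|T1"], [1.0], [1.0])
        le = build_life_tables(pop, groups, "men")["robust|T1"].le_at_50
        k = np.arange(0, 51)
        expected = np.sum(np.exp(-m * k) * (1 - 0.5 * (1 - np.exp(-m))))
        assert le == pytest.approx(expected, abs=1e-10)

    def test_continuous_time_oracle_constant_hazard(self):
        """Discrete LE within 0.05 y of the analytic integral of e^{-mt}
        over the 51-year closed horizon."""
        for m in (0.005, 0.02, 0.08):
            pop = constant_rate_pop(m)
            le = build_life_tables(pop, GroupSpec(["robust|T1"], [1.0], [1.0]), "men")[
                "robust|T1"
            ].le_at_50
            analytic = (1 - np.exp(-m * 51)) / m
            assert abs(le - analytic) < 0.05

    def test_extreme_rates_drive_le_to_zero(self):
        pop = constant_rate_pop(50.0)
        le = build_life_tables(pop, GroupSpec(["robust|T1"], [1.0], [1.0]), "men")[
            "robust|T1"
        ].le_at_50
        assert le < 0.6  # only the first half-year of person-time survives

    def test_le_strictly_decreasing_in_hr(self):
        pop = synthetic_population_rates()
        groups = GroupSpec(
            ["robust|T1", "g2", "g3", "g4"], [0.25] * 4, [1.0, 1.3, 1.9, 2.6]
        )
        tables = build_life_tables(pop, groups, "men")
        les = [tables[g].le_at_50 for g in groups.labels]
        assert all(a > b for a, b in zip(les, les[1:]))

    def test_survivorship_monotone_and_q_bounded(self):
        pop = synthetic_population_rates()
        t = build_life_tables(pop, GroupSpec(["robust|T1"], [1.0], [1.0]), "women")["robust|T1"]
        assert (np.diff(t.l) <= 0).all()
        assert ((t.q >= 0) & (t.q <= 1)).all()
        assert t.ages[0] == 50 and t.ages[-1] == 100

    def test_invalid_population_table_rejected(self):
        pop = synthetic_population_rates()
        with pytest.raises(ValueError):
            validate_population_rates(pop[pop["age"] > 60])


class TestLEDifference:
    def test_reference_delta_zero_and_monotone_in_hr(self):
        pop = synthetic_population_rates()
        groups = GroupSpec(["robust|T1", "a", "b"], [0.4, 0.3, 0.3], [1.0, 1.5, 2.5])
        tables = build_life_tables(pop, groups, "men")
        diff = le_difference(tables, "robust|T1").set_index("group")
        assert diff.loc["robust|T1", "delta_years"] == 0.0
        assert diff.loc["b", "delta_years"] > diff.loc["a", "delta_years"] > 0

    def test_unknown_reference_rejected(self):
        pop = synthetic_population_rates()
        tables = build_life_tables(pop, GroupSpec(["robust|T1"], [1.0], [1.0]), "men")
        with pytest.raises(KeyError):
            le_difference(tables, "nope")

    def test_uniform_hr_doubling_shifts_only_via_renormalisation(self):
        """Doubling every HR with fixed prevalences leaves the adjusted rates
        unchanged (the reference-rate renormalisation absorbs the scale), so
        all deltas are unchanged — verified against direct recomputation."""
        pop = synthetic_population_rates()
        hr = np.array([1.0, 1.4, 2.2])
        p = np.array([0.5, 0.3, 0.2])
        t1 = build_life_tables(pop, GroupSpec(["robust|T1", "a", "b"], p, hr), "men")
        m_pop = pop[pop["sex"] == "men"].sort_values("age")["rate"].to_numpy()
        le_a = le_from_hrs(m_pop, p, hr)
        le_b = le_from_hrs(m_pop, p, 2 * hr)
        assert np.allclose(le_a, le_b, atol=1e-12)
        d1 = le_difference(t1, "robust|T1")["delta_years"].to_numpy()
        assert np.allclose((le_b[0] - le_b), d1, atol=1e-12)


class TestBootstrap:
    POP = synthetic_population_rates()

    def _groups(self):
        return GroupSpec(["robust|T1", "a", "b"], [0.5, 0.3, 0.2], [1.0, 1.5, 2.0])

    def test_zero_covariance_gives_zero_width(self):
        fit = toy_fit({"jg_a": np.log(1.5), "jg_b": np.log(2.0)}, np.zeros((2, 2)))
        out = bootstrap_le_ci(fit, self.POP, self._groups(), "men", n_runs=200, seed=1)
        assert np.allclose(out["ci_lo"], out["delta_years"])
        assert np.allclose(out["ci_hi"], out["delta_years"])

    def test_same_seed_identical_cis(self):
        cov = np.array([[0.02, 0.005], [0.005, 0.03]])
        fit = toy_fit({"jg_a": np.log(1.5), "jg_b": np.log(2.0)}, cov)
        o1 = bootstrap_le_ci(fit, self.POP, self._groups(), "men", n_runs=500, seed=9)
        o2 = bootstrap_le_ci(fit, self.POP, self._groups(), "men", n_runs=500, seed=9)
        pd.testing.assert_frame_equal(o1, o2)

    def test_point_estimate_matches_direct_tables(self):
        cov = np.eye(2) * 0.01
        fit = toy_fit({"jg_a": np.log(1.5), "jg_b": np.log(2.0)}, cov)
        out = bootstrap_le_ci(fit, self.POP, self._groups(), "men", n_runs=200, seed=2)
        tables = build_life_tables(self.POP, self._groups(), "men")
        direct = le_difference(tables, "robust|T1").set_index("group")
        merged = out.set_index("group")
        assert np.allclose(merged["delta_years"], direct.loc[merged.index, "delta_years"])

    def test_too_few_runs_rejected(self):
        fit = toy_fit({"jg_a": 0.0, "jg_b": 0.0}, np.zeros((2, 2)))
        with pytest.raises(ValueError):
            bootstrap_le_ci(fit, self.POP, self._groups(), "men", n_runs=50, seed=1)

    def test_ci_contains_point_estimate(self):
        cov = np.array([[0.05, 0.0], [0.0, 0.08]])
        fit = toy_fit({"jg_a": np.log(1.5), "jg_b": np.log(2.0)}, cov)
        out = bootstrap_le_ci(fit, self.POP, self._groups(), "men", n_runs=300, seed=3)
        assert ((out["ci_lo"] <= out["delta_years"]) & (out["delta_years"] <= out["ci_hi"])).all()


class TestGroupsFromCohort:
    def test_prevalences_are_observed_frequencies(self):
        labels = pd.Series(["robust|T1"] * 6 + ["a"] * 3 + ["b"])
        hr_table = pd.DataFrame(
            {"group": ["robust|T1", "a", "b"], "hr": [1.0, 1.5, 2.0]}
        )
        g = groups_from_cohort(pd.DataFrame(), labels, hr_table)
        assert np.allclose(g.prevalence, [0.6, 0.3, 0.1])
        assert g.reference == "robust|T1"
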