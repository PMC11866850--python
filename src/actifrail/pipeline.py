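"""End-to-end orchestration: exclusions, imputation, models, life tables.

The pipeline mirrors the analysis flow of the study design: generate (or
load) a cohort -> apply the exclusion cascade -> score the frailty index ->
derive exposures and tertiles -> impute covariates -> fit the joint,
spline and interaction models with PH diagnostics -> build life tables with
bootstrap CIs -> write every table plus the resolved configuration to an
output directory.  Re-running with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import exposures as expo_mod
from . import life_expectancy as le_mod
from . import survival_models as sm
from .frailty_index import default_codebook
from .synthetic_cohort import GeneratorConfig, generate_cohort

EXPOSURE_COLUMNS = ("tvpa_mg", "mvpa_h_day", "lpa_h_day", "st_h_day")

#: covariate columns eligible for imputation (never outcome/exposure/deficits)
IMPUTABLE_COVARIATES = [
    "bmi_category", "ethnicity", "education", "employment", "income",
    "townsend", "smoking", "alcohol", "sleep_duration", "diet_score",
    "famhx_diabetes", "famhx_cvd", "famhx_cancer", "season", "assessment_center",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def _rule_invalid_wear(c: pd.DataFrame) -> pd.Series:
    return c["wear_valid"].astype(bool)


def _rule_incomplete_fi(c: pd.DataFrame) -> pd.Series:
    return c["fi"].notna()


def _rule_missing_mortality(c: pd.DataFrame) -> pd.Series:
    return c["mortality_known"].astype(bool) if "mortality_known" in c else pd.Series(True, index=c.index)


def _rule_age_under_45(c: pd.DataFrame) -> pd.Series:
    return c["age"] >= 45.0


def _rule_landmark_2y(c: pd.DataFrame) -> pd.Series:
    return ~(c["event"].astype(bool) & (c["time_months"] < 24.0))


def _rule_shift_workers(c: pd.DataFrame) -> pd.Series:
    return ~c["shift_worker"].astype(bool)


EXCLUSION_RULES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "invalid_wear": _rule_invalid_wear,
    "incomplete_fi": _rule_incomplete_fi,
    "missing_mortality": _rule_missing_mortality,
    "age_under_45": _rule_age_under_45,
    "landmark_2y": _rule_landmark_2y,
    "shift_workers": _rule_shift_workers,
}

#: the study's main exclusion cascade, in flowchart order
DEFAULT_EXCLUSION_ORDER = ["invalid_wear", "incomplete_fi", "missing_mortality", "age_under_45"]


def apply_exclusions(
    cohort: pd.DataFrame, rules: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply named exclusion rules in order; return the kept cohort and a
    telescoping log (rule, n_before, n_removed, n_after)."""
    log_rows = []
    current = cohort
    for rule in rules:
        if rule not in EXCLUSION_RULES:
            raise KeyError(f"unknown exclusion rule {rule!r}")
        keep = EXCLUSION_RULES[rule](current)
        n_before = len(current)
        current = current.loc[keep]
        log_rows.append(
            {
                "rule": rule,
                "n_before": n_before,
                "n_removed": n_before - len(current),
                "n_after": len(current),
            }
        )
    return current.copy(), pd.DataFrame(log_rows, columns=["rule", "n_before", "n_removed", "n_after"])


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_covariates(
    cohort: pd.DataFrame,
    method: str = "simple",
    seed: int | None = None,
    *,
    covariate_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fill missing covariate values; outcome and exposures are never imputed.

    ``simple`` fills categoricals with the observed mode and numerics with
    the median.  ``forest-iterative`` runs chained tree-ensemble imputation
    (iterative imputer with extra-trees regressors on integer-coded
    categoricals, decoded by rounding), seeded.
    """
    protected = ["time_months", "event", *EXPOSURE_COLUMNS]
    present = [c for c in protected if c in cohort.columns]
    if present and cohort[present].isna().any().any():
        bad = [c for c in present if cohort[c].isna().any()]
        raise ValueError(f"missing values in outcome/exposure columns {bad}; these are never imputed")
    cols = [c for c in (covariate_cols or IMPUTABLE_COVARIATES) if c in cohort.columns]
    out = cohort.copy()
    if not out[cols].isna().any().any():
        return out
    if method == "simple":
        for c in cols:
            col = out[c]
            if not col.isna().any():
                continue
            if col.dtype.kind in "fiu":
                out[c] = col.fillna(col.median())
            else:
                out[c] = col.fillna(col.mode(dropna=True).iloc[0])
        return out
    if method == "forest-iterative":
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
        from sklearn.ensemble import ExtraTreesRegressor

        codes = pd.DataFrame(index=out.index)
        decoders: dict[str, pd.Index] = {}
        for c in cols:
            col = out[c]
            if col.dtype.kind in "fiu":
                codes[c] = col.astype(float)
            else:
                cat = pd.Categorical(col)
                decoders[c] = cat.categories
                codes[c] = np.where(col.isna(), np.nan, cat.codes.astype(float))
        imputer = IterativeImputer(
            estimator=ExtraTreesRegressor(n_estimators=10, random_state=seed),
            max_iter=5,
            random_state=seed,
            sample_posterior=False,
        )
        filled = pd.DataFrame(imputer.fit_transform(codes), columns=codes.columns, index=out.index)
        for c in cols:
            if c in decoders:
                idx = np.clip(np.round(filled[c]).astype(int), 0, len(decoders[c]) - 1)
                out[c] = pd.Series(decoders[c][idx], index=out.index).where(
                    True, other=None
                )
            else:
                out[c] = filled[c]
        return out
    raise ValueError(f"unknown imputation method {method!r}")


# ---------------------------------------------------------------------------
# run configuration + pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_path: str | None = None  # load instead of generate
    output_dir: str = "actifrail_out"
    awake_window: str = "06:00-22:00"
    exposures: Sequence[str] = EXPOSURE_COLUMNS
    adjustment: Sequence[str] = field(default_factory=lambda: list(sm.DEFAULT_ADJUSTMENT))
    seed: int = 2025
    bootstrap_runs: int = 1_000
    impute_method: str = "simple"
    complete_case: bool = False  # sensitivity: drop rather than impute
    landmark_exclusion: bool = False  # sensitivity: drop deaths in first 2 y
    exclude_shift_workers: bool = False
    mutual_mvpa_lpa: bool = False
    run_splines: bool = True
    spline_min_events: int = 50
    life_expectancy_rates: pd.DataFrame | None = None  # defaults to synthetic table

    def exclusion_order(self) -> list[str]:
        rules = list(DEFAULT_EXCLUSION_ORDER)
        if self.landmark_exclusion:
            rules.append("landmark_2y")
        if self.exclude_shift_workers:
            rules.append("shift_workers")
        return rules

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["exposure_corr"] = np.asarray(
            d["generator"]["exposure_corr"]
        ).tolist()
        d.pop("life_expectancy_rates", None)
        d["exclusion_order"] = self.exclusion_order()
        return d


@dataclass
class ReportBundle:
    output_dir: str
    exclusion_log: pd.DataFrame
    cohort: pd.DataFrame
    joint_tables: dict[str, pd.DataFrame]
    spline_curves: dict[str, pd.DataFrame]
    interactions: dict[str, dict]
    ph_diagnostics: dict[str, dict]
    life_expectancy: dict[str, pd.DataFrame]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write all outputs under ``output_dir``."""
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda *p: os.path.join(config.output_dir, *p)
    window = expo_mod.AwakeWindow.parse(config.awake_window)

    # --- generate or load ---------------------------------------------------
    if config.cohort_path is not None:
        cohort = _stage("load")(pd.read_csv, config.cohort_path)
        epochs = pd.DataFrame(columns=expo_mod.EPOCH_COLUMNS)
    else:
        cohort, epochs, truth = _stage("generate")(generate_cohort, config.generator)
        truth.to_json(out("true_effects.json"))
    default_codebook().to_json(out("codebook.json"))

    # --- epoch aggregation (subsample with epochs) --------------------------
    if len(epochs):
        summaries = _stage("aggregate")(expo_mod.aggregate_cohort, epochs, window)
        summaries.to_csv(out("exposure_summaries.csv"), index=False)

    # --- exclusions ----------------------------------------------------------
    cohort, log = _stage("exclusions")(apply_exclusions, cohort, config.exclusion_order())
    log.to_csv(out("exclusion_log.csv"), index=False)

    # --- imputation / complete case -----------------------------------------
    cols = [c for c in IMPUTABLE_COVARIATES if c in cohort.columns]
    if config.complete_case:
        cohort = cohort.dropna(subset=cols)
    else:
        cohort = _stage("imputation")(
            impute_covariates, cohort, config.impute_method, config.seed
        )
    cohort.to_csv(out("cohort_analyzed.csv"), index=False)

    # --- tertiles ------------------------------------------------------------
    cuts = {}
    for exp in config.exposures:
        scheme, _ = expo_mod.assign_tertiles(cohort[exp].to_numpy(), exposure=exp)
        cuts[exp] = {"cut_lo": scheme.cut_lo, "cut_hi": scheme.cut_hi}
    with open(out("tertile_cuts.json"), "w") as fh:
        json.dump(cuts, fh, indent=1)

    # --- models per exposure --------------------------------------------------
    joint_tables, spline_curves, interactions, ph_diag = {}, {}, {}, {}
    joint_fits = {}
    for exp in config.exposures:
        spec = sm.AnalysisSpec(
            exposure=exp,
            fi_form="joint",
            adjustment=config.adjustment,
            mutual_mvpa_lpa=config.mutual_mvpa_lpa,
        )
        table, fit = _stage(f"joint:{exp}")(joint := sm.joint_group_hrs, cohort, spec)
        table.to_csv(out(f"joint_hr_{exp}.csv"), index=False)
        joint_tables[exp] = table
        joint_fits[exp] = fit

        # multiplicative interaction: tertile x FI cross-product LRT
        spec_main = dataclasses.replace(spec, fi_form="category")
        fit_red = _stage(f"lrt:{exp}")(sm.fit_cox, cohort, spec_main)
        stat, dof, p = sm.lrt_interaction(fit, fit_red)
        # additive interaction for the frail x low-activity contrast
        res = {"lrt_stat": stat, "lrt_df": dof, "lrt_p": p, "reri": {}}
        for cat in ("pre_frail", "frail"):
            for t in (2, 3):
                terms = (f"jg_robust|T{t}", f"jg_{cat}|T1", f"jg_{cat}|T{t}")
                try:
                    r = sm.reri(fit, *terms, seed=config.seed, n_boot=config.bootstrap_runs)
                    res["reri"][f"{cat}|T{t}"] = {
                        "reri": r.reri, "ci_lo": r.reri_ci_lo, "ci_hi": r.reri_ci_hi,
                    }
                except KeyError:
                    continue
        interactions[exp] = res
        with open(out(f"interaction_{exp}.json"), "w") as fh:
            json.dump(res, fh, indent=1)

        diag = _stage(f"ph:{exp}")(sm.ph_check, fit)
        ph_payload = {
            "global_stat": diag.global_stat,
            "global_p": diag.global_p,
            "per_term_p": diag.per_term["p"].to_dict(),
        }
        ph_diag[exp] = ph_payload
        with open(out(f"ph_{exp}.json"), "w") as fh:
            json.dump(ph_payload, fh, indent=1)

        if config.run_splines:
            for cat in ("robust", "pre_frail", "frail"):
                try:
                    curve = sm.rcs_dose_response(
                        cohort,
                        dataclasses.replace(spec, fi_form="category", exposure_form="spline"),
                        fi_subset=cat,
                        min_events=config.spline_min_events,
                    )
                except ValueError:
                    continue  # stratum too small for a stable curve
                curve.grid.to_csv(out(f"spline_{exp}_{cat}.csv"), index=False)
                spline_curves[f"{exp}|{cat}"] = curve.grid

    # --- life expectancy ------------------------------------------------------
    rates = (
        config.life_expectancy_rates
        if config.life_expectancy_rates is not None
        else le_mod.synthetic_population_rates()
    )
    life = {}
    for exp in config.exposures:
        for sex in ("women", "men"):
            sub = cohort[cohort["sex"] == sex]
            spec = sm.AnalysisSpec(
                exposure=exp,
                fi_form="joint",
                adjustment=[c for c in config.adjustment if c != "sex"],
                mutual_mvpa_lpa=config.mutual_mvpa_lpa,
            )
            table, fit = _stage(f"le_fit:{exp}:{sex}")(sm.joint_group_hrs, sub, spec)
            labels = sm.joint_group_labels(sub, exp)
            groups = le_mod.groups_from_cohort(sub, labels, table)
            le = _stage(f"le_bootstrap:{exp}:{sex}")(
                le_mod.bootstrap_le_ci,
                fit,
                rates,
                groups,
                sex,
                n_runs=config.bootstrap_runs,
                seed=config.seed,
            )
            le.to_csv(out(f"life_expectancy_{exp}_{sex}.csv"), index=False)
            life[f"{exp}|{sex}"] = le

    with open(out("config_resolved.json"), "w") as fh:
        json.dump(config.resolved(), fh, indent=1, default=str)

    return ReportBundle(
        output_dir=config.output_dir,
        exclusion_log=log,
        cohort=cohort,
        joint_tables=joint_tables,
        spline_curves=spline_curves,
        interactions=interactions,
        ph_diagnostics=ph_diag,
        life_expectancy=life,
    )
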