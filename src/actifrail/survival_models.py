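"""Proportional-hazards modelling of mortality against activity and frailty.

All models are Cox partial-likelihood fits on follow-up time (months) with
Efron handling of tied event times (month-resolution follow-up produces many
ties).  The module covers the analyses of the study design it implements:

* adjusted hazard ratios for exposure tertiles and frailty categories,
* the 9-group joint analysis (3 FI categories x 3 exposure tertiles,
  robust x tertile-1 as reference),
* restricted cubic spline dose–response curves (4 knots at the
  5/35/65/95th percentiles, HR referenced to the 5th percentile),
* multiplicative (likelihood-ratio) and additive (RERI) interaction,
* scaled-Schoenfeld proportional-hazards diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .exposures import assign_tertiles

Z95 = stats.norm.ppf(0.975)

#: adjustment set used by the fully adjusted models (columns of the cohort)
DEFAULT_ADJUSTMENT = [
    "age", "sex", "assessment_center", "bmi_category", "ethnicity", "education",
    "employment", "income", "townsend", "smoking", "alcohol", "sleep_duration",
    "diet_score", "famhx_diabetes", "famhx_cvd", "famhx_cancer", "season",
    "n_wear_days",
]

#: mutual-adjustment rule: the ST model adds MVPA, the MVPA and LPA models
#: add ST, and the TVPA model adds nothing.
MUTUAL_ADJUSTMENT = {
    "tvpa_mg": None,
    "mvpa_h_day": "st_h_day",
    "lpa_h_day": "st_h_day",
    "st_h_day": "mvpa_h_day",
}

FI_LEVELS = ("robust", "pre_frail", "frail")


@dataclass
class AnalysisSpec:
    """Declarative description of one Cox analysis."""

    exposure: str = "tvpa_mg"
    exposure_form: str = "tertile"  # "tertile" | "spline"
    fi_form: str = "category"  # "category" | "joint"
    adjustment: Sequence[str] = field(default_factory=lambda: list(DEFAULT_ADJUSTMENT))
    mutual_adjustment: bool = True
    mutual_mvpa_lpa: bool = False  # sensitivity: also cross-adjust MVPA<->LPA
    duration_col: str = "time_months"
    event_col: str = "event"

    def mutual_terms(self) -> list[str]:
        terms = []
        if self.mutual_adjustment:
            extra = MUTUAL_ADJUSTMENT.get(self.exposure)
            if extra:
                terms.append(extra)
        if self.mutual_mvpa_lpa:
            if self.exposure == "mvpa_h_day":
                terms.append("lpa_h_day")
            elif self.exposure == "lpa_h_day":
                terms.append("mvpa_h_day")
        return terms


@dataclass
class HazardModelFit:
    """Cox fit: coefficients, covariance, log-likelihood.

    ``params`` are log hazard ratios; ``cov`` is the inverse-information
    covariance of the coefficient vector.
    """

    params: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    n_events: int
    ties_method: str = "efron"
    _fitter: CoxPHFitter | None = field(default=None, repr=False, compare=False)
    _df: pd.DataFrame | None = field(default=None, repr=False, compare=False)
    duration_col: str = "time_months"
    event_col: str = "event"

    def hr(self) -> pd.Series:
        return np.exp(self.params)

    def wald_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame(
            {
                "hr": np.exp(self.params),
                "ci_lo": np.exp(self.params - z * se),
                "ci_hi": np.exp(self.params + z * se),
            },
            index=self.params.index,
        )


@dataclass
class SplineCurve:
    exposure: str
    knots: np.ndarray
    reference_x: float
    grid: pd.DataFrame  # columns x, hr, ci_lo, ci_hi
    fit: HazardModelFit


@dataclass
class InteractionResult:
    lrt_stat: float = float("nan")
    lrt_df: int = 0
    lrt_p: float = float("nan")
    reri: float = float("nan")
    reri_ci_lo: float = float("nan")
    reri_ci_hi: float = float("nan")


@dataclass
class PHDiagnostic:
    per_term: pd.DataFrame  # columns stat, p
    global_stat: float
    global_p: float


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _encode_covariates(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """One-hot (drop-first) categorical covariates; continuous pass through."""
    if not columns:
        return pd.DataFrame(index=cohort.index)
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks covariate columns: {missing}")
    block = cohort[list(columns)]
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"missing values in modelled columns {bad}; impute upstream")
    num = block.select_dtypes(include=[np.number, bool]).astype(float)
    cat = block.drop(columns=num.columns)
    parts = [num]
    if len(cat.columns):
        parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def fit_cox_design(
    design: pd.DataFrame,
    durations: pd.Series,
    events: pd.Series,
    *,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> HazardModelFit:
    """Fit a Cox model on an explicit design matrix (Efron ties)."""
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("no events in the data")
    df = design.copy()
    df[duration_col] = durations.to_numpy(dtype=float)
    df[event_col] = events.to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col=duration_col,
            event_col=event_col,
            fit_options={"precision": 1e-9, "max_steps": 500},
        )
    except Exception as exc:  # lifelines raises on separation / collinearity
        raise ValueError(f"Cox fit failed ({exc})") from exc
    return HazardModelFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        log_likelihood=float(cph.log_likelihood_),
        n_events=n_events,
        _fitter=cph,
        _df=df,
        duration_col=duration_col,
        event_col=event_col,
    )


def _exposure_terms(cohort: pd.DataFrame, spec: AnalysisSpec) -> pd.DataFrame:
    if spec.exposure_form == "tertile":
        _, labels = assign_tertiles(cohort[spec.exposure].to_numpy(), exposure=spec.exposure)
        return pd.DataFrame(
            {
                f"{spec.exposure}_T2": (labels == 2).astype(float),
                f"{spec.exposure}_T3": (labels == 3).astype(float),
            },
            index=cohort.index,
        )
    if spec.exposure_form == "spline":
        x = cohort[spec.exposure].to_numpy(dtype=float)
        knots = np.percentile(x, [5, 35, 65, 95])
        basis = rcs_basis(x, knots)
        return pd.DataFrame(
            basis,
            columns=[f"{spec.exposure}_rcs{j}" for j in range(basis.shape[1])],
            index=cohort.index,
        )
    raise ValueError(f"unknown exposure_form {spec.exposure_form!r}")


def _fi_terms(cohort: pd.DataFrame) -> pd.DataFrame:
    cat = cohort["fi_category"]
    return pd.DataFrame(
        {
            "fi_pre_frail": (cat == "pre_frail").astype(float),
            "fi_frail": (cat == "frail").astype(float),
        },
        index=cohort.index,
    )


def fit_cox(cohort: pd.DataFrame, spec: AnalysisSpec) -> HazardModelFit:
    """Adjusted Cox model per an :class:`AnalysisSpec`.

    Exposure enters as tertile indicators or a restricted-cubic-spline
    basis; frailty as category indicators; adjustment covariates per the
    spec including the mutual-adjustment rule.  Deterministic for a fixed
    input.
    """
    parts = [_exposure_terms(cohort, spec)]
    if spec.fi_form == "category":
        if "fi_category" in cohort.columns:
            parts.append(_fi_terms(cohort))
    elif spec.fi_form == "joint":
        raise ValueError("use joint_group_hrs for fi_form='joint'")
    else:
        raise ValueError(f"unknown fi_form {spec.fi_form!r}")
    adj = [c for c in spec.adjustment if c in cohort.columns]
    parts.append(_encode_covariates(cohort, adj + spec.mutual_terms()))
    design = pd.concat(parts, axis=1)
    return fit_cox_design(
        design,
        cohort[spec.duration_col],
        cohort[spec.event_col],
        duration_col=spec.duration_col,
        event_col=spec.event_col,
    )


# ---------------------------------------------------------------------------
# joint 9-group analysis
# ---------------------------------------------------------------------------

def joint_group_labels(cohort: pd.DataFrame, exposure: str) -> pd.Series:
    """Per-participant ``"<fi_category>|T<k>"`` labels for an exposure."""
    _, tert = assign_tertiles(cohort[exposure].to_numpy(), exposure=exposure)
    return pd.Series(
        [f"{c}|T{t}" for c, t in zip(cohort["fi_category"], tert)], index=cohort.index
    )


def joint_group_hrs(
    cohort: pd.DataFrame,
    spec: AnalysisSpec,
    *,
    reference: str = "robust|T1",
) -> tuple[pd.DataFrame, HazardModelFit]:
    """9-row joint hazard-ratio table (3 FI categories x 3 tertiles).

    A single model with 8 indicator terms against the robust x tertile-1
    reference plus the spec's adjustment covariates; Wald 95% CIs from the
    coefficient covariance.  Every group must be non-empty with at least one
    event.
    """
    labels = joint_group_labels(cohort, spec.exposure)
    order = [f"{c}|T{t}" for c in FI_LEVELS for t in (1, 2, 3)]
    events = cohort[spec.event_col].astype(bool)
    for g in order:
        in_g = labels == g
        if not in_g.any():
            raise ValueError(f"joint group {g!r} is empty")
        if not (in_g & events).any():
            raise ValueError(f"joint group {g!r} has no events")
    dummies = pd.DataFrame(
        {f"jg_{g}": (labels == g).astype(float) for g in order if g != reference},
        index=cohort.index,
    )
    adj = [c for c in spec.adjustment if c in cohort.columns]
    design = pd.concat(
        [dummies, _encode_covariates(cohort, adj + spec.mutual_terms())], axis=1
    )
    fit = fit_cox_design(
        design,
        cohort[spec.duration_col],
        cohort[spec.event_col],
        duration_col=spec.duration_col,
        event_col=spec.event_col,
    )
    rows = []
    ci = fit.wald_ci()
    for g in order:
        if g == reference:
            rows.append({"group": g, "hr": 1.0, "ci_lo": 1.0, "ci_hi": 1.0, "is_reference": True})
        else:
            r = ci.loc[f"jg_{g}"]
            rows.append(
                {"group": g, "hr": r["hr"], "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"], "is_reference": False}
            )
    return pd.DataFrame(rows), fit


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted (natural) cubic spline basis with k knots -> k-1 columns.

    Column 0 is x itself; the remaining k-2 columns are the truncated-cube
    combinations constrained to be linear beyond the boundary knots
    (Harrell's parameterisation, normalised by the squared knot span).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(sorted(knots), dtype=float)
    k = t.size
    if k < 3 or np.unique(t).size != k:
        raise ValueError("need >= 3 distinct knots for a restricted cubic spline")
    span2 = (t[-1] - t[0]) ** 2
    cols = [x]
    plus = lambda v: np.maximum(v, 0.0) ** 3
    for j in range(k - 2):
        term = (
            plus(x - t[j])
            - plus(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / span2
        cols.append(term)
    return np.column_stack(cols)


def rcs_dose_response(
    cohort: pd.DataFrame,
    spec: AnalysisSpec,
    *,
    fi_subset: str | None = None,
    grid: np.ndarray | None = None,
    min_events: int = 50,
) -> SplineCurve:
    """Spline dose–response curve HR(x) = exp(f(x) - f(x_ref)).

    Four knots at the 5/35/65/95th percentiles of the (optionally
    FI-stratified) analysis sample; the reference is the 5th percentile so
    HR(reference) = 1 exactly.  Pointwise Wald 95% CIs from the coefficient
    covariance.
    """
    sub = cohort if fi_subset is None else cohort[cohort["fi_category"] == fi_subset]
    n_events = int(sub[spec.event_col].sum())
    if n_events < min_events:
        raise ValueError(
            f"only {n_events} events in FI subset {fi_subset!r}; need >= {min_events}"
        )
    x = sub[spec.exposure].to_numpy(dtype=float)
    knots = np.percentile(x, [5, 35, 65, 95])
    if np.unique(knots).size < 3:
        raise ValueError("degenerate exposure: spline knots are not distinct")
    basis_cols = [f"{spec.exposure}_rcs{j}" for j in range(len(knots) - 1)]
    design = pd.DataFrame(rcs_basis(x, knots), columns=basis_cols, index=sub.index)
    adj = [c for c in spec.adjustment if c in sub.columns]
    design = pd.concat([design, _encode_covariates(sub, adj + spec.mutual_terms())], axis=1)
    fit = fit_cox_design(
        design,
        sub[spec.duration_col],
        sub[spec.event_col],
        duration_col=spec.duration_col,
        event_col=spec.event_col,
    )
    x_ref = float(knots[0])
    if grid is None:
        grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 100)
    contrast = rcs_basis(grid, knots) - rcs_basis(np.full_like(grid, x_ref), knots)
    beta = fit.params[basis_cols].to_numpy()
    cov = fit.cov.loc[basis_cols, basis_cols].to_numpy()
    log_hr = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov, contrast))
    curve = pd.DataFrame(
        {
            "x": grid,
            "hr": np.exp(log_hr),
            "ci_lo": np.exp(log_hr - Z95 * se),
            "ci_hi": np.exp(log_hr + Z95 * se),
        }
    )
    return SplineCurve(spec.exposure, knots, x_ref, curve, fit)


# ---------------------------------------------------------------------------
# interaction
# ---------------------------------------------------------------------------

def lrt_interaction(
    fit_full: HazardModelFit, fit_reduced: HazardModelFit
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox models (e.g. with/without a
    cross-product term): stat = 2 (ll_full - ll_reduced), chi-square df =
    parameter-count difference."""
    df = len(fit_full.params) - len(fit_reduced.params)
    if fit_full.n_events != fit_reduced.n_events:
        raise ValueError("models were fitted on different event sets")
    stat = max(2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood), 0.0)
    if df == 0:
        if abs(fit_full.log_likelihood - fit_reduced.log_likelihood) < 1e-9:
            return 0.0, 0, 1.0  # degenerate self-comparison
        raise ValueError("fit_reduced must be nested in fit_full (df > 0)")
    if df < 0:
        raise ValueError("fit_reduced must be nested in fit_full (df > 0)")
    return stat, df, float(stats.chi2.sf(stat, df))


def reri_point(hr10: float, hr01: float, hr11: float) -> float:
    """Relative excess risk due to interaction: HR11 - HR10 - HR01 + 1."""
    return hr11 - hr10 - hr01 + 1.0


def reri(
    fit: HazardModelFit,
    term_10: str,
    term_01: str,
    term_11: str,
    *,
    n_boot: int = 5_000,
    seed: int | None = None,
    method: str = "bootstrap",
) -> InteractionResult:
    """Additive interaction on the hazard-ratio scale.

    ``term_10``/``term_01``/``term_11`` name the coefficients of
    exposure-only, frailty-only and joint indicators against a common
    reference.  The CI is a seeded parametric bootstrap over
    beta* ~ MVN(beta_hat, cov) with percentile 2.5/97.5 limits
    (``method="delta"`` gives the delta-method alternative).
    """
    terms = [term_10, term_01, term_11]
    missing = [t for t in terms if t not in fit.params.index]
    if missing:
        raise KeyError(f"fit lacks required terms: {missing}")
    beta = fit.params[terms].to_numpy()
    cov = fit.cov.loc[terms, terms].to_numpy()
    hr10, hr01, hr11 = np.exp(beta)
    point = reri_point(hr10, hr01, hr11)
    if method == "delta":
        grad = np.array([-hr10, -hr01, hr11])
        se = float(np.sqrt(grad @ cov @ grad))
        lo, hi = point - Z95 * se, point + Z95 * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(beta, cov, size=n_boot, method="svd")
        h = np.exp(draws)
        samples = h[:, 2] - h[:, 0] - h[:, 1] + 1.0
        lo, hi = np.percentile(samples, [2.5, 97.5])
        lo, hi = min(lo, point), max(hi, point)
    else:
        raise ValueError(f"unknown method {method!r}")
    return InteractionResult(reri=point, reri_ci_lo=float(lo), reri_ci_hi=float(hi))


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def ph_check(fit: HazardModelFit, transform: str = "rank") -> PHDiagnostic:
    """Scaled-Schoenfeld test of the proportional-hazards assumption.

    Regresses Schoenfeld residuals on a transform of event time (the rank
    of the event time by default); per-term chi-square(1) statistics and a
    global chi-square(p) statistic in the Grambsch–Therneau form, using the
    fit covariance as the average-information approximation.
    """
    if fit._fitter is None or fit._df is None:
        raise ValueError("fit does not carry residual information")
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for a PH check")
    resid = fit._fitter.compute_residuals(fit._df, "schoenfeld")
    times = fit._df.loc[resid.index, fit.duration_col].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    s = resid.to_numpy(dtype=float)[order]
    times = times[order]
    d = s.shape[0]
    if transform == "rank":
        g = stats.rankdata(times, method="average")
    elif transform == "identity":
        g = times.copy()
    elif transform == "km":
        # left-continuous KM of the censoring-inclusive sample is not carried
        # here; fall back to rank which is scale-free
        g = stats.rankdata(times, method="average")
    else:
        raise ValueError(f"unknown time transform {transform!r}")
    gc = g - g.mean()
    denom = float(gc @ gc)
    u = gc @ s  # per-term weighted residual sums
    cov = fit.cov.to_numpy()
    su = cov @ u
    per_stat = d * su**2 / (np.diag(cov) * denom)
    per_p = stats.chi2.sf(per_stat, 1)
    global_stat = float(d * (u @ su) / denom)
    global_p = float(stats.chi2.sf(global_stat, s.shape[1]))
    per = pd.DataFrame({"stat": per_stat, "p": per_p}, index=fit.params.index)
    return PHDiagnostic(per_term=per, global_stat=global_stat, global_p=global_p)
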