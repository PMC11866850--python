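"""Synthetic UK-Biobank-like cohort generator.

Emulates the design of a prospective accelerometer sub-cohort: ~78k
participants aged 45–80 wearing a wrist accelerometer for 7 consecutive
24-h periods (30-s epochs with ENMO and behaviour labels), 49 age-correlated
health deficits, a standard baseline covariate panel, and mortality follow-up
(~2.9% deaths over ~6.9-year median follow-up) under a Gompertz
proportional-hazards model with known, injected joint-group hazard ratios.

The generator is the ground-truth oracle for every downstream stage: the
injected linear predictor is returned alongside the cohort so that Cox
recovery, interaction tests and life-table estimates can be checked against
known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exposures import (
    DEFAULT_AWAKE_WINDOW,
    EPOCH_COLUMNS,
    EPOCH_SECONDS,
    EPOCHS_PER_HOUR,
    WEEKDAYS,
)
from .frailty_index import DeficitCodebook, default_codebook, score_cohort

EXPOSURES = ("tvpa_mg", "mvpa_h_day", "lpa_h_day", "st_h_day")

FI_CATEGORIES = ("robust", "pre_frail", "frail")
TERTILES = ("T1", "T2", "T3")


def joint_group_label(fi_category: str, tertile: int | str) -> str:
    t = tertile if isinstance(tertile, str) else f"T{tertile}"
    return f"{fi_category}|{t}"


REFERENCE_GROUP = joint_group_label("robust", 1)

# Injected joint-group hazard ratios (frailty category x TVPA tertile) versus
# robust x tertile-1.  Chosen so that the extreme contrast frail x T1 versus
# robust x T3 is ~3.05, the scale of joint-association estimates reported for
# cohorts of this design, with activity protective within every FI stratum.
DEFAULT_TRUE_LOG_HR: dict[str, float] = {
    "robust|T1": 0.0,
    "robust|T2": float(np.log(0.75)),
    "robust|T3": float(np.log(0.62)),
    "pre_frail|T1": float(np.log(1.35)),
    "pre_frail|T2": float(np.log(1.00)),
    "pre_frail|T3": float(np.log(0.80)),
    "frail|T1": float(np.log(1.90)),
    "frail|T2": float(np.log(1.35)),
    "frail|T3": float(np.log(1.05)),
}

# Correlation targets for the Gaussian copula over the four exposures
# (order: TVPA, MVPA, LPA, ST).  Cohorts of this design publish the
# exposure correlation structure only graphically, so these are round values
# with the expected signs: activity measures co-vary positively and each is
# negatively related to sedentary time.
DEFAULT_EXPOSURE_CORR = np.array(
    [
        [1.00, 0.70, 0.60, -0.40],
        [0.70, 1.00, 0.30, -0.30],
        [0.60, 0.30, 1.00, -0.40],
        [-0.40, -0.30, -0.40, 1.00],
    ]
)

# Correlation of the latent frailty liability with each exposure's copula
# latent: frail participants move less and sit slightly more.
DEFAULT_LIABILITY_EXPOSURE_CORR = (-0.25, -0.30, -0.10, 0.05)

DEFAULT_COVARIATE_PREVALENCES: dict[str, dict[str, float]] = {
    "assessment_center": {f"center_{i:02d}": 0.1 for i in range(1, 11)},
    "bmi_category": {"<25": 0.399, "25-29.9": 0.409, ">=30": 0.191},
    "ethnicity": {"white": 0.973, "other": 0.027},
    "education": {"college": 0.448, "secondary": 0.367, "primary": 0.079, "professional": 0.106},
    "employment": {"employed": 0.540, "retired": 0.409, "inactive": 0.051},
    "income": {"<18k": 0.159, "18-31k": 0.251, "31-52k": 0.278, "52-100k": 0.233, ">100k": 0.079},
    "smoking": {"never": 0.576, "previous": 0.363, "current": 0.062},
    "alcohol": {"3+_per_week": 0.485, "<3_per_week": 0.456, "never": 0.060},
    "sleep_duration": {"7-8h": 0.714, "<7h": 0.219, ">8h": 0.067},
    "diet_score": {"0-2": 0.346, "3-5": 0.608, ">=6": 0.045},
    "famhx_diabetes": {"no": 0.777, "yes": 0.223},
    "famhx_cvd": {"no": 0.224, "yes": 0.776},
    "famhx_cancer": {"no": 0.625, "yes": 0.375},
    "season": {"autumn": 0.297, "spring": 0.228, "summer": 0.264, "winter": 0.212},
}

DEFAULT_MISSING_RATES: dict[str, float] = {
    "bmi_category": 0.02,
    "education": 0.03,
    "employment": 0.02,
    "income": 0.06,
    "smoking": 0.01,
    "alcohol": 0.01,
    "sleep_duration": 0.01,
    "diet_score": 0.05,
}

# Wear-schedule mixture: most participants wear the device for all 7 days;
# some lose 1-2 weekdays; a small fraction fail the validity rules outright
# (only 2 days, or weekdays only) so the exclusion filters are exercised.
DEFAULT_WEAR_PATTERN_PROBS: dict[str, float] = {
    "full": 0.72,
    "drop1": 0.15,
    "drop2": 0.10,
    "short": 0.015,
    "no_weekend": 0.015,
}

#: columns the missingness injector must never touch
PROTECTED_COLUMNS_PREFIXES = ("deficit_",)
PROTECTED_COLUMNS = {
    "participant_id", "time_months", "event", "mortality_known",
    "age", "sex", "fi", "fi_category",
    "tvpa_mg", "mvpa_h_day", "lpa_h_day", "st_h_day",
    "n_wear_days", "weekend_covered", "wear_valid",
    "wear_start_weekday", "wear_day_mask",
}

# Per-epoch ENMO scale (mg) by behaviour before the participant-level
# rescaling that pins the awake-window mean to the drawn TVPA target.
_ENMO_BY_BEHAVIOR = {"sleep": 3.0, "sedentary": 9.0, "light": 32.0, "mvpa": 110.0}
_BEHAVIOR_CODES = ("sleep", "sedentary", "light", "mvpa")

# Deficit-model constants.  Binary base prevalences (at mean liability and
# mean age) are spread log-odds-linearly between ~2% and ~25%; ordinal items
# use a graded-response layout with evenly spaced thresholds.  The global
# shift and loading below are calibrated so the default cohort splits
# ~63/33/4% across robust / pre-frail / frail.
_BINARY_BASE_LOGIT_RANGE = (-3.9, -1.1)
_ORD3_BASE, _ORD5_BASE = -0.25, -0.20
_ORD_STEP = 1.5
DEFAULT_DEFICIT_LOADING = 0.60
DEFAULT_DEFICIT_SHIFT = -0.30
DEFAULT_DEFICIT_AGE_SLOPE = 0.42

# Gompertz baseline: log-hazard doubles roughly every 8 years of attained
# age; the rate at age 50 is calibrated so the default cohort experiences
# ~2.9% deaths over the follow-up window.
DEFAULT_GOMPERTZ_SHAPE = float(np.log(2) / 8)
DEFAULT_GOMPERTZ_RATE_AT_50 = 1.03e-3


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GompertzBaseline:
    """Baseline hazard h0(t) = rate_at_50 * exp(shape * (age0 + t - 50))."""

    shape: float = DEFAULT_GOMPERTZ_SHAPE
    rate_at_50: float = DEFAULT_GOMPERTZ_RATE_AT_50


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative horizon (scalar or per-participant, years) plus an
    optional constant loss-to-follow-up hazard."""

    admin_horizon_years: float | np.ndarray = 8.15
    dropout_rate_per_year: float = 0.0


@dataclass
class GeneratorConfig:
    n_participants: int = 78_508
    seed: int = 2025
    prop_women: float = 0.555
    age_mean: float = 62.0
    age_sd: float = 7.8
    age_range: tuple[float, float] = (45.0, 80.0)
    exposure_means: dict[str, float] = field(
        default_factory=lambda: {"tvpa_mg": 38.4, "mvpa_h_day": 0.517, "lpa_h_day": 5.27, "st_h_day": 7.98}
    )
    exposure_sds: dict[str, float] = field(
        default_factory=lambda: {"tvpa_mg": 11.9, "mvpa_h_day": 0.447, "lpa_h_day": 1.58, "st_h_day": 1.60}
    )
    exposure_corr: np.ndarray = field(default_factory=lambda: DEFAULT_EXPOSURE_CORR.copy())
    liability_exposure_corr: tuple[float, ...] = DEFAULT_LIABILITY_EXPOSURE_CORR
    deficit_loadings: np.ndarray | None = None
    deficit_shift: float = DEFAULT_DEFICIT_SHIFT
    deficit_age_slope: float = DEFAULT_DEFICIT_AGE_SLOPE
    covariate_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PREVALENCES.items()}
    )
    townsend_mean: float = -1.79
    townsend_sd: float = 2.78
    gompertz_shape: float = DEFAULT_GOMPERTZ_SHAPE
    gompertz_rate_at_50: float = DEFAULT_GOMPERTZ_RATE_AT_50
    true_log_hr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_LOG_HR))
    recruit_window_years: float = 2.5
    admin_censor_years: float = 8.15
    dropout_rate_per_year: float = 0.002
    missing_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    prop_shift_workers: float = 0.037
    prop_mortality_unknown: float = 6e-5
    wear_pattern_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEAR_PATTERN_PROBS)
    )
    n_epoch_participants: int = 1_000

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        fracs = [self.prop_women, self.prop_shift_workers, self.prop_mortality_unknown]
        fracs += list(self.missing_rates.values())
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigurationError("fractions and missing rates must lie in [0, 1]")
        if self.age_sd <= 0 or any(s <= 0 for s in self.exposure_sds.values()):
            raise ConfigurationError("standard deviations must be positive")
        corr = np.asarray(self.exposure_corr, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ConfigurationError("exposure_corr must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(self._copula_corr()).min() < -1e-10:
            raise ConfigurationError("copula correlation matrix is not positive semi-definite")
        if self.true_log_hr.get(REFERENCE_GROUP, None) != 0.0:
            raise ConfigurationError(
                f"true_log_hr must contain the reference group {REFERENCE_GROUP!r} with value 0"
            )
        if self.gompertz_shape < 0 or self.gompertz_rate_at_50 <= 0:
            raise ConfigurationError("Gompertz parameters must be positive")
        if abs(sum(self.wear_pattern_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("wear_pattern_probs must sum to 1")

    def _copula_corr(self) -> np.ndarray:
        """5x5 latent correlation: (liability, TVPA, MVPA, LPA, ST)."""
        c = np.eye(5)
        c[1:, 1:] = np.asarray(self.exposure_corr, dtype=float)
        lam = np.asarray(self.liability_exposure_corr, dtype=float)
        c[0, 1:] = lam
        c[1:, 0] = lam
        return c


@dataclass
class TrueEffects:
    """Ground truth injected into a generated cohort."""

    group_hr: dict[str, float]
    joint_group: np.ndarray  # per-participant label
    linear_predictor: np.ndarray
    baseline: GompertzBaseline
    tvpa_tertile_cuts: tuple[float, float]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "group_hr": self.group_hr,
                    "baseline": asdict(self.baseline),
                    "tvpa_tertile_cuts": list(self.tvpa_tertile_cuts),
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------

def simulate_survival(
    linear_predictor: np.ndarray,
    baseline: GompertzBaseline,
    censoring: CensoringSpec,
    *,
    age_at_entry: np.ndarray | float = 50.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event times (months) and event flags under a Gompertz PH model.

    The hazard at follow-up time t (years) for a participant entering at
    attained age ``age_at_entry`` is

        h(t) = rate_at_50 * exp(shape * (age_at_entry + t - 50)) * exp(lp)

    sampled by inverse transform; the observation is censored at the
    administrative horizon or at an exponential dropout time, whichever
    comes first.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    if baseline.rate_at_50 <= 0 or baseline.shape < 0:
        raise ValueError("baseline requires rate_at_50 > 0 and shape >= 0")
    rng = np.random.default_rng(rng)
    n = lp.shape[0]
    scale = baseline.rate_at_50 * np.exp(
        baseline.shape * (np.asarray(age_at_entry, dtype=float) - 50.0) + lp
    )
    u = -np.log(rng.uniform(size=n))  # unit-exponential
    if baseline.shape == 0.0:
        t_death = u / scale
    else:
        t_death = np.log1p(baseline.shape * u / scale) / baseline.shape
    horizon = np.broadcast_to(
        np.asarray(censoring.admin_horizon_years, dtype=float), (n,)
    ).copy()
    if censoring.dropout_rate_per_year > 0:
        t_drop = rng.exponential(1.0 / censoring.dropout_rate_per_year, size=n)
        horizon = np.minimum(horizon, t_drop)
    event = t_death <= horizon
    time_years = np.where(event, t_death, horizon)
    return time_years * 12.0, event


# ---------------------------------------------------------------------------
# deficits
# ---------------------------------------------------------------------------

def _deficit_item_params(codebook: DeficitCodebook) -> tuple[np.ndarray, np.ndarray]:
    """Per-item (base intercept, n_levels) arrays for the response model."""
    n_binary = sum(1 for it in codebook if it.kind == "binary")
    base = np.empty(len(codebook))
    nlev = np.empty(len(codebook), dtype=int)
    b_lo, b_hi = _BINARY_BASE_LOGIT_RANGE
    j_bin = 0
    for j, item in enumerate(codebook):
        nlev[j] = item.n_levels
        if item.kind == "binary":
            base[j] = b_lo + (b_hi - b_lo) * (j_bin / max(n_binary - 1, 1))
            j_bin += 1
        else:
            base[j] = _ORD3_BASE if item.n_levels == 3 else _ORD5_BASE
    return base, nlev


def _draw_deficits(
    rng: np.random.Generator,
    codebook: DeficitCodebook,
    liability: np.ndarray,
    age_std: np.ndarray,
    loadings: np.ndarray,
    shift: float,
    age_slope: float,
) -> pd.DataFrame:
    """Raw deficit responses from a latent-liability graded-response model.

    Binary item j: P(deficit) = expit(a_j + shift + b_j * u) with
    u = liability + age_slope * standardized age.  Ordinal items use the
    same linear predictor against evenly spaced thresholds, drawn with a
    single uniform so levels are consistent.
    """
    base, nlev = _deficit_item_params(codebook)
    u = liability + age_slope * age_std
    out = {}
    for j, item in enumerate(codebook):
        eta = base[j] + shift + loadings[j] * u
        draw = rng.uniform(size=u.shape[0])
        if item.kind == "binary":
            out[item.name] = (draw < expit(eta)).astype(np.int8)
        else:
            level = np.zeros(u.shape[0], dtype=np.int8)
            for k in range(1, nlev[j]):
                level += (draw < expit(eta - _ORD_STEP * (k - 1))).astype(np.int8)
            out[item.name] = level
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# exposures (participant-level targets)
# ---------------------------------------------------------------------------

def _draw_exposures(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Latent liability + exposure targets from the Gaussian copula.

    TVPA and MVPA get lognormal marginals (right-skewed, positive); LPA and
    ST get zero-truncated normal marginals.  The behaviour-hour sum is then
    capped at the awake-window length with ST renormalised as the remainder.
    """
    corr = config._copula_corr()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
    z = rng.standard_normal((n, 5)) @ chol.T
    liability = z[:, 0]
    uz = stats.norm.cdf(z[:, 1:])
    cols = {}
    for i, name in enumerate(EXPOSURES):
        m, s = config.exposure_means[name], config.exposure_sds[name]
        if name in ("tvpa_mg", "mvpa_h_day"):
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2
            cols[name] = np.exp(stats.norm.ppf(uz[:, i]) * np.sqrt(sigma2) + mu)
        else:
            a = (0.0 - m) / s  # truncate at zero
            cols[name] = stats.truncnorm.ppf(uz[:, i], a, np.inf, loc=m, scale=s)
    awake_h = DEFAULT_AWAKE_WINDOW.hours
    active = cols["mvpa_h_day"] + cols["lpa_h_day"]
    scale = np.where(active > awake_h, awake_h / active, 1.0)  # extreme tail draws
    cols["mvpa_h_day"] = cols["mvpa_h_day"] * scale
    cols["lpa_h_day"] = cols["lpa_h_day"] * scale
    total = cols["mvpa_h_day"] + cols["lpa_h_day"] + cols["st_h_day"]
    over = total > awake_h
    cols["st_h_day"] = np.where(
        over, np.maximum(awake_h - cols["mvpa_h_day"] - cols["lpa_h_day"], 0.0), cols["st_h_day"]
    )
    return liability, pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# wear schedules + epoch emission
# ---------------------------------------------------------------------------

def _draw_wear_schedule(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> pd.DataFrame:
    patterns = list(config.wear_pattern_probs)
    probs = np.array([config.wear_pattern_probs[p] for p in patterns])
    pat = rng.choice(len(patterns), size=n, p=probs / probs.sum())
    start = rng.integers(0, 7, size=n)
    masks = np.ones((n, 7), dtype=bool)
    weekday_grid = (start[:, None] + np.arange(7)[None, :]) % 7  # 5=Sat, 6=Sun
    is_weekend = weekday_grid >= 5
    for i, p in enumerate(patterns):
        rows = pat == i
        if p == "short":
            masks[rows, 2:] = False
        elif p == "no_weekend":
            masks[rows] &= ~is_weekend[rows]
        elif p in ("drop1", "drop2"):
            k = 1 if p == "drop1" else 2
            # drop the first k non-weekend days so weekend coverage survives
            weekday_pos = ~is_weekend[rows]
            cum = np.cumsum(weekday_pos, axis=1)
            masks[rows] &= ~(weekday_pos & (cum <= k))
    mask_str = ["".join("1" if b else "0" for b in row) for row in masks]
    n_days = masks.sum(axis=1)
    weekend_covered = (masks & is_weekend).any(axis=1)
    return pd.DataFrame(
        {
            "wear_start_weekday": start,
            "wear_day_mask": mask_str,
            "n_wear_days": n_days,
            "weekend_covered": weekend_covered,
            "wear_valid": (n_days >= 3) & weekend_covered,
        }
    )


def _participant_epochs(
    pid: int,
    seed: int,
    start_weekday: int,
    day_mask: str,
    targets: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Emit one participant's 30-s epochs (columns as parallel arrays).

    Behaviour-labelled epochs are laid out in blocks inside the 06:00–22:00
    window (sedentary, then light, then MVPA, then waking-rest labelled
    sleep); the night hours are sleep.  Per-epoch ENMO is gamma noise around
    behaviour-specific levels, rescaled so the pooled awake-window mean
    equals the participant's TVPA target exactly.
    """
    rng = np.random.default_rng([seed, int(pid)])
    window = DEFAULT_AWAKE_WINDOW
    n_window = (window.end_s - window.start_s) // EPOCH_SECONDS
    n_mvpa = min(int(round(targets["mvpa_h_day"] * EPOCHS_PER_HOUR)), n_window)
    n_lpa = min(int(round(targets["lpa_h_day"] * EPOCHS_PER_HOUR)), n_window - n_mvpa)
    n_st = int(round(targets["st_h_day"] * EPOCHS_PER_HOUR))
    if n_mvpa + n_lpa + n_st > n_window:  # rounding can overshoot by one
        n_st = n_window - n_mvpa - n_lpa
    n_fill = n_window - n_mvpa - n_lpa - n_st

    day_sec = np.arange(0, 86400, EPOCH_SECONDS, dtype=np.int32)
    in_window = (day_sec >= window.start_s) & (day_sec < window.end_s)
    beh_day = np.zeros(day_sec.shape[0], dtype=np.int8)  # 0 = sleep
    window_codes = np.concatenate(
        [
            np.full(n_st, 1, dtype=np.int8),
            np.full(n_lpa, 2, dtype=np.int8),
            np.full(n_mvpa, 3, dtype=np.int8),
            np.zeros(n_fill, dtype=np.int8),
        ]
    )
    beh_day[in_window] = window_codes

    days = [d for d in range(7) if day_mask[d] == "1"]
    n_days = len(days)
    n_epochs = n_days * day_sec.shape[0]
    beh = np.tile(beh_day, n_days)
    sec = np.tile(day_sec, n_days)
    day_index = np.repeat(np.array(days, dtype=np.int8) + 1, day_sec.shape[0])
    weekday = np.repeat(
        ((start_weekday + np.array(days)) % 7).astype(np.int8), day_sec.shape[0]
    )
    level = np.array([_ENMO_BY_BEHAVIOR[b] for b in _BEHAVIOR_CODES])
    enmo = rng.standard_gamma(4.0, size=n_epochs) * (level[beh] / 4.0)
    awake = np.tile(in_window, n_days)
    enmo[awake] *= targets["tvpa_mg"] / enmo[awake].mean()
    return {
        "participant_id": np.full(n_epochs, pid, dtype=np.int64),
        "day_index": day_index,
        "weekday": weekday,
        "epoch_start_s": sec,
        "enmo_mg": enmo.astype(np.float32),
        "behavior": beh,
    }


def _epoch_frame(parts: list[dict[str, np.ndarray]]) -> pd.DataFrame:
    cols = {k: np.concatenate([p[k] for p in parts]) for k in parts[0]}
    df = pd.DataFrame(
        {
            "participant_id": cols["participant_id"],
            "day_index": cols["day_index"],
            "weekday": pd.Categorical.from_codes(cols["weekday"], categories=list(WEEKDAYS)),
            "epoch_start_s": cols["epoch_start_s"],
            "enmo_mg": cols["enmo_mg"],
            "behavior": pd.Categorical.from_codes(cols["behavior"], categories=list(_BEHAVIOR_CODES)),
        }
    )
    return df[EPOCH_COLUMNS]


def generate_epochs(
    cohort: pd.DataFrame, config: GeneratorConfig, participant_ids: Sequence[int] | None = None
) -> pd.DataFrame:
    """Epoch records for the given participants (defaults to all rows).

    Each participant has an independent seeded substream keyed on
    (config.seed, participant_id), so the output is identical however the
    cohort is chunked.
    """
    sub = cohort if participant_ids is None else cohort[cohort["participant_id"].isin(participant_ids)]
    parts = []
    for row in sub.itertuples(index=False):
        parts.append(
            _participant_epochs(
                row.participant_id,
                config.seed,
                int(row.wear_start_weekday),
                row.wear_day_mask,
                {
                    "tvpa_mg": row.tvpa_mg,
                    "mvpa_h_day": row.mvpa_h_day,
                    "lpa_h_day": row.lpa_h_day,
                    "st_h_day": row.st_h_day,
                },
            )
        )
    if not parts:
        return pd.DataFrame(columns=EPOCH_COLUMNS)
    return _epoch_frame(parts)


def iter_epoch_frames(
    cohort: pd.DataFrame, config: GeneratorConfig, chunk_size: int = 250
) -> Iterator[pd.DataFrame]:
    """Stream epoch records in participant chunks (memory-bounded)."""
    for lo in range(0, len(cohort), chunk_size):
        yield generate_epochs(cohort.iloc[lo : lo + chunk_size], config)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    cohort: pd.DataFrame,
    missing_rates: Mapping[str, float],
    *,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """MCAR missingness on covariate columns only (seeded).

    Outcome, exposure, wear and deficit columns are protected; requesting a
    rate on one of them raises.
    """
    rng = np.random.default_rng(rng)
    out = cohort.copy()
    for col, rate in missing_rates.items():
        if col in PROTECTED_COLUMNS or any(col.startswith(p) for p in PROTECTED_COLUMNS_PREFIXES):
            raise ValueError(f"column {col!r} is protected and cannot be made missing")
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in cohort")
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missing rate for {col!r} outside [0, 1]")
        if rate == 0.0:
            continue
        mask = rng.uniform(size=len(out)) < rate
        if out[col].dtype.kind in "iub":
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GeneratorConfig | None = None,
    *,
    codebook: DeficitCodebook | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueEffects]:
    """Generate a cohort, an epoch subsample, and the injected ground truth.

    The cohort table carries one row per participant: deficit responses,
    exposure targets, wear metadata, covariates (with MCAR missingness
    already injected), follow-up time in months and the event flag, plus the
    computed ``fi`` / ``fi_category``.  Epochs are emitted for the first
    ``config.n_epoch_participants`` participants; use
    :func:`iter_epoch_frames` to stream more.
    """
    config = config or GeneratorConfig()
    config.validate()
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # demographics
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=config.age_mean, scale=config.age_sd)
    sex = np.where(rng.uniform(size=n) < config.prop_women, "women", "men")
    age_std = (age - config.age_mean) / config.age_sd

    # liability + exposures, deficits, frailty
    liability, expo = _draw_exposures(rng, config, n)
    loadings = (
        np.asarray(config.deficit_loadings, dtype=float)
        if config.deficit_loadings is not None
        else np.full(len(codebook), DEFAULT_DEFICIT_LOADING)
    )
    deficits = _draw_deficits(
        rng, codebook, liability, age_std, loadings, config.deficit_shift, config.deficit_age_slope
    )

    cohort = pd.DataFrame({"participant_id": np.arange(n, dtype=np.int64), "age": age, "sex": sex})
    cohort = pd.concat([cohort, deficits, expo], axis=1)
    cohort = score_cohort(cohort, codebook)

    # injected joint groups: frailty category x TVPA tertile on this sample
    from .exposures import assign_tertiles

    scheme, tert = assign_tertiles(cohort["tvpa_mg"].to_numpy(), exposure="tvpa_mg")
    group = np.array(
        [joint_group_label(c, t) for c, t in zip(cohort["fi_category"], tert)], dtype=object
    )
    lp = np.array([config.true_log_hr[g] for g in group])

    # survival
    baseline = GompertzBaseline(config.gompertz_shape, config.gompertz_rate_at_50)
    entry = rng.uniform(0.0, config.recruit_window_years, size=n)
    censoring = CensoringSpec(
        admin_horizon_years=config.admin_censor_years - entry,
        dropout_rate_per_year=config.dropout_rate_per_year,
    )
    time_months, event = simulate_survival(
        lp, baseline, censoring, age_at_entry=age, rng=rng
    )
    cohort["time_months"] = time_months
    cohort["event"] = event
    cohort["mortality_known"] = rng.uniform(size=n) >= config.prop_mortality_unknown

    # wear schedule + covariates
    cohort = pd.concat([cohort, _draw_wear_schedule(rng, config, n)], axis=1)
    for name, prev in config.covariate_prevalences.items():
        levels = list(prev)
        p = np.array([prev[l] for l in levels], dtype=float)
        cohort[name] = rng.choice(levels, size=n, p=p / p.sum())
    cohort["townsend"] = rng.normal(config.townsend_mean, config.townsend_sd, size=n)
    cohort["shift_worker"] = rng.uniform(size=n) < config.prop_shift_workers

    cohort = inject_missingness(
        cohort, config.missing_rates, rng=np.random.default_rng([config.seed, 999_983])
    )

    truth = TrueEffects(
        group_hr={k: float(np.exp(v)) for k, v in config.true_log_hr.items()},
        joint_group=group,
        linear_predictor=lp,
        baseline=baseline,
        tvpa_tertile_cuts=(scheme.cut_lo, scheme.cut_hi),
    )
    epochs = generate_epochs(
        cohort.head(config.n_epoch_participants), config
    )
    return cohort, epochs, truth
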