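"""Accelerometer exposure derivation from 30-s epoch records.

Exposures follow the accelerometer convention of UK-Biobank-style studies:

* **TVPA** — total volume of physical activity: mean ENMO (mg) over epochs
  falling in the awake clock window (default 06:00–22:00), pooled across
  valid wear days.
* **MVPA / LPA / ST** — mean daily hours spent in epochs labelled
  moderate-to-vigorous (>= 3 METs), light (1.5–2.9 METs) or sedentary,
  within the awake window, averaged over valid days.

Wear validity requires >= 3 valid days and data on Saturday or Sunday.
Exposures are categorised into tertiles with tertile 1 as reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30
EPOCHS_PER_DAY = 86400 // EPOCH_SECONDS
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
BEHAVIORS = ("sleep", "sedentary", "light", "mvpa")

#: minimum fraction of a 24-h day covered by epochs for the day to count
DEFAULT_VALID_DAY_FRACTION = 0.75
#: minimum number of valid days for a participant's data to be usable
MIN_VALID_DAYS = 3

EPOCH_COLUMNS = ["participant_id", "day_index", "weekday", "epoch_start_s", "enmo_mg", "behavior"]


@dataclass(frozen=True)
class AwakeWindow:
    """Half-open clock window [start, end) in seconds since midnight."""

    start_s: int = 6 * 3600
    end_s: int = 22 * 3600

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s <= 86400):
            raise ValueError("awake window must satisfy 0 <= start < end <= 24h")

    @property
    def hours(self) -> float:
        return (self.end_s - self.start_s) / 3600.0

    def contains(self, epoch_start_s) -> np.ndarray:
        t = np.asarray(epoch_start_s)
        return (t >= self.start_s) & (t < self.end_s)

    @classmethod
    def parse(cls, text: str) -> "AwakeWindow":
        """Parse ``"HH:MM-HH:MM"`` (e.g. ``"06:00-22:00"``)."""
        try:
            start, end = text.split("-")
            h1, m1 = (int(x) for x in start.split(":"))
            h2, m2 = (int(x) for x in end.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse awake window {text!r}") from exc
        return cls(h1 * 3600 + m1 * 60, h2 * 3600 + m2 * 60)

    def __str__(self) -> str:
        fmt = lambda s: f"{s // 3600:02d}:{(s % 3600) // 60:02d}"
        return f"{fmt(self.start_s)}-{fmt(self.end_s)}"


DEFAULT_AWAKE_WINDOW = AwakeWindow()


@dataclass(frozen=True)
class ExposureSummary:
    tvpa_mg: float
    mvpa_h_day: float
    lpa_h_day: float
    st_h_day: float
    n_valid_days: int
    weekend_covered: bool
    valid: bool


@dataclass(frozen=True)
class TertileScheme:
    exposure: str
    cut_lo: float
    cut_hi: float
    reference_tertile: int = 1

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "exposure": self.exposure,
                    "cut_lo": self.cut_lo,
                    "cut_hi": self.cut_hi,
                    "reference_tertile": self.reference_tertile,
                },
                fh,
            )


def _valid_days(epochs: pd.DataFrame, valid_day_fraction: float) -> pd.Series:
    """Per-day epoch counts -> boolean validity, indexed by day_index."""
    counts = epochs.groupby("day_index", observed=True).size()
    return counts >= valid_day_fraction * EPOCHS_PER_DAY


def assess_wear_validity(
    epochs: pd.DataFrame,
    *,
    valid_day_fraction: float = DEFAULT_VALID_DAY_FRACTION,
) -> tuple[int, bool, bool]:
    """Wear-validity check for one participant's epochs.

    A day is valid when at least ``valid_day_fraction`` of its 24 h carries
    epochs.  The record is valid when there are >= 3 valid days and any data
    on Saturday or Sunday.  Empty input is invalid, never an error.
    """
    if len(epochs) == 0:
        return 0, False, False
    day_ok = _valid_days(epochs, valid_day_fraction)
    n_valid = int(day_ok.sum())
    weekend = bool(epochs["weekday"].isin(["Sat", "Sun"]).any())
    return n_valid, weekend, (n_valid >= MIN_VALID_DAYS) and weekend


def aggregate_epochs(
    epochs: pd.DataFrame,
    window: AwakeWindow = DEFAULT_AWAKE_WINDOW,
    *,
    valid_day_fraction: float = DEFAULT_VALID_DAY_FRACTION,
) -> ExposureSummary:
    """Exposure summary for one participant.

    TVPA is the ENMO mean over *all* awake-window epochs on valid days
    (pooled, including sleep-labelled epochs: the total volume is defined by
    the clock window).  MVPA/LPA/ST hours count behaviour-labelled epochs in
    the window, averaged over valid days.
    """
    n_valid, weekend, valid = assess_wear_validity(
        epochs, valid_day_fraction=valid_day_fraction
    )
    if n_valid == 0:
        raise ValueError("no valid wear days: cannot aggregate")
    day_ok = _valid_days(epochs, valid_day_fraction)
    keep = epochs["day_index"].map(day_ok).fillna(False).astype(bool)
    sub = epochs.loc[keep]
    awake = sub.loc[window.contains(sub["epoch_start_s"].to_numpy())]
    if len(awake) == 0:
        raise ValueError("no epochs fall inside the awake window")
    tvpa = float(awake["enmo_mg"].mean())
    hours = {}
    counts = awake["behavior"].value_counts()
    for label in ("mvpa", "light", "sedentary"):
        hours[label] = float(counts.get(label, 0)) / n_valid / EPOCHS_PER_HOUR
    return ExposureSummary(
        tvpa_mg=tvpa,
        mvpa_h_day=hours["mvpa"],
        lpa_h_day=hours["light"],
        st_h_day=hours["sedentary"],
        n_valid_days=n_valid,
        weekend_covered=weekend,
        valid=valid,
    )


def aggregate_cohort(
    epochs: pd.DataFrame,
    window: AwakeWindow = DEFAULT_AWAKE_WINDOW,
    *,
    valid_day_fraction: float = DEFAULT_VALID_DAY_FRACTION,
) -> pd.DataFrame:
    """Vectorised :func:`aggregate_epochs` over a long-format epoch table.

    Returns one row per participant_id with the ExposureSummary fields.
    Participants with zero valid days get NaN exposures and ``valid=False``.
    Implemented with integer-coded bincounts so that cohort-scale epoch
    tables (1e7–1e8 rows) aggregate in seconds.
    """
    pid, pid_codes = np.unique(epochs["participant_id"].to_numpy(), return_inverse=True)
    n = len(pid)
    day = epochs["day_index"].to_numpy()
    n_days = int(day.max()) + 1 if len(day) else 0
    cell = pid_codes * n_days + (day - 1)
    day_counts = np.bincount(cell, minlength=n * n_days).reshape(n, n_days)
    day_valid = day_counts >= valid_day_fraction * EPOCHS_PER_DAY
    n_valid = day_valid.sum(axis=1)

    weekend_rows = epochs["weekday"].isin(["Sat", "Sun"]).to_numpy()
    weekend = np.bincount(pid_codes[weekend_rows], minlength=n) > 0

    keep = day_valid.reshape(-1)[cell]
    awake = keep & window.contains(epochs["epoch_start_s"].to_numpy())
    codes_awake = pid_codes[awake]
    n_awake = np.bincount(codes_awake, minlength=n)
    enmo_sum = np.bincount(codes_awake, weights=epochs["enmo_mg"].to_numpy()[awake], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        tvpa = np.where(n_awake > 0, enmo_sum / np.maximum(n_awake, 1), np.nan)

    hours = {}
    for label in ("mvpa", "light", "sedentary"):
        lab_mask = (epochs["behavior"] == label).to_numpy()
        cnt = np.bincount(codes_awake[lab_mask[awake]], minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            hours[label] = np.where(n_valid > 0, cnt / np.maximum(n_valid, 1), np.nan) / EPOCHS_PER_HOUR

    return pd.DataFrame(
        {
            "participant_id": pid,
            "tvpa_mg": np.where(n_valid > 0, tvpa, np.nan),
            "mvpa_h_day": hours["mvpa"],
            "lpa_h_day": hours["light"],
            "st_h_day": hours["sedentary"],
            "n_valid_days": n_valid,
            "weekend_covered": weekend,
            "valid": (n_valid >= MIN_VALID_DAYS) & weekend,
        }
    )


def assign_tertiles(values, *, exposure: str = "exposure") -> tuple[TertileScheme, np.ndarray]:
    """Split an exposure into tertiles on its own empirical distribution.

    Cut points sit at the 33 1/3 and 66 2/3 percentiles (linear
    interpolation); labels are 1/2/3 ascending in the exposure, ties at a
    cut resolving to the lower tertile.  Tertile 1 is always the reference.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 3 or np.unique(finite).size < 3:
        raise ValueError("need at least 3 finite distinct values to form tertiles")
    cut_lo, cut_hi = np.percentile(finite, [100 / 3, 200 / 3])
    labels = np.where(np.isfinite(arr), 1 + (arr > cut_lo).astype(int) + (arr > cut_hi).astype(int), 0)
    for t in (1, 2, 3):
        if not np.any(labels == t):
            raise ValueError(f"tertile {t} is empty on the defining sample")
    return TertileScheme(exposure, float(cut_lo), float(cut_hi)), labels
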