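"""Deficit-accumulation frailty index.

The frailty index (FI) of a participant is the sum of their deficit scores
divided by the number of deficits considered.  Binary items score 0 (no
deficit) or 1 (deficit present); ordinal items map each severity level onto
a score in [0, 1].  Participants are categorised as robust (FI <= 0.12),
pre-frail (0.12 < FI < 0.24) or frail (FI >= 0.24).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROBUST_CUT = 0.12
FRAIL_CUT = 0.24

CATEGORY_ORDER = ("robust", "pre_frail", "frail")


class CodingError(ValueError):
    """A response level not declared in the codebook."""


@dataclass(frozen=True)
class DeficitItem:
    """One codebook entry.

    ``level_scores`` maps each declared response level to a deficit score in
    [0, 1].  Binary items use scores {0, 1}; ordinal items use non-decreasing
    scores with minimum 0 and maximum 1.
    """

    name: str
    kind: str  # "binary" | "ordinal"
    level_scores: Mapping[object, float]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"unknown item kind {self.kind!r} for {self.name}")
        scores = list(self.level_scores.values())
        if not scores:
            raise ValueError(f"item {self.name} declares no levels")
        if any(s < 0 or s > 1 for s in scores):
            raise ValueError(f"item {self.name}: scores must lie in [0, 1]")
        if self.kind == "binary":
            if sorted(set(scores)) != [0.0, 1.0]:
                raise ValueError(f"binary item {self.name} must score {{0, 1}}")
        else:
            if scores != sorted(scores):
                raise ValueError(f"ordinal item {self.name}: scores must be non-decreasing")
            if scores[0] != 0.0 or scores[-1] != 1.0:
                raise ValueError(f"ordinal item {self.name}: scores must span [0, 1]")

    @property
    def n_levels(self) -> int:
        return len(self.level_scores)


@dataclass(frozen=True)
class DeficitCodebook:
    items: Sequence[DeficitItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def to_json(self, path: str) -> None:
        payload = [
            {
                "name": it.name,
                "kind": it.kind,
                "levels": list(it.level_scores.keys()),
                "scores": list(it.level_scores.values()),
            }
            for it in self.items
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "DeficitCodebook":
        with open(path) as fh:
            payload = json.load(fh)
        items = [
            DeficitItem(d["name"], d["kind"], dict(zip(d["levels"], d["scores"])))
            for d in payload
        ]
        return cls(items)


def equally_spaced_scores(n_levels: int) -> list[float]:
    """Default ordinal mapping: levels 0..K-1 onto 0, 1/(K-1), ..., 1."""
    if n_levels < 2:
        raise ValueError("an item needs at least two levels")
    return [k / (n_levels - 1) for k in range(n_levels)]


def default_codebook(n_items: int = 49) -> DeficitCodebook:
    """Structurally realistic 49-item codebook.

    Forty binary items (self-reported conditions, symptoms and functional
    limitations) and nine ordinal items (severity-graded ratings such as
    self-rated health, 3 or 5 levels) with equally spaced scores.  The item
    set is a synthetic stand-in with the coding structure of a standard
    UK-Biobank-style deficit list, not a clone of any published item list.
    """
    items: list[DeficitItem] = []
    n_ordinal3, n_ordinal5 = 5, 4
    n_binary = n_items - n_ordinal3 - n_ordinal5
    for i in range(n_binary):
        items.append(
            DeficitItem(f"deficit_bin_{i + 1:02d}", "binary", {0: 0.0, 1: 1.0})
        )
    for i in range(n_ordinal3):
        items.append(
            DeficitItem(
                f"deficit_ord3_{i + 1}",
                "ordinal",
                dict(zip(range(3), equally_spaced_scores(3))),
            )
        )
    for i in range(n_ordinal5):
        items.append(
            DeficitItem(
                f"deficit_ord5_{i + 1}",
                "ordinal",
                dict(zip(range(5), equally_spaced_scores(5))),
            )
        )
    return DeficitCodebook(items)


@dataclass(frozen=True)
class FrailtyScore:
    fi: float
    category: str
    n_items_scored: int


def code_deficit(response, item: DeficitItem) -> float:
    """Map a raw response level onto its deficit score.

    Missing responses (None / NaN) propagate as NaN without raising.
    """
    if response is None or (isinstance(response, float) and np.isnan(response)):
        return float("nan")
    for level, score in item.level_scores.items():
        if response == level:
            return float(score)
    raise CodingError(
        f"item {item.name!r}: response {response!r} is not a declared level "
        f"(declared: {list(item.level_scores.keys())})"
    )


def classify_fi(fi: float) -> str:
    """Robust iff FI <= 0.12; frail iff FI >= 0.24; pre-frail otherwise."""
    if not (0.0 <= fi <= 1.0):
        raise ValueError(f"frailty index {fi} outside [0, 1]")
    if fi <= ROBUST_CUT:
        return "robust"
    if fi >= FRAIL_CUT:
        return "frail"
    return "pre_frail"


def compute_fi(
    scores: Sequence[float],
    *,
    min_fraction_scored: float | None = None,
) -> FrailtyScore:
    """Frailty index from a per-item score vector.

    By default (``min_fraction_scored=None``) the index uses the full
    complete-case denominator: FI = sum(scores) / n_items, and any missing
    item yields FI = NaN / category ``"incomplete"`` so the participant can
    be excluded upstream.  With ``min_fraction_scored`` set, participants
    scoring at least that fraction of items get FI = sum / n_scored instead.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    if np.any((arr < 0) | (arr > 1)) and not np.all(np.isnan(arr[(arr < 0) | (arr > 1)])):
        raise ValueError("deficit scores must lie in [0, 1]")
    n_scored = int(np.sum(~np.isnan(arr)))
    if min_fraction_scored is None:
        if n_scored < arr.size:
            return FrailtyScore(float("nan"), "incomplete", n_scored)
        fi = float(arr.sum() / arr.size)
    else:
        if n_scored / arr.size < min_fraction_scored:
            return FrailtyScore(float("nan"), "incomplete", n_scored)
        fi = float(np.nansum(arr) / n_scored)
    return FrailtyScore(fi, classify_fi(fi), n_scored)


def score_cohort(
    cohort: pd.DataFrame,
    codebook: DeficitCodebook,
    *,
    min_fraction_scored: float | None = None,
) -> pd.DataFrame:
    """Append ``fi`` and ``fi_category`` columns computed from deficit columns.

    Each codebook item name must be a column of raw response levels in
    ``cohort``.  Vectorised over the cohort; the per-participant semantics
    are those of :func:`code_deficit` + :func:`compute_fi`.
    """
    missing_cols = [it.name for it in codebook if it.name not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks deficit columns: {missing_cols[:5]} ...")
    score_mat = np.full((len(cohort), len(codebook)), np.nan)
    for j, item in enumerate(codebook):
        col = cohort[item.name]
        mapped = col.map(item.level_scores)
        bad = mapped.isna() & col.notna()
        if bad.any():
            value = col[bad].iloc[0]
            raise CodingError(
                f"item {item.name!r}: response {value!r} is not a declared level"
            )
        score_mat[:, j] = mapped.to_numpy(dtype=float)
    out = cohort.copy()
    if min_fraction_scored is None:
        complete = ~np.isnan(score_mat).any(axis=1)
        fi = np.where(complete, score_mat.sum(axis=1) / len(codebook), np.nan)
    else:
        n_scored = (~np.isnan(score_mat)).sum(axis=1)
        ok = n_scored / len(codebook) >= min_fraction_scored
        with np.errstate(invalid="ignore"):
            fi = np.where(ok, np.nansum(score_mat, axis=1) / n_scored, np.nan)
    out["fi"] = fi
    cats = np.where(
        np.isnan(fi),
        "incomplete",
        np.where(fi <= ROBUST_CUT, "robust", np.where(fi >= FRAIL_CUT, "frail", "pre_frail")),
    )
    out["fi_category"] = cats
    return out
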