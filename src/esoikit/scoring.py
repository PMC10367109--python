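"""Cleaning and scoring of ESOI questionnaire records.

The Epstein Sexual Orientation Inventory (ESOI) has 18 items on a
0-3 ordinal scale: nine about opposite-sex (OS) fantasies, attractions
and behaviors, nine about same-sex (SS) ones.  Each item is normalized
to [0, 1]; the subscale inclinations are

    o = sum of normalized OS items   (in [0, 9])
    s = sum of normalized SS items   (in [0, 9])

and the derived scores place the respondent on the 0-18 continuum:

    MSO  = 9 + s - o        midpoint of the two inclination points
    SOR  = o + s            breadth of the spanned interval
    sex drive = 10 * mean normalized intensity over answered items
    deviation = |MSO - expected MSO of the self-label|
                (expected 0 for straight, 18 for gay/lesbian; undefined
                for other labels)

Cleaning mirrors the survey protocol: drop records with fewer than half
the items answered, drop respondents reporting English fluency below 6
on a 1-10 scale, and for repeat submissions by the same user on the same
calendar day keep only the earliest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_COLUMNS",
    "OS_COLUMNS",
    "SS_COLUMNS",
    "LABELS",
    "CleaningReport",
    "clean_records",
    "score_subscales",
    "compute_mso",
    "compute_sor",
    "compute_sex_drive",
    "deviation_score",
    "score_table",
]

OS_COLUMNS = tuple(f"os{i}" for i in range(1, 10))
SS_COLUMNS = tuple(f"ss{i}" for i in range(1, 10))
ITEM_COLUMNS = OS_COLUMNS + SS_COLUMNS

ITEM_MAX = 3  # 4-point ordinal response scale 0..3

LABELS = ("straight", "gay/lesbian", "bisexual", "asexual", "other", "unsure")

#: Continuum anchor each self-label is expected to sit at.
EXPECTED_MSO = {"straight": 0.0, "gay/lesbian": 18.0}

MIN_ANSWERED = 9  # "fewer than half answered" removes records with < 9
MIN_FLUENCY = 6


@dataclass(frozen=True)
class CleaningReport:
    """Per-rule removal counts for one cleaning pass."""

    n_input: int
    n_removed_incomplete: int
    n_removed_fluency: int
    n_removed_duplicate: int
    n_retained: int
    n_missing_fluency: int = 0  # removed under the fluency rule with no rating at all

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_removed_incomplete
            + self.n_removed_fluency
            + self.n_removed_duplicate
        )
        if total != self.n_input:
            raise ValueError("cleaning report counts do not add up")

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _item_matrix(records: pd.DataFrame) -> np.ndarray:
    missing = [c for c in ITEM_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack item columns: {missing}")
    return records[list(ITEM_COLUMNS)].to_numpy(dtype=float)


def clean_records(records: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the three cleaning rules, in order, and report removals.

    1. incompleteness: fewer than 9 of 18 items answered;
    2. fluency: self-rated English fluency below 6 (a missing rating
       also fails, and is counted separately in the report);
    3. duplicates: same user key on the same calendar date -> keep the
       earliest timestamp only.

    Returns the retained rows (original order preserved) and a
    :class:`CleaningReport`. Cleaning is idempotent.
    """
    n_input = len(records)
    items = _item_matrix(records)
    answered = (~np.isnan(items)).sum(axis=1)
    keep = answered >= MIN_ANSWERED
    n_incomplete = int((~keep).sum())
    df = records.loc[keep]

    fluency = pd.to_numeric(df["fluency"], errors="coerce")
    fl_ok = fluency >= MIN_FLUENCY
    n_missing_fluency = int(fluency.isna().sum())
    n_fluency = int((~fl_ok).sum())
    df = df.loc[fl_ok.to_numpy()]

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    dup_sized = df.groupby("user_key")["user_key"].transform("size") > 1
    if ts.isna()[dup_sized].any():
        bad = df.loc[ts.isna() & dup_sized]
        raise ValueError(
            f"missing timestamp on duplicate-candidate record(s): "
            f"{bad.index.tolist()[:5]}"
        )
    key = pd.DataFrame({"user_key": df["user_key"], "date": ts.dt.date, "ts": ts})
    first_idx = key.sort_values("ts", kind="stable").groupby(
        ["user_key", "date"], dropna=False
    ).head(1).index
    n_dup = len(df) - len(first_idx)
    df = df.loc[df.index.isin(first_idx)]

    report = CleaningReport(
        n_input=n_input,
        n_removed_incomplete=n_incomplete,
        n_removed_fluency=n_fluency,
        n_removed_duplicate=n_dup,
        n_retained=len(df),
        n_missing_fluency=n_missing_fluency,
    )
    return df, report


def score_subscales(items) -> tuple[float, float]:
    """Subscale inclinations (o, s) for one 18-item response vector.

    ``items``: sequence of 18 values in {0..3}, NaN/None for missing;
    the first nine are the OS items, the last nine the SS items. A
    subscale with unanswered items is rescaled by 9/answered (mean
    imputation); an entirely unanswered subscale scores 0 with a warning.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (18,):
        raise ValueError("expected exactly 18 item responses")
    answered = ~np.isnan(arr)
    if answered.sum() < MIN_ANSWERED:
        raise ValueError("record has fewer than 9 answered items; clean first")
    if np.any((arr[answered] < 0) | (arr[answered] > ITEM_MAX)):
        raise ValueError(f"item responses must lie in 0..{ITEM_MAX}")

    out = []
    for half in (arr[:9], arr[9:]):
        k = int((~np.isnan(half)).sum())
        if k == 0:
            warnings.warn(
                "entirely unanswered subscale scored as 0", RuntimeWarning, stacklevel=2
            )
            out.append(0.0)
        else:
            out.append(float(np.nansum(half) / ITEM_MAX * (9.0 / k)))
    return out[0], out[1]


def compute_mso(o: float, s: float) -> float:
    """Mean sexual orientation: midpoint of the OS point (18 - 2o) and SS point (2s)."""
    _check_subscale(o, s)
    return 9.0 + s - o


def compute_sor(o: float, s: float) -> float:
    """Sexual orientation range: breadth o + s of the spanned interval."""
    _check_subscale(o, s)
    return o + s


def _check_subscale(o: float, s: float) -> None:
    if not (0.0 <= o <= 9.0 and 0.0 <= s <= 9.0):
        raise ValueError(f"subscale scores must lie in [0, 9], got o={o}, s={s}")


def compute_sex_drive(items) -> float:
    """Overall intensity: 10 x mean normalized response over answered items."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (18,):
        raise ValueError("expected exactly 18 item responses")
    answered = ~np.isnan(arr)
    if not answered.any():
        raise ValueError("no answered items")
    return float(10.0 * np.nanmean(arr) / ITEM_MAX)


def deviation_score(label: str, mso: float):
    """Distance of MSO from the label's expected continuum anchor.

    Defined only for straight (anchor 0) and gay/lesbian (anchor 18);
    any other label returns NaN, the explicit "undefined" sentinel.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    if not (0.0 <= mso <= 18.0):
        raise ValueError("mso must lie in [0, 18]")
    anchor = EXPECTED_MSO.get(label)
    if anchor is None:
        return float("nan")
    return abs(mso - anchor)


def score_table(records: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a cleaned table.

    Returns a copy with columns ``o, s, mso, sor, sex_drive, deviation``
    appended. Vectorized equivalent of the per-record scorers above.
    """
    items = _item_matrix(records)
    answered = ~np.isnan(items)
    if np.any(answered.sum(axis=1) < MIN_ANSWERED):
        raise ValueError("table contains records with < 9 answered items; clean first")

    def subscale(half, mask):
        k = mask.sum(axis=1)
        raw = np.nansum(np.where(mask, half, 0.0), axis=1) / ITEM_MAX
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(k > 0, raw * 9.0 / np.maximum(k, 1), 0.0)
        return score

    o = subscale(items[:, :9], answered[:, :9])
    s = subscale(items[:, 9:], answered[:, 9:])

    out = records.copy()
    out["o"] = o
    out["s"] = s
    out["mso"] = 9.0 + s - o
    out["sor"] = o + s
    out["sex_drive"] = 10.0 * np.nanmean(items, axis=1) / ITEM_MAX
    labels = out["label"].to_numpy()
    mso = out["mso"].to_numpy()
    dev = np.full(len(out), np.nan)
    dev[labels == "straight"] = mso[labels == "straight"]
    dev[labels == "gay/lesbian"] = 18.0 - mso[labels == "gay/lesbian"]
    out["deviation"] = dev
    return out
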