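"""Synthetic questionnaire cohorts with the structure the analyses assume.

No public accession exists for the survey data, so this module generates
respondent tables whose statistical structure matches what the analysis
stages expect: a latent mean-sexual-orientation (MSO) draw from the
social-pressure mixture, a conditional orientation-range (SOR) draw on
its feasible interval, expansion into 18 item responses that re-score to
the latent subscale values, label assignment with realistic overlap,
rank-correlated distress and uncertainty via a Gaussian copula, and
configurable contamination (incomplete records, low-fluency respondents,
same-day duplicate submissions) for exercising the cleaning rules.

Latent pipeline per respondent
------------------------------
1. m  ~ pressure mixture truncated to [0, 18]        (MSO)
2. r  ~ scaled Beta on [|m-9|, 18-|m-9|]             (SOR, always feasible)
3. o = (9 - m + r)/2, s = (m - 9 + r)/2              (subscale inclinations)
4. items: largest-remainder allocation of round(3*o) points over 9 OS
   items (likewise SS) plus one point-preserving random swap, so
   re-scoring reproduces o and s to within 1/6 of a point
5. label ~ softmax over distance of m to the label anchors
   (straight at 0, gay/lesbian at 18, the rest at 9)
6. distress rank-correlated with the label's deviation score through a
   Gaussian copula (Spearman target converted by rho_p = 2 sin(pi rho_s/6))
7. uncertainty rank-correlated with latent distress the same way
8. changed_so ~ Bernoulli(logistic(slope*(m - 9) + intercept))
9. demographics drawn independently from configured margins
10. contamination rows appended, with a manifest of their ids
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .model import PressureMixture, apply_pressure
from .sas import SinhArcsinhParams
from .scoring import ITEM_COLUMNS, LABELS

__all__ = [
    "LabelRule",
    "Contamination",
    "CohortConfig",
    "generate_cohort",
    "inject_contamination",
    "spearman_to_pearson",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = (
    ("record_id", "user_key", "timestamp")
    + ITEM_COLUMNS
    + (
        "label",
        "distress",
        "uncertainty",
        "changed_so",
        "fluency",
        "age",
        "gender",
        "race",
        "education",
        "country",
    )
)

#: Continuum anchors of the self-labels; the four centre labels share 9
#: and differ only by prior weight.
LABEL_ANCHORS = {
    "straight": 0.0,
    "gay/lesbian": 18.0,
    "bisexual": 9.0,
    "asexual": 9.0,
    "other": 9.0,
    "unsure": 9.0,
}


def _normalized(d: dict) -> dict:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


def _default_margins() -> dict:
    # marginal rates reported for the survey sample (age given as bands)
    return {
        "age": _normalized(
            {"12-17": 0.47, "18-24": 0.30, "25-34": 0.12, "35-49": 0.07, "50-95": 0.04}
        ),
        "gender": _normalized({"female": 0.542, "male": 0.430, "other": 0.027}),
        "race": _normalized(
            {
                "american_indian": 0.008,
                "asian": 0.104,
                "black": 0.056,
                "hispanic": 0.073,
                "other": 0.074,
                "white": 0.684,
            }
        ),
        "education": _normalized(
            {
                "none": 0.210,
                "high_school": 0.444,
                "associate": 0.040,
                "bachelors": 0.229,
                "masters": 0.060,
                "doctorate": 0.017,
            }
        ),
        "country": _normalized(
            {"US": 0.450, "UK": 0.120, "Canada": 0.069, "other": 0.361}
        ),
    }

_AGE_BANDS = {
    "12-17": (12, 17),
    "18-24": (18, 24),
    "25-34": (25, 34),
    "35-49": (35, 49),
    "50-95": (50, 95),
}


@dataclass(frozen=True)
class LabelRule:
    """Softmax label assignment over distance to continuum anchors.

    P(label | m) is proportional to weight * exp(-|m - anchor| / temperature);
    larger temperatures produce broader, more overlapping label
    distributions (mismatch between label and inclinations).
    """

    temperature: float = 3.0
    weights: dict = field(
        default_factory=lambda: _normalized(
            {
                "straight": 0.244,
                "gay/lesbian": 0.074,
                "bisexual": 0.139,
                "asexual": 0.012,
                "other": 0.028,
                "unsure": 0.503,
            }
        )
    )

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError("temperature must be > 0")
        if set(self.weights) - set(LABELS):
            raise ValueError("label weights name unknown labels")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("label weights must be non-negative")
        anchors = sorted(
            LABEL_ANCHORS[l] for l in ("straight", "bisexual", "gay/lesbian")
        )
        if not (anchors[0] < anchors[1] < anchors[2]):
            raise ValueError("label anchors must be strictly increasing")


@dataclass(frozen=True)
class Contamination:
    """Rates (relative to n) of the three dirty-record classes."""

    incomplete_rate: float = 0.06
    low_fluency_rate: float = 0.04
    duplicate_rate: float = 0.03

    def __post_init__(self) -> None:
        for name in ("incomplete_rate", "low_fluency_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def _default_base_model() -> PressureMixture:
    # components at the full-sample location/scale (M = 8.5, SD = 3.4)
    comp = SinhArcsinhParams(mu=8.5, sigma=3.4)
    return PressureMixture(comp_nonss=comp, comp_ss=comp)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic population."""

    n: int = 1000
    seed: int = 0
    pressure: float = 0.0
    base_model: PressureMixture = field(default_factory=_default_base_model)
    sor_shape: tuple = (2.0, 2.0)
    label_rule: LabelRule = field(default_factory=LabelRule)
    distress_rho_by_label: dict = field(
        default_factory=lambda: {"straight": 0.29, "gay/lesbian": 0.10}
    )
    uncertainty_rho: float = 0.63
    changed_slope: float = 0.3
    changed_intercept: float = -1.0
    demo_margins: dict = field(default_factory=_default_margins)
    contamination: Contamination = field(default_factory=Contamination)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(a <= 0 for a in self.sor_shape):
            raise ValueError("sor_shape parameters must be > 0")
        for label, rho in self.distress_rho_by_label.items():
            if label not in ("straight", "gay/lesbian"):
                raise ValueError(f"deviation is undefined for label {label!r}")
            spearman_to_pearson(rho)  # validates range
        spearman_to_pearson(self.uncertainty_rho)
        for name, margin in self.demo_margins.items():
            if abs(sum(margin.values()) - 1.0) > 1e-9:
                raise ValueError(f"margin {name!r} does not sum to 1")
            if any(p < 0 for p in margin.values()):
                raise ValueError(f"margin {name!r} has negative mass")


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion rho_p = 2 sin(pi rho_s / 6).

    Rejects targets whose conversion leaves (-1, 1).
    """
    if not (-1.0 < rho_s < 1.0):
        raise ValueError(f"Spearman target must lie in (-1, 1), got {rho_s}")
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    if not (-1.0 < rho_p < 1.0):
        raise ValueError(f"copula conversion of {rho_s} leaves (-1, 1)")
    return rho_p


# ---------------------------------------------------------------------------
# latent draws
# ---------------------------------------------------------------------------


def _draw_mso(mixture: PressureMixture, n: int, rng) -> np.ndarray:
    """Rejection-sample the mixture truncated to [0, 18]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = mixture.sample(max(n - filled, 1000), rng)
        ok = draw[(draw >= 0.0) & (draw <= 18.0)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _draw_sor(m: np.ndarray, shape: tuple, rng) -> np.ndarray:
    lo = np.abs(m - 9.0)
    hi = 18.0 - lo
    r = lo + (hi - lo) * rng.beta(shape[0], shape[1], size=m.size)
    if np.any((r < lo - 1e-9) | (r > hi + 1e-9)):
        raise RuntimeError("infeasible (m, r) pair generated")  # unreachable
    return r


def _expand_items(score: np.ndarray, rng) -> np.ndarray:
    """Expand subscale scores in [0, 9] into 9 ordinal items in 0..3.

    Largest-remainder allocation of round(3*score) points (equal quotas,
    remainder to randomly chosen items) followed by one random
    point-preserving swap. Column sums divided by 3 recover the score to
    within the rounding error of 1/6.
    """
    n = score.size
    total = np.round(3.0 * score).astype(int)  # 0..27
    base, rem = np.divmod(total, 9)
    items = np.tile(base[:, None], (1, 9))
    # remainder points go to the first `rem` slots of a random permutation
    perm = np.argsort(rng.random((n, 9)), axis=1)
    items[perm < rem[:, None]] += 1

    # swap noise: move one point between two random items where legal
    i = rng.integers(0, 9, size=n)
    j = (i + rng.integers(1, 9, size=n)) % 9
    rows = np.arange(n)
    can = (items[rows, i] > 0) & (items[rows, j] < 3)
    items[rows[can], i[can]] -= 1
    items[rows[can], j[can]] += 1
    return items


def _draw_labels(m: np.ndarray, rule: LabelRule, rng) -> np.ndarray:
    labels = [l for l in LABELS if rule.weights.get(l, 0.0) > 0]
    w = np.array([rule.weights[l] for l in labels])
    anchors = np.array([LABEL_ANCHORS[l] for l in labels])
    logits = w[None, :] * np.exp(-np.abs(m[:, None] - anchors[None, :]) / rule.temperature)
    probs = logits / logits.sum(axis=1, keepdims=True)
    u = rng.random(m.size)
    idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.array(labels, dtype=object)[idx]


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - 0.5) / values.size)


def _discretize_decile(z: np.ndarray) -> np.ndarray:
    """Map latent normal scores to a 1..10 ordinal scale via their CDF."""
    return np.clip(np.ceil(10.0 * stats.norm.cdf(z)), 1, 10).astype(int)


def _draw_distress_uncertainty(m, labels, config: CohortConfig, rng):
    n = m.size
    z_lat = rng.standard_normal(n)  # latent distress, independent by default
    for label, rho_s in config.distress_rho_by_label.items():
        mask = labels == label
        k = int(mask.sum())
        if k < 2 or rho_s == 0.0:
            continue
        dev = m[mask] if label == "straight" else 18.0 - m[mask]
        z_dev = _normal_scores(dev)
        rho_p = spearman_to_pearson(rho_s)
        z_lat[mask] = rho_p * z_dev + math.sqrt(1.0 - rho_p**2) * z_lat[mask]
    distress = _discretize_decile(z_lat)

    rho_pu = spearman_to_pearson(config.uncertainty_rho)
    z_unc = rho_pu * z_lat + math.sqrt(1.0 - rho_pu**2) * rng.standard_normal(n)
    uncertainty = _discretize_decile(z_unc)
    return distress, uncertainty


def _draw_margin(margin: dict, n: int, rng) -> np.ndarray:
    cats = np.array(list(margin.keys()), dtype=object)
    p = np.array(list(margin.values()))
    return rng.choice(cats, size=n, p=p / p.sum())


def _draw_ages(margin: dict, n: int, rng) -> np.ndarray:
    bands = _draw_margin(margin, n, rng)
    ages = np.empty(n, dtype=int)
    for band, (lo, hi) in _AGE_BANDS.items():
        mask = bands == band
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return ages


def _timestamps(n: int, rng) -> pd.Series:
    # submission window of ~8 years; times kept before 22:00 so a same-day
    # duplicate one hour later never crosses midnight
    days = rng.integers(0, 2900, size=n)
    secs = rng.integers(0, 22 * 3600, size=n)
    base = pd.Timestamp("2013-01-01")
    return pd.Series(
        base + pd.to_timedelta(days, unit="D") + pd.to_timedelta(secs, unit="s")
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a respondent table plus a contamination manifest.

    Returns exactly ``config.n`` clean rows followed by the configured
    contamination rows; deterministic for a given config (the seed is
    part of the config). The manifest maps each contamination class to
    the record ids it injected.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    mixture = config.base_model
    if config.pressure != 0.0:
        mixture = apply_pressure(mixture, config.pressure)

    m = _draw_mso(mixture, n, rng)
    r = _draw_sor(m, config.sor_shape, rng)
    o = np.clip((9.0 - m + r) / 2.0, 0.0, 9.0)
    s = np.clip((m - 9.0 + r) / 2.0, 0.0, 9.0)

    os_items = _expand_items(o, rng)
    ss_items = _expand_items(s, rng)

    labels = _draw_labels(m, config.label_rule, rng)
    distress, uncertainty = _draw_distress_uncertainty(m, labels, config, rng)
    changed = rng.random(n) < expit(
        config.changed_slope * (m - 9.0) + config.changed_intercept
    )

    df = pd.DataFrame(
        {
            "record_id": [f"r{i:07d}" for i in range(n)],
            "user_key": [f"u{i:07d}" for i in range(n)],
            "timestamp": _timestamps(n, rng),
        }
    )
    for k, col in enumerate(ITEM_COLUMNS):
        df[col] = pd.array(
            os_items[:, k] if k < 9 else ss_items[:, k - 9], dtype="Int64"
        )
    df["label"] = labels
    df["distress"] = pd.array(distress, dtype="Int64")
    df["uncertainty"] = pd.array(uncertainty, dtype="Int64")
    df["changed_so"] = changed
    df["fluency"] = pd.array(rng.integers(6, 11, size=n), dtype="Int64")
    df["age"] = _draw_ages(config.demo_margins["age"], n, rng)
    df["gender"] = _draw_margin(config.demo_margins["gender"], n, rng)
    df["race"] = _draw_margin(config.demo_margins["race"], n, rng)
    df["education"] = _draw_margin(config.demo_margins["education"], n, rng)
    df["country"] = _draw_margin(config.demo_margins["country"], n, rng)

    return inject_contamination(df, config, rng)


def inject_contamination(
    table: pd.DataFrame, config: CohortConfig, rng=None
) -> tuple[pd.DataFrame, dict]:
    """Append the configured dirty rows and return (table, manifest).

    Three classes are injected, each derived from randomly chosen clean
    rows: records with more than 9 missing items, records with fluency
    below 6, and same-user same-day re-submissions with a later
    timestamp. The manifest lists injected record ids per class.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(table)
    cont = config.contamination
    counts = {
        "incomplete": int(round(cont.incomplete_rate * config.n)),
        "low_fluency": int(round(cont.low_fluency_rate * config.n)),
        "duplicate": int(round(cont.duplicate_rate * config.n)),
    }
    if any(c > n for c in counts.values()):
        raise ValueError("contamination counts exceed the clean-row count")

    manifest = {k: [] for k in counts}
    pieces = [table]
    next_id = n

    def _fresh(row_idx, kind):
        nonlocal next_id
        rows = table.iloc[row_idx].copy()
        ids = [f"r{next_id + i:07d}" for i in range(len(rows))]
        rows["record_id"] = ids
        manifest[kind].extend(ids)
        next_id += len(rows)
        return rows

    if counts["incomplete"]:
        rows = _fresh(rng.choice(n, counts["incomplete"], replace=False), "incomplete")
        rows["user_key"] = [f"u_inc{i:06d}" for i in range(len(rows))]
        # blank 13 of 18 items -> 5 answered, fails the half-answered rule
        k = len(rows)
        blank = np.argsort(rng.random((k, 18)), axis=1) < 13
        items = rows[list(ITEM_COLUMNS)].to_numpy(dtype=float)
        items[blank] = np.nan
        for c, col in enumerate(ITEM_COLUMNS):
            rows[col] = pd.array(items[:, c], dtype="Int64")
        pieces.append(rows)

    if counts["low_fluency"]:
        rows = _fresh(rng.choice(n, counts["low_fluency"], replace=False), "low_fluency")
        rows["user_key"] = [f"u_flu{i:06d}" for i in range(len(rows))]
        rows["fluency"] = pd.array(
            rng.integers(1, 6, size=len(rows)), dtype="Int64"
        )
        pieces.append(rows)

    if counts["duplicate"]:
        chosen = rng.choice(n, counts["duplicate"], replace=False)
        rows = _fresh(chosen, "duplicate")
        # same user, same calendar day, strictly later submission
        rows["timestamp"] = table.iloc[chosen]["timestamp"].to_numpy() + pd.Timedelta(
            hours=1
        )
        pieces.append(rows)

    out = pd.concat(pieces, ignore_index=True) if len(pieces) > 1 else table
    return out, manifest
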