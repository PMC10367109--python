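"""Descriptive and inferential battery for scored cohorts.

Everything the survey analysis reports: the 19-bin MSO histogram, moment
skewness/kurtosis, label deviation curves, nonparametric group
comparisons (Kruskal-Wallis H, Mann-Whitney U, Kolmogorov-Smirnov D,
Spearman rho) plus Cohen's d, demographic raking to population margins,
and per-subgroup skewness reports for the sampling-bias splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import BIN_EDGES

__all__ = [
    "HistogramMSO",
    "GroupComparison",
    "mso_histogram",
    "moment_skew_kurtosis",
    "deviation_curve",
    "group_tests",
    "cohens_d",
    "rake_weights",
    "demographic_match_resample",
    "subgroup_skew_report",
    "SPLIT_SPECS",
]


@dataclass(frozen=True)
class HistogramMSO:
    """19-bin histogram of MSO scores, bins centred at the integers 0..18."""

    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return np.arange(19, dtype=float)

    @property
    def edges(self) -> np.ndarray:
        return BIN_EDGES.copy()

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GroupComparison:
    """One inferential result: statistic, p-value and group descriptives."""

    statistic: str  # H | U | D | d | rho
    value: float
    p_value: float
    group_sizes: tuple
    group_means: tuple
    group_sds: tuple

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def mso_histogram(scores) -> HistogramMSO:
    """Bin MSO scores into unit bins [k - 0.5, k + 0.5), last bin closed."""
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0.0) | (scores > 18.0)):
        raise ValueError("MSO scores must lie in [0, 18]")
    counts, _ = np.histogram(scores, bins=BIN_EDGES)
    return HistogramMSO(counts=counts)


def moment_skew_kurtosis(values) -> tuple[float, float]:
    """Third and fourth standardized central moments (kurtosis non-excess)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        raise ValueError("constant input has undefined moments")
    return float(sps.skew(values)), float(sps.kurtosis(values, fisher=False))


def deviation_curve(labels, msos) -> dict:
    """Per-label cumulative percentage with deviation >= d, d = 0..18.

    Only the anchored labels (straight, expected MSO 0; gay/lesbian,
    expected 18) have deviation scores. Each curve starts at 100% and is
    non-increasing; a label absent from the input is simply absent from
    the result.
    """
    labels = np.asarray(labels, dtype=object)
    msos = np.asarray(msos, dtype=float)
    bad = set(np.unique(labels)) - {"straight", "gay/lesbian"}
    if bad:
        raise ValueError(f"deviation curves defined only for anchored labels; got {bad}")
    curves = {}
    d_grid = np.arange(19)
    for label, anchor in (("straight", 0.0), ("gay/lesbian", 18.0)):
        mask = labels == label
        if not mask.any():
            continue
        dev = np.abs(msos[mask] - anchor)
        curves[label] = np.array(
            [100.0 * np.mean(dev >= d) for d in d_grid]
        )
    return curves


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def group_tests(values, groups=None, kind: str = "H") -> GroupComparison:
    """Run one of the report's tests and package the result.

    kind
        ``H``   Kruskal-Wallis across >= 2 groups (tie-corrected);
        ``U``   Mann-Whitney across exactly 2 groups (two-sided);
        ``D``   two-sample Kolmogorov-Smirnov across exactly 2 groups;
        ``d``   Cohen's d with pooled SD (no p-value);
        ``rho`` Spearman rank correlation; here ``values`` and
        ``groups`` are the two paired vectors.
    """
    if kind == "rho":
        x = np.asarray(values, dtype=float)
        y = np.asarray(groups, dtype=float)
        if x.size != y.size:
            raise ValueError("rho requires paired vectors of equal length")
        res = sps.spearmanr(x, y)
        return GroupComparison(
            "rho",
            float(res.statistic),
            float(res.pvalue),
            (x.size,),
            (float(x.mean()), float(y.mean())),
            (float(x.std(ddof=1)), float(y.std(ddof=1))),
        )

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("group comparisons need at least two groups")
    samples = [values[groups == g] for g in uniq]
    sizes = tuple(int(s.size) for s in samples)
    means = tuple(float(s.mean()) for s in samples)
    sds = tuple(float(s.std(ddof=1)) if s.size > 1 else 0.0 for s in samples)

    if kind == "H":
        res = sps.kruskal(*samples)
        value, p = float(res.statistic), float(res.pvalue)
    elif kind in ("U", "D", "d"):
        if len(samples) != 2:
            raise ValueError(f"kind {kind!r} requires exactly two groups")
        if kind == "U":
            res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            value, p = float(res.statistic), float(res.pvalue)
        elif kind == "D":
            res = sps.ks_2samp(samples[0], samples[1])
            value, p = float(res.statistic), float(res.pvalue)
        else:
            value, p = cohens_d(samples[0], samples[1]), float("nan")
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return GroupComparison(kind, value, p, sizes, means, sds)


# ---------------------------------------------------------------------------
# demographic matching
# ---------------------------------------------------------------------------


def rake_weights(
    records: pd.DataFrame,
    target_margins: dict,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterative proportional fitting of case weights to target margins.

    Cycles through the margin variables multiplying weights so each
    variable's weighted distribution matches its target, until every
    margin agrees within ``tol``. Raises if a target category is empty
    in the data (unattainable margin).
    """
    w = np.ones(len(records))
    cols = {var: records[var].to_numpy() for var in target_margins}
    for var, margin in target_margins.items():
        for cat, p in margin.items():
            if p > 0 and not np.any(cols[var] == cat):
                raise ValueError(f"margin {var!r} unattainable: no records with {cat!r}")
    for _ in range(max_iter):
        worst = 0.0
        for var, margin in target_margins.items():
            col = cols[var]
            for cat, p in margin.items():
                mask = col == cat
                cur = w[mask].sum() / w.sum()
                if p == 0:
                    w[mask] = 0.0
                    continue
                if cur > 0:
                    w[mask] *= p / cur
                worst = max(worst, abs(cur - p))
        if worst < tol:
            break
    return w / w.sum()


def demographic_match_resample(
    records: pd.DataFrame, target_margins: dict, m: int, seed=None
) -> pd.DataFrame:
    """Draw a margin-matched subsample of ``m`` records.

    Rakes case weights to the target margins, then samples ``m`` rows
    without replacement with probability proportional to weight.
    """
    if m > len(records):
        raise ValueError("subsample size exceeds available records")
    w = rake_weights(records, target_margins)
    rng = np.random.default_rng(seed)
    # systematic PPS sampling: inclusion probability m*w_i per record, so
    # the achieved margins are unbiased for the raked targets (sequential
    # weighted draws without replacement would drift toward the sample's
    # own margins)
    pi = m * w
    for _ in range(50):
        over = pi > 1.0
        if not over.any():
            break
        deficit = m - over.sum()
        rest = pi[~over].sum()
        pi[over] = 1.0
        pi[~over] *= deficit / rest
    # implicit stratification: order by the demographic cells (random
    # within cell) so the systematic pass allocates each cell its
    # proportional share to within one record
    cell = pd.MultiIndex.from_frame(records[list(target_margins)].reset_index(drop=True))
    order = np.lexsort((rng.random(len(records)), pd.factorize(cell)[0]))
    cum = np.cumsum(pi[order])
    points = rng.random() + np.arange(m)
    picks = order[np.searchsorted(cum, points)]
    return records.iloc[np.sort(picks)]


# ---------------------------------------------------------------------------
# subgroup skewness reports
# ---------------------------------------------------------------------------

SPLIT_SPECS = ("changed", "distress", "uncertainty", "combined", "age", "country")


def _split_masks(records: pd.DataFrame, split_spec: str) -> dict:
    if split_spec == "changed":
        changed = records["changed_so"].astype(bool)
        return {"changed": changed, "unchanged": ~changed}
    if split_spec in ("distress", "uncertainty"):
        v = pd.to_numeric(records[split_spec], errors="coerce")
        # "8 or over" vs "under 4"; 4-7 belongs to neither subgroup
        return {"high": v >= 8, "low": v < 4}
    if split_spec == "combined":
        d = pd.to_numeric(records["distress"], errors="coerce")
        u = pd.to_numeric(records["uncertainty"], errors="coerce")
        return {"low_both": (d < 4) & (u < 4), "rest": ~((d < 4) & (u < 4))}
    if split_spec == "age":
        age = pd.to_numeric(records["age"], errors="coerce")
        med = age.median()
        return {"younger": age < med, "older": age >= med}
    if split_spec == "country":
        core = records["country"].isin(["US", "UK", "Canada"])
        return {"us_uk_canada": core, "other": ~core}
    raise ValueError(f"unknown split spec {split_spec!r}; one of {SPLIT_SPECS}")


def subgroup_skew_report(records: pd.DataFrame, split_spec: str) -> pd.DataFrame:
    """Per-subgroup MSO skewness, plus KS D/p for two-subgroup splits.

    Empty subgroups are reported with NaN statistics rather than
    silently dropped.
    """
    masks = _split_masks(records, split_spec)
    mso = records["mso"].to_numpy(dtype=float)
    rows = []
    for name, mask in masks.items():
        vals = mso[mask.to_numpy()]
        if vals.size >= 3 and np.ptp(vals) > 0:
            skp, kurt = moment_skew_kurtosis(vals)
        else:
            skp, kurt = float("nan"), float("nan")
        rows.append({"split": split_spec, "subgroup": name, "n": vals.size,
                     "skp": skp, "kurtosis": kurt})
    report = pd.DataFrame(rows)
    if len(masks) == 2:
        a, b = (mso[m.to_numpy()] for m in masks.values())
        if a.size and b.size:
            ks = sps.ks_2samp(a, b)
            report["ks_d"] = float(ks.statistic)
            report["ks_p"] = float(ks.pvalue)
        else:
            report["ks_d"] = float("nan")
            report["ks_p"] = float("nan")
    return report
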