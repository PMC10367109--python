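"""Descriptive/inferential battery against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from esoikit.stats import (
    GroupComparison,
    demographic_match_resample,
    deviation_curve,
    group_tests,
    moment_skew_kurtosis,
    mso_histogram,
    rake_weights,
    subgroup_skew_report,
)


class TestHistogram:
    def test_single_scores_land_in_their_bins(self):
        h = mso_histogram([0.0, 9.0, 18.0])
        expected = np.zeros(19, dtype=int)
        expected[[0, 9, 18]] = 1
        np.testing.assert_array_equal(h.counts, expected)

    def test_edge_convention_half_open(self):
        h = mso_histogram([8.6, 9.4, 9.5, 8.5])
        assert h.counts[9] == 3  # 8.6, 9.4 and the left-closed 8.5
        assert h.counts[10] == 1  # 9.5 belongs to the next bin

    def test_counts_conserve_n(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 18, 1000)
        assert mso_histogram(x).n == 1000

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mso_histogram([-0.6])

    def test_symmetric_model_cohort_modal_bin_is_nine(self, symmetric_cohort_scored):
        h = mso_histogram(symmetric_cohort_scored["mso"])
        assert int(np.argmax(h.counts)) == 9


class TestMoments:
    def test_symmetric_list_has_zero_skew(self):
        skew, _ = moment_skew_kurtosis([1, 2, 3])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_hand_list_by_direct_enumeration(self):
        vals = np.array([0.0, 0.0, 0.0, 1.0])
        mean = vals.mean()
        sd = np.sqrt(np.mean((vals - mean) ** 2))
        exp_skew = np.mean(((vals - mean) / sd) ** 3)
        exp_kurt = np.mean(((vals - mean) / sd) ** 4)
        skew, kurt = moment_skew_kurtosis(vals)
        assert skew == pytest.approx(exp_skew, abs=1e-12)
        assert kurt == pytest.approx(exp_kurt, abs=1e-12)

    def test_large_gaussian_sample_near_normal_values(self):
        x = np.random.default_rng(1).standard_normal(200_000)
        skew, kurt = moment_skew_kurtosis(x)
        assert skew == pytest.approx(0.0, abs=0.02)
        assert kurt == pytest.approx(3.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            moment_skew_kurtosis([1, 2])
        with pytest.raises(ValueError):
            moment_skew_kurtosis([5, 5, 5, 5])


class TestDeviationCurves:
    def test_straights_at_their_anchor(self):
        curves = deviation_curve(["straight"] * 3, [0.0, 0.0, 0.0])
        assert curves["straight"][0] == 100.0
        assert np.all(curves["straight"][1:] == 0.0)

    def test_mixed_roster_equals_direct_counting(self):
        labels = ["straight"] * 6 + ["gay/lesbian"] * 4
        msos = [0, 2, 4.5, 7, 9, 13, 18, 16, 11.2, 5]
        curves = deviation_curve(labels, msos)
        for label, anchor in (("straight", 0.0), ("gay/lesbian", 18.0)):
            devs = [abs(m - anchor) for l, m in zip(labels, msos) if l == label]
            for d in range(19):
                expected = 100.0 * sum(v >= d for v in devs) / len(devs)
                assert curves[label][d] == pytest.approx(expected)

    def test_curves_monotone_non_increasing(self, symmetric_cohort_scored):
        sub = symmetric_cohort_scored[
            symmetric_cohort_scored["label"].isin(["straight", "gay/lesbian"])
        ]
        curves = deviation_curve(sub["label"].to_numpy(), sub["mso"].to_numpy())
        for curve in curves.values():
            assert curve[0] == 100.0
            assert np.all(np.diff(curve) <= 1e-12)

    def test_absent_label_yields_no_curve(self):
        curves = deviation_curve(["straight"] * 2, [1.0, 2.0])
        assert "gay/lesbian" not in curves

    def test_unanchored_labels_rejected(self):
        with pytest.raises(ValueError):
            deviation_curve(["bisexual"], [9.0])


def brute_force_mannwhitney_u(a, b):
    """U for sample a by pairwise comparison (ties count half)."""
    return sum(
        1.0 if x > y else 0.5 if x == y else 0.0 for x, y in itertools.product(a, b)
    )


def brute_force_kruskal_h(samples):
    """Tie-corrected H from mid-ranks, computed from the definition."""
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    h = 0.0
    i = 0
    for s in samples:
        r = ranks[i : i + s.size]
        h += r.sum() ** 2 / s.size
        i += s.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestGroupTests:
    def test_identical_groups_null_values(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        grp = np.repeat(["a", "b"], 4)
        assert group_tests(vals, grp, kind="d").value == pytest.approx(0.0)
        u = group_tests(vals, grp, kind="U").value
        assert u == pytest.approx(4 * 4 / 2)  # null mean n1*n2/2

    def test_h_matches_hand_computed_ranks(self):
        samples = [np.array([3.0, 7, 7]), np.array([1.0, 4]), np.array([9.0, 2, 5])]
        vals = np.concatenate(samples)
        grp = np.repeat(["x", "y", "z"], [3, 2, 3])
        got = group_tests(vals, grp, kind="H").value
        assert got == pytest.approx(brute_force_kruskal_h(samples), abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_u_matches_pairwise_enumeration_small_rosters(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=6).astype(float)
        b = rng.integers(0, 10, size=6).astype(float)
        got = group_tests(
            np.concatenate([a, b]), np.repeat(["a", "b"], 6), kind="U"
        ).value
        assert got == pytest.approx(brute_force_mannwhitney_u(a, b))

    def test_perfectly_monotone_pairs_give_rho_one(self):
        x = np.arange(10.0)
        assert group_tests(x, x**3, kind="rho").value == pytest.approx(1.0)

    def test_ks_detects_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 300)
        res = group_tests(
            np.concatenate([a, a + 2.0]), np.repeat(["a", "b"], 300), kind="D"
        )
        assert res.value > 0.5 and res.p_value < 1e-6

    def test_h_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=12)
        grp = np.repeat(["a", "b", "c"], 4)
        swapped = np.where(grp == "a", "c", np.where(grp == "c", "a", "b"))
        assert group_tests(vals, grp, "H").value == pytest.approx(
            group_tests(vals, swapped, "H").value
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests(np.arange(5.0), np.repeat("a", 5), kind="H")
        with pytest.raises(ValueError):
            group_tests(np.arange(6.0), np.repeat(["a", "b", "c"], 2), kind="U")

    def test_result_invariants(self):
        res = group_tests(np.arange(8.0), np.repeat(["a", "b"], 4), kind="U")
        assert isinstance(res, GroupComparison)
        assert 0 <= res.p_value <= 1
        assert res.group_sizes == (4, 4)


def _demo_frame(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gender": rng.choice(["female", "male"], size=n),
            "race": rng.choice(["white", "black", "asian"], size=n, p=[0.5, 0.3, 0.2]),
            "mso": rng.uniform(0, 18, size=n),
        }
    )


class TestRaking:
    def test_uniform_targets_on_balanced_data(self):
        df = _demo_frame(4000, 0)
        w = rake_weights(df, {"gender": {"female": 0.5, "male": 0.5}})
        assert w.sum() == pytest.approx(1.0)
        female = w[(df["gender"] == "female").to_numpy()].sum()
        assert female == pytest.approx(0.5, abs=1e-6)

    def test_sixty_forty_target_achieved_in_subsample(self):
        df = _demo_frame(20_000, 1)
        targets = {
            "gender": {"female": 0.6, "male": 0.4},
            "race": {"white": 0.7, "black": 0.2, "asian": 0.1},
        }
        sub = demographic_match_resample(df, targets, m=2_000, seed=2)
        got = sub["gender"].value_counts(normalize=True)
        assert got["female"] == pytest.approx(0.6, abs=0.01)
        race = sub["race"].value_counts(normalize=True)
        assert race["white"] == pytest.approx(0.7, abs=0.01)

    def test_resample_deterministic_given_seed(self):
        df = _demo_frame(2000, 3)
        targets = {"gender": {"female": 0.55, "male": 0.45}}
        a = demographic_match_resample(df, targets, m=200, seed=7)
        b = demographic_match_resample(df, targets, m=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_unattainable_margin_reports_variable(self):
        df = _demo_frame(100, 4)
        with pytest.raises(ValueError, match="race"):
            rake_weights(df, {"race": {"white": 0.5, "martian": 0.5}})

    def test_oversized_subsample_rejected(self):
        df = _demo_frame(50, 5)
        with pytest.raises(ValueError):
            demographic_match_resample(df, {"gender": {"female": 0.5, "male": 0.5}}, 60)


class TestSubgroupSkewReports:
    @staticmethod
    def _records(skew_a, skew_b, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        # lognormal-style positive skew, magnitude controlled per subgroup
        a = 9 + rng.normal(size=n) + skew_a * rng.exponential(size=n)
        b = 9 + rng.normal(size=n) + skew_b * rng.exponential(size=n)
        mso = np.clip(np.concatenate([a, b]), 0, 18)
        return pd.DataFrame(
            {
                "mso": mso,
                "changed_so": np.repeat([True, False], n),
                "distress": np.tile([9, 1], n),
                "uncertainty": np.tile([9, 1], n),
                "age": np.repeat([15, 30], n),
                "country": np.repeat(["US", "other"], n),
            }
        )

    def test_subgroup_skew_ordering_matches_generating_skews(self):
        records = self._records(skew_a=2.0, skew_b=0.3)
        rep = subgroup_skew_report(records, "changed").set_index("subgroup")
        assert rep.loc["changed", "skp"] > rep.loc["unchanged", "skp"]

    def test_identical_subgroups_have_near_zero_ks(self):
        rng = np.random.default_rng(1)
        mso = np.tile(rng.uniform(0, 18, 2000), 2)
        records = pd.DataFrame(
            {"mso": mso, "age": np.repeat([15, 30], 2000)}
        )
        rep = subgroup_skew_report(records, "age")
        assert rep["ks_d"].iloc[0] < 0.05

    def test_distress_split_thresholds(self):
        records = pd.DataFrame(
            {"mso": np.linspace(0, 18, 7), "distress": [8, 9, 10, 4, 7, 1, 3]}
        )
        rep = subgroup_skew_report(records, "distress").set_index("subgroup")
        assert rep.loc["high", "n"] == 3  # distress 8, 9, 10
        assert rep.loc["low", "n"] == 2  # distress 1, 3; the 4-7 band is excluded

    def test_empty_subgroup_reported_not_skipped(self):
        records = pd.DataFrame({"mso": [1.0, 2, 3], "changed_so": [True, True, True]})
        rep = subgroup_skew_report(records, "changed").set_index("subgroup")
        assert rep.loc["unchanged", "n"] == 0
        assert np.isnan(rep.loc["unchanged", "skp"])

    def test_unknown_split_rejected(self):
        with pytest.raises(ValueError):
            subgroup_skew_report(pd.DataFrame({"mso": [1.0]}), "zodiac")
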