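"""Kaplan-Meier, log-rank, cutoffs, Cox backward elimination, group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcnslkit import synthetic
from pcnslkit.survival import (
    cohort_compare,
    cox_backward,
    filter_survival_cohort,
    km_fit,
    logrank_chi2_two_group,
    logrank_test,
    optimal_cutoff,
    univariable_screen,
)


class TestCohortFilter:
    def test_mirrors_56_of_74_retention(self, default_cohort):
        """74 rows with exactly 18 failing (immunodeficient or no chemo) -> 56 kept."""
        df = default_cohort.copy()
        df["immune_deficient"] = False
        df["chemo"] = True
        df.loc[df.index[:7], "immune_deficient"] = True
        df.loc[df.index[7:18], "chemo"] = False
        assert len(filter_survival_cohort(df)) == 56

    def test_all_pass_is_identity(self, default_cohort):
        df = default_cohort.copy()
        df["immune_deficient"] = False
        df["chemo"] = True
        pd.testing.assert_frame_equal(filter_survival_cohort(df), df)

    def test_missing_flag_excluded_with_warning(self, default_cohort):
        df = default_cohort.copy()
        df["immune_deficient"] = pd.Series(False, index=df.index, dtype="boolean")
        df["chemo"] = True
        df.loc[df.index[0], "immune_deficient"] = pd.NA
        with pytest.warns(UserWarning, match="missing immune/chemo flags"):
            out = filter_survival_cohort(df)
        assert df.index[0] not in out.index

    def test_empty_result_is_error(self, default_cohort):
        df = default_cohort.copy()
        df["chemo"] = False
        with pytest.raises(ValueError, match="empty"):
            filter_survival_cohort(df)


class TestKaplanMeier:
    def test_distinct_events_step_by_one_over_n(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        curve = km_fit(times, np.ones(5, bool))
        steps = curve.survival_probabilities
        np.testing.assert_allclose(steps[1:], 1 - np.arange(1, 6) / 5)
        assert curve.median_os_months == 3.0  # order statistic ceil(n/2)

    def test_exponential_median_matches_closed_form(self):
        lam = 0.1
        rng = np.random.default_rng(42)
        curve = km_fit(rng.exponential(1 / lam, 2000), np.ones(2000, bool))
        assert curve.median_os_months == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_single_censored_observation_flat_curve(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = km_fit([7.0], [False])
        assert (curve.survival_probabilities == 1.0).all()
        assert not curve.median_defined

    def test_survival_non_increasing_from_one(self):
        rng = np.random.default_rng(3)
        curve = km_fit(rng.exponential(5, 100), rng.random(100) < 0.7)
        s = curve.survival_probabilities
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 200)
        curve = km_fit(times, np.ones(200, bool))
        for t, s in zip(curve.event_times[1:], curve.survival_probabilities[1:]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)


def _manual_logrank(times, events, group):
    """Hand tabulation of the two-group log-rank statistic (independent oracle)."""
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)
        chi2, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([True, True, False, True, True, True])
        group = np.array([False, False, False, True, True, True])
        expected = _manual_logrank(times, events, group)
        chi2, _ = logrank_test([(times[~group], events[~group]), (times[group], events[group])])
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert logrank_chi2_two_group(times, events, group) == pytest.approx(expected, abs=1e-10)

    def test_fast_statistic_matches_lifelines(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            t = rng.exponential(10, 60)
            e = rng.random(60) < 0.8
            g = rng.random(60) < 0.5
            if not (e[g].any() or e[~g].any()):
                continue
            chi2, _ = logrank_test([(t[g], e[g]), (t[~g], e[~g])])
            assert logrank_chi2_two_group(t, e, g) == pytest.approx(chi2, rel=1e-9)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 over 1000 replicates within 0.05 +/- 0.02."""
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(1000):
            t = rng.exponential(10, 100)
            chi2 = logrank_chi2_two_group(t, np.ones(100, bool), np.arange(100) < 50)
            rejections += stats.chi2.sf(chi2, 1) < 0.05
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([True])), (np.array([]), np.array([]))])


class TestOptimalCutoff:
    def test_planted_change_point_recovered(self):
        """Hazard doubles above x=10: recovered cutoffs concentrate near 10."""
        rng = np.random.default_rng(21)
        cuts = []
        for _ in range(15):
            x = rng.uniform(0, 20, 200)
            lam = 0.05 * np.exp(np.log(2) * (x > 10))
            t = rng.exponential(1 / lam)
            res = optimal_cutoff(x, t, np.ones(200, bool), min_leaf=7, variable="x")
            cuts.append(res.cutoff_value)
        q1, q3 = np.percentile(cuts, [25, 75])
        assert q1 <= 10 <= q3 or abs(np.median(cuts) - 10) < 2.5

    def test_null_variable_statistic_is_maximally_selected(self):
        """For a no-effect variable, the scan statistic matches a permutation oracle."""
        rng = np.random.default_rng(22)
        t = rng.exponential(10, 60)
        e = np.ones(60, bool)
        x = rng.normal(0, 1, 60)
        observed = optimal_cutoff(x, t, e, min_leaf=7).logrank_statistic
        perm_stats = []
        for _ in range(200):
            perm_stats.append(optimal_cutoff(rng.permutation(x), t, e, min_leaf=7).logrank_statistic)
        # the observed maximally selected statistic is a typical draw from the
        # permutation null (between its 1st and 99th percentile)
        lo, hi = np.percentile(perm_stats, [1, 99])
        assert lo <= observed <= hi
        # and inflated relative to a fixed median split's chi2 ~ chi2(1)
        assert np.mean(perm_stats) > 1.0

    def test_constant_variable_no_admissible_split(self):
        t = np.arange(1.0, 21.0)
        assert optimal_cutoff(np.full(20, 3.0), t, np.ones(20, bool)) is None

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(23)
        x = np.arange(30.0)
        t = rng.exponential(10, 30)
        res = optimal_cutoff(x, t, np.ones(30, bool), min_leaf=10)
        assert res.n_low >= 10 and res.n_high >= 10


class TestUnivariableScreen:
    def test_planted_predictor_selected_in_its_stratum(self):
        rng = np.random.default_rng(31)
        n = 120
        df = pd.DataFrame({
            "sex": np.repeat(["female", "male"], n // 2),
            "biomarker": rng.uniform(0, 10, n),
            "noise": rng.normal(0, 1, n),
        })
        lam = 0.05 * np.exp(1.2 * ((df["biomarker"] > 5) & (df["sex"] == "female")))
        df["os_months"] = rng.exponential(1 / lam)
        df["event"] = True
        out = univariable_screen(df, ["biomarker", "noise"], alpha=0.1)
        assert out[out["variable"] == "biomarker"]["selected"].all()
        female_p = out.query("variable == 'biomarker' and stratum == 'female'")["p"].iloc[0]
        assert female_p < 0.1

    def test_empty_candidate_list(self, default_cohort):
        out = univariable_screen(default_cohort.dropna(), [])
        assert out.empty


class TestCoxBackward:
    def test_single_binary_covariate_recovers_planted_hr(self):
        """Planted HR 4.4 at n=300: estimate lands in [3.3, 5.9] in >=90% of reps."""
        rng = np.random.default_rng(41)
        hits, reps = 0, 40
        for _ in range(reps):
            x = (np.arange(300) < 150).astype(float)
            t = rng.exponential(1 / (0.0673 * np.exp(np.log(4.4) * x)))
            df = pd.DataFrame({"x": x, "os_months": t, "event": True})
            res = cox_backward(df, ["x"], retention_alpha=1.1)  # no elimination
            hits += 3.3 <= res.term("x").hr <= 5.9
        assert hits / reps >= 0.9

    def test_null_covariate_eliminated_among_strong_ones(self):
        rng = np.random.default_rng(42)
        eliminated = 0
        reps = 60
        for _ in range(reps):
            n = 300
            strong = rng.normal(0, 1, n)
            null = rng.normal(0, 1, n)
            t = rng.exponential(1 / (0.07 * np.exp(0.8 * strong)))
            df = pd.DataFrame({"strong": strong, "null": null, "os_months": t, "event": True})
            res = cox_backward(df, ["strong", "null"], retention_alpha=0.1)
            eliminated += "null" in res.eliminated
        assert eliminated / reps >= 0.85

    def test_dichotomized_coding(self):
        rng = np.random.default_rng(43)
        age = rng.uniform(40, 80, 400)
        t = rng.exponential(1 / (0.05 * np.exp(1.2 * (age > 60))))
        df = pd.DataFrame({"age": age, "os_months": t, "event": True})
        res = cox_backward(df, ["age"], coding_map={"age": ("dichotomized_at_cutoff", 60.0)})
        term = res.term("age")
        assert term.coding == "dichotomized_at_cutoff"
        assert term.ci95_low <= term.hr <= term.ci95_high
        assert 2.0 <= term.hr <= 5.5  # planted exp(1.2) ~ 3.32

    def test_all_covariates_dropped_gives_empty_model(self):
        rng = np.random.default_rng(44)
        df = pd.DataFrame({
            "noise": rng.normal(0, 1, 100),
            "os_months": rng.exponential(10, 100),
            "event": True,
        })
        res = cox_backward(df, ["noise"], retention_alpha=0.01)
        assert res.terms == [] and res.eliminated == ["noise"]


def _fisher_enumeration(table):
    """Two-sided Fisher p by full hypergeometric enumeration (oracle)."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    return float(rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum())


class TestCohortCompare:
    def test_fisher_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            tab = rng.integers(0, 26, (2, 2))
            if tab.sum() == 0:
                continue
            p_scipy = stats.fisher_exact(tab)[1]
            assert p_scipy == pytest.approx(_fisher_enumeration(tab), abs=1e-9)

    def test_reported_nominal_comparisons(self, default_cohort):
        """Planted 2x2 treatment counts reproduce their exact Fisher p-values."""
        df = default_cohort.copy()
        females = df[df["sex"] == "female"].index
        males = df[df["sex"] == "male"].index
        df["rituximab"] = False
        df.loc[females[:13], "rituximab"] = True
        df.loc[males[:3], "rituximab"] = True
        out = cohort_compare(df, {"rituximab": "nominal"})
        assert out.loc[0, "p"] == pytest.approx(
            _fisher_enumeration([[13, 28], [3, 30]]), abs=1e-12
        )
        assert round(out.loc[0, "p"], 2) == 0.02

    def test_identical_groups_give_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({
            "sex": ["female"] * 4 + ["male"] * 4,
            "age": np.concatenate([vals, vals]),
            "flag": [True, True, False, False] * 2,
        })
        out = cohort_compare(df, {"age": "numerical", "flag": "nominal"})
        assert out.set_index("variable").loc["age", "p"] == pytest.approx(1.0)
        assert out.set_index("variable").loc["flag", "p"] == pytest.approx(1.0)

    def test_descriptive_formats(self, default_cohort):
        out = cohort_compare(
            default_cohort.dropna(),
            {"age": "numerical", "ecog": "ordinal", "chemo": "nominal"},
        )
        fmts = out.set_index("variable")
        assert "±" in fmts.loc["age", "female"]
        assert "IQR" in fmts.loc["ecog", "female"]
        assert "%" in fmts.loc["chemo", "female"]

    def test_empty_stratum_rejected(self, default_cohort):
        df = default_cohort[default_cohort["sex"] == "female"]
        with pytest.raises(ValueError, match="non-empty"):
            cohort_compare(df, {"age": "numerical"})
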