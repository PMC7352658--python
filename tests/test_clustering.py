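"""Imputation, z-scoring, Ward clustering and cluster characterization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pcnslkit import synthetic
from pcnslkit.clustering import (
    DEFAULT_FEATURES,
    characterize_clusters,
    impute_missing,
    sex_stratified_clustering,
    ward_clusters,
    zscore_features,
)


class TestImputation:
    def test_complete_table_returned_unchanged(self, default_cohort):
        complete = default_cohort.dropna()
        out = impute_missing(complete, seed=0, columns=list(DEFAULT_FEATURES))
        pd.testing.assert_frame_equal(out, complete)

    def test_deterministic_under_seed(self, default_cohort):
        a = impute_missing(default_cohort, seed=3, columns=list(DEFAULT_FEATURES))
        b = impute_missing(default_cohort, seed=3, columns=list(DEFAULT_FEATURES))
        pd.testing.assert_frame_equal(a, b)

    def test_observed_entries_never_altered(self, default_cohort):
        out = impute_missing(default_cohort, seed=0, columns=list(DEFAULT_FEATURES))
        for col in DEFAULT_FEATURES:
            observed = default_cohort[col].notna()
            pd.testing.assert_series_equal(out.loc[observed, col],
                                           default_cohort.loc[observed, col])
        assert not out[list(DEFAULT_FEATURES)].isna().any().any()

    def test_ordinal_columns_snap_to_grid(self, default_cohort):
        out = impute_missing(default_cohort, seed=0, columns=list(DEFAULT_FEATURES))
        assert (out["ecog"] % 1 == 0).all()
        assert out["ecog"].between(0, 4).all()

    def test_mask_and_recover_beats_mean_imputation(self):
        """RF imputation RMSE <= 1.2x column-mean RMSE under 10% MCAR."""
        cfg = synthetic.default_cohort_config(seed=21)
        cfg = synthetic.CohortConfig(
            n_female=cfg.n_female, n_male=cfg.n_male, cluster_spec=cfg.cluster_spec,
            hazard_spec=cfg.hazard_spec, censor_rate=0.0, missing_rate=0.0, seed=21,
        )
        truth = synthetic.generate_cohort(cfg)
        rng = np.random.default_rng(7)
        masked = truth.copy()
        holes = {}
        for col in DEFAULT_FEATURES:
            m = rng.random(len(masked)) < 0.10
            holes[col] = m
            masked.loc[m, col] = np.nan
        imputed = impute_missing(masked, seed=7, columns=list(DEFAULT_FEATURES))
        se_rf, se_mean = [], []
        for col in DEFAULT_FEATURES:
            m = holes[col]
            if not m.any():
                continue
            true_vals = truth.loc[m, col].astype(float)
            se_rf.extend((imputed.loc[m, col].astype(float) - true_vals) ** 2)
            se_mean.extend((masked[col].mean() - true_vals) ** 2)
        assert np.sqrt(np.mean(se_rf)) <= 1.2 * np.sqrt(np.mean(se_mean))

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(df, columns=["a", "b"])


class TestZScore:
    def test_mean_zero_unit_sample_sd(self, default_cohort):
        complete = default_cohort.dropna()
        z = zscore_features(complete)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_translation_invariance(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 7.0], "y": [2.0, 2.5, 4.0]})
        shifted = df + 100.0
        pd.testing.assert_frame_equal(
            zscore_features(df, ["x", "y"]), zscore_features(shifted, ["x", "y"])
        )

    def test_two_point_column_sample_sd_convention(self):
        # {0, 10}: sample SD = 7.0710..., so z = {-0.7071, +0.7071}
        z = zscore_features(pd.DataFrame({"x": [0.0, 10.0]}), ["x"])
        np.testing.assert_allclose(z["x"], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_zero_variance_feature_dropped_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_features(df, ["x", "flat"])
        assert list(z.columns) == ["x"]


def _brute_force_ward_merges(points: np.ndarray) -> list[frozenset]:
    """Greedy Ward by exhaustive search: minimal ESS-increase merge each step."""
    clusters: list[set[int]] = [{i} for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            ma = points[list(ca)].mean(axis=0)
            mb = points[list(cb)].mean(axis=0)
            cost = len(ca) * len(cb) / (len(ca) + len(cb)) * np.sum((ma - mb) ** 2)
            if best is None or cost < best[0]:
                best = (cost, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(frozenset(merged))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


class TestWard:
    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in ((0, 0), (5, 0), (0, 5))])
        truth = np.repeat([0, 1, 2], 20)
        mat = pd.DataFrame(pts, columns=["a", "b"])
        res = ward_clusters(mat, k=3)
        assert adjusted_rand_score(truth, res.assignments) >= 0.95
        # the merge-height gap criterion also lands on k = 3
        assert ward_clusters(mat, k=None).k == 3

    def test_duplicated_rows_co_assigned(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=list("abc"))
        doubled = pd.concat([base, base], ignore_index=True)
        res = ward_clusters(doubled, k=3, min_cluster_size=1)
        first, second = res.assignments[:10].to_numpy(), res.assignments[10:].to_numpy()
        np.testing.assert_array_equal(first, second)

    def test_small_instance_matches_exhaustive_greedy_ward(self):
        """Merge order on n<=6 points equals the brute-force Ward oracle."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            pts = rng.normal(0, 1, (6, 2))
            expected = _brute_force_ward_merges(pts)
            tree = ward_clusters(pd.DataFrame(pts, columns=["a", "b"]), k=2).linkage_tree
            members = [{i} for i in range(6)]
            got = []
            for row in tree:
                merged = members[int(row[0])] | members[int(row[1])]
                members.append(merged)
                got.append(frozenset(merged))
            assert got == expected

    def test_merge_heights_monotone(self, default_cohort):
        complete = impute_missing(default_cohort, seed=0, columns=list(DEFAULT_FEATURES))
        res = ward_clusters(zscore_features(complete), k=3)
        heights = res.linkage_tree[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_n_rejected(self):
        mat = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError):
            ward_clusters(mat, k=5)


class TestCharacterize:
    def test_identical_groups_kruskal_h_zero(self):
        df = pd.DataFrame({"ecog": [1, 2, 3, 1, 2, 3]})
        assignments = pd.Series([1, 1, 1, 2, 2, 2])
        out = characterize_clusters(df, assignments, features=["ecog"])
        assert out.loc[0, "test"] == "kruskal-wallis"
        assert out.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        """With identical cluster distributions, ANOVA p is Uniform(0,1)."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            df = pd.DataFrame({"age": rng.normal(60, 10, 40)})
            assignments = pd.Series(np.repeat([1, 2], 20))
            pvals.append(characterize_clusters(df, assignments, ["age"]).loc[0, "p"])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_three_sd_shift_detected(self):
        """A 3-SD planted mean shift yields p < 0.01 in >95% of replicates at n=40."""
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            x = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
            df = pd.DataFrame({"cd3": x})
            assignments = pd.Series(np.repeat([1, 2], 20))
            hits += characterize_clusters(df, assignments, ["cd3"]).loc[0, "p"] < 0.01
        assert hits / 50 > 0.95

    def test_singleton_cluster_left_out(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0, 99.0]})
        assignments = pd.Series([1, 1, 2, 2, 3])
        with pytest.warns(UserWarning, match="singleton"):
            out = characterize_clusters(df, assignments, ["age"])
        assert len(out) == 1


class TestSexStratified:
    def test_planted_clusters_recovered_with_high_ari(self, default_cohort):
        res = sex_stratified_clustering(default_cohort, seed=11)
        for sex in ("female", "male"):
            sub = default_cohort[default_cohort["sex"] == sex]
            ari = adjusted_rand_score(sub["true_cluster"], res[sex].assignments)
            assert ari >= 0.9, f"{sex} ARI {ari:.3f}"

    def test_three_member_satellite_flagged_excluded(self, default_cohort):
        res = sex_stratified_clustering(default_cohort, seed=11)
        male = res["male"]
        assert len(male.excluded) == 1
        assert int(male.sizes[male.excluded[0]]) == 3
        assert not res["female"].excluded

    def test_row_permutation_invariance(self, default_cohort):
        rng = np.random.default_rng(9)
        shuffled = default_cohort.sample(frac=1.0, random_state=rng.integers(2**31))
        a = sex_stratified_clustering(default_cohort, seed=11)
        b = sex_stratified_clustering(shuffled, seed=11)
        for sex in ("female", "male"):
            left = a[sex].assignments
            right = b[sex].assignments.reindex(left.index)
            assert adjusted_rand_score(left, right) == pytest.approx(1.0)

    def test_stratum_smaller_than_k_rejected(self, default_cohort):
        tiny = pd.concat([
            default_cohort[default_cohort["sex"] == "female"].head(2),
            default_cohort[default_cohort["sex"] == "male"].head(5),
        ])
        with pytest.raises(ValueError, match="smaller than k"):
            sex_stratified_clustering(tiny, k_female=3, k_male=2, seed=0)
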