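from __future__ import annotations

import numpy as np
import pytest

from mirscreen.descreen import (
    DegenerateScaleError,
    DeMethod,
    de_genes,
    de_mirnas,
    knn_impute,
    outlier_statistic,
    select_method_by_overlap,
    two_sided_outlier_statistic,
)

from .conftest import make_study
from .oracles import knn_impute_oracle, lsoss_oracle, most_oracle

OUTLIER_METHODS = [DeMethod.COPA, DeMethod.OS, DeMethod.ORT, DeMethod.MOST,
                   DeMethod.LSOSS]


class TestKnnImpute:
    def test_complete_matrix_returned_unchanged(self, rng):
        study = make_study(rng.normal(size=(6, 5)), 2)
        out = knn_impute(study, k=2)
        assert out.values.equals(study.values)

    def test_single_nearest_neighbour_fills_value(self):
        X = np.array(
            [[np.nan, 1.0, 2.0, 3.0], [5.0, 1.1, 2.1, 3.1], [50.0, 9.0, -3.0, 7.0]]
        )
        out = knn_impute(make_study(X, 2), k=1)
        assert out.values.iloc[0, 0] == 5.0

    def test_matches_exhaustive_search_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        X[0, 1] = np.nan
        X[2, 0] = np.nan
        X[4, 3] = np.nan
        out = knn_impute(make_study(X, 2), k=2)
        np.testing.assert_allclose(out.values.to_numpy(), knn_impute_oracle(X, 2))

    def test_entirely_missing_feature_is_named(self):
        X = np.full((3, 4), 1.0)
        X[1] = np.nan
        with pytest.raises(ValueError, match="f001"):
            knn_impute(make_study(X, 2), k=1)


class TestOutlierStatistics:
    def test_copa_of_centred_zeros_is_zero(self):
        assert outlier_statistic([0, 0, 0, 0], [-1, 1, -2, 2], "COPA") == 0.0

    def test_os_with_no_outliers_is_zero(self):
        # all disease values below the pooled q75 + IQR threshold
        assert outlier_statistic([0.1, 0.2, 0.0, 0.1], [0, 1, -1, 0.5], "OS") == 0.0

    def test_welch_t_hand_value(self):
        stat = outlier_statistic([4, 5, 6], [1, 2, 3], "t")
        assert stat == pytest.approx(3.6742, abs=1e-4)

    @pytest.mark.parametrize("method", [DeMethod.MOST, DeMethod.LSOSS])
    def test_most_lsoss_match_brute_force_on_6v6(self, method, rng):
        oracle = most_oracle if method is DeMethod.MOST else lsoss_oracle
        for _ in range(25):
            disease = rng.normal(0, 1, 6)
            disease[:2] += rng.uniform(0, 4)
            control = rng.normal(0, 1, 6)
            assert outlier_statistic(disease, control, method) == pytest.approx(
                oracle(disease, control), abs=1e-9
            )

    @pytest.mark.parametrize("method", list(DeMethod))
    def test_location_shift_invariance(self, method, rng):
        disease = rng.normal(1, 1, 8)
        control = rng.normal(0, 1, 8)
        base = outlier_statistic(disease, control, method)
        shifted = outlier_statistic(disease + 37.5, control + 37.5, method)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("method", OUTLIER_METHODS)
    def test_monotone_in_single_planted_outlier(self, method, rng):
        control = rng.normal(0, 1, 10)
        disease = rng.normal(0, 1, 10)
        stats = []
        for magnitude in (2.0, 4.0, 8.0, 16.0):
            d = disease.copy()
            d[0] = magnitude
            stats.append(outlier_statistic(d, control, method))
        assert all(b >= a - 1e-12 for a, b in zip(stats, stats[1:]))

    def test_zero_mad_raises_degenerate_scale(self):
        with pytest.raises(DegenerateScaleError):
            outlier_statistic([1, 2, 3, 9], [5, 5, 5, 5], "ORT")

    def test_two_sided_statistic_detects_down_outliers(self):
        control = [0.0, 0.1, -0.1, 0.05, 0.0, -0.05]
        disease = [0.0, 0.1, -8.0, -9.0, 0.0, 0.05]
        assert two_sided_outlier_statistic(disease, control, "OS") < 0


class TestDeGenes:
    def test_list_lengths_follow_top_fraction(self, rng):
        studies = [make_study(rng.normal(size=(10, 8)), 4) for _ in range(2)]
        lists = de_genes(studies, "t", top_fraction=0.4)
        assert all(len(lst) == 4 for lst in lists)

    def test_full_fraction_returns_complete_ranking(self, rng):
        study = make_study(rng.normal(size=(7, 8)), 4)
        (lst,) = de_genes([study], "t", top_fraction=1.0)
        assert sorted(lst) == study.feature_ids

    def test_planted_shift_tops_t_ranking(self, rng):
        X = rng.normal(0, 0.3, size=(30, 12))
        X[:3, :6] += 4.0  # first three features shifted in disease
        (lst,) = de_genes([make_study(X, 6)], "t", top_fraction=0.1)
        assert set(lst) == {"f000", "f001", "f002"}

    def test_disjoint_feature_universes_error(self, rng):
        a = make_study(rng.normal(size=(4, 6)), 3, feature_ids=list("abcd"))
        b = make_study(rng.normal(size=(4, 6)), 3, feature_ids=list("wxyz"))
        with pytest.raises(ValueError, match="share no features"):
            de_genes([a, b], "t")


class TestMethodSelection:
    def test_identical_lists_beat_disjoint_lists(self):
        lists = {
            DeMethod.COPA: [["a", "b"], ["a", "b"]],
            DeMethod.OS: [["a", "b"], ["c", "d"]],
        }
        best, reports = select_method_by_overlap(lists)
        assert best is DeMethod.COPA
        by_method = {r.method: r.mean_overlap for r in reports}
        assert by_method[DeMethod.COPA] == 100.0
        assert by_method[DeMethod.OS] == 0.0

    def test_single_method_returned_as_is(self):
        best, _ = select_method_by_overlap({DeMethod.MOST: [["a"], ["a"]]})
        assert best is DeMethod.MOST

    def test_mean_overlap_matches_exhaustive_pairwise_oracle(self, rng):
        lists = {}
        for method in (DeMethod.T, DeMethod.COPA, DeMethod.ORT):
            lists[method] = [
                list(rng.choice(20, size=8, replace=False).astype(str))
                for _ in range(3)
            ]
        _, reports = select_method_by_overlap(lists)
        for rep in reports:
            pairs = []
            ls = rep.per_study_lists
            for i in range(3):
                for j in range(i + 1, 3):
                    pairs.append(100 * len(set(ls[i]) & set(ls[j])) / 8)
            assert rep.mean_overlap == pytest.approx(np.mean(pairs))

    def test_tie_broken_by_method_order_with_warning(self):
        lists = {
            DeMethod.OS: [["a"], ["a"]],
            DeMethod.T: [["b"], ["b"]],
        }
        with pytest.warns(UserWarning, match="tie"):
            best, _ = select_method_by_overlap(lists)
        assert best is DeMethod.T


class TestDeMirnas:
    def test_large_uniform_shift_detected_up(self, rng):
        X = rng.normal(0, 1, size=(5, 18))
        X[0, :9] += 10.0
        results = de_mirnas(make_study(X, 9), alpha=0.05)
        assert any(r.feature_id == "f000" and r.direction == "up" for r in results)

    def test_alpha_one_returns_all_testable_features(self, rng):
        X = rng.normal(size=(6, 10))
        assert len(de_mirnas(make_study(X, 5), alpha=1.0)) == 6

    def test_no_variance_feature_skipped_with_warning(self):
        X = np.vstack([np.ones(8), np.arange(8.0)])
        with pytest.warns(UserWarning, match="no variance"):
            results = de_mirnas(make_study(X, 4), alpha=1.0)
        assert [r.feature_id for r in results] == ["f001"]

    def test_type_one_error_near_alpha_on_null_data(self, rng):
        X = rng.normal(size=(800, 18))
        rate = len(de_mirnas(make_study(X, 9), alpha=0.05)) / 800
        assert rate == pytest.approx(0.05, abs=0.02)


def test_power_ordering_subgroup_vs_uniform_shift(rng):
    """Outlier statistics beat t under subgroup shifts; t competes under
    uniform shifts."""
    n_feat, n = 150, 10
    planted = 25

    def detection(X, method):
        (lst,) = de_genes([make_study(X, n)], method, top_fraction=0.25)
        hits = len([f for f in lst if int(f[1:]) < planted])
        return hits / planted

    # subgroup regime: shift in 25% of disease samples only
    Xs = rng.normal(0, 0.5, size=(n_feat, 2 * n))
    for i in range(planted):
        cols = rng.choice(n, size=3, replace=False)
        Xs[i, cols] += 2.0
    t_rate = detection(Xs, DeMethod.T)
    for method in OUTLIER_METHODS:
        assert detection(Xs, method) >= t_rate

    # uniform regime: t is competitive (within a tolerance band)
    Xu = rng.normal(0, 0.5, size=(n_feat, 2 * n))
    Xu[:planted, :n] += 1.0
    t_uniform = detection(Xu, DeMethod.T)
    best_outlier = max(detection(Xu, m) for m in OUTLIER_METHODS)
    assert t_uniform >= best_outlier - 0.1
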