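"""Scoring core: trimming, neighbors, inference, distances, threshold, detect."""

import math

import numpy as np
import pandas as pd
import pytest

from oppti import (
    DataError,
    OpptiConfig,
    background_threshold,
    build_neighbor_model,
    detect,
    deviation_scores,
    infer_background,
    mad_normalize,
    pairwise_pearson,
    simulate_cohort,
    trim_high_outliers,
)


class TestTrimHighOutliers:
    def test_single_spike_masked(self, make_matrix):
        # Q3 = 0, IQR = 0 -> 10 masked (10 >= 0 and 10 > Q3)
        m = trim_high_outliers(make_matrix([[0, 0, 0, 0, 10.0]]))
        assert np.isnan(m.values.to_numpy()[0, 4])
        assert np.array_equal(m.values.to_numpy()[0, :4], np.zeros(4))

    def test_constant_row_untouched(self, make_matrix):
        m = trim_high_outliers(make_matrix([[3.0] * 6]))
        assert not m.values.isna().any().any()

    def test_row_below_cutoff_unchanged(self, make_matrix, rng):
        arr = rng.normal(size=(1, 20)) * 0.01  # tight spread, no extreme point
        arr[0, 0] = arr[0].max()  # still within Q3 + 1.5 IQR for normal-ish data
        m = trim_high_outliers(make_matrix(arr))
        # nothing masked unless it genuinely clears the cutoff
        q1, q3 = np.quantile(arr[0], [0.25, 0.75])
        expected = (arr[0] >= q3 + 1.5 * (q3 - q1)) & (arr[0] > q3)
        assert np.array_equal(m.values.isna().to_numpy()[0], expected)

    def test_short_row_passes_with_warning(self, make_matrix):
        arr = np.array([[1.0, 2.0, 100.0, np.nan, np.nan]])
        with pytest.warns(UserWarning, match="fewer than 4"):
            m = trim_high_outliers(make_matrix(arr))
        assert m.values.to_numpy()[0, 2] == 100.0

    def test_original_matrix_untouched(self, make_matrix):
        m = make_matrix([[0, 0, 0, 0, 10.0]])
        before = m.values.copy()
        trim_high_outliers(m)
        pd.testing.assert_frame_equal(m.values, before)


class TestPairwisePearson:
    def test_matches_pandas_pairwise_complete(self, rng):
        X = rng.normal(size=(15, 30))
        X[rng.random(X.shape) < 0.2] = np.nan
        r, n = pairwise_pearson(X, min_overlap=5)
        oracle = pd.DataFrame(X).T.corr(min_periods=5).to_numpy()
        both = np.isfinite(r) & np.isfinite(oracle)
        assert np.allclose(r[both], oracle[both], atol=1e-10)
        # entries below the overlap requirement are masked on our side
        assert not np.isfinite(r[n < 5]).any()

    def test_duplicate_rows_correlate_exactly_one(self, rng):
        x = rng.normal(size=20)
        r, _ = pairwise_pearson(np.vstack([x, x, rng.normal(size=20)]))
        assert r[0, 1] == 1.0


class TestNeighborSelection:
    def _trimmed(self, make_matrix, n_markers=5, n_samples=30, seed=0):
        g = np.random.default_rng(seed)
        return make_matrix(g.normal(size=(n_markers, n_samples)))

    def test_signed_ranking_excludes_anticorrelated(self, make_matrix):
        trimmed = self._trimmed(make_matrix)
        corr = np.full((5, 5), np.nan)
        corr[0, 1:] = [0.9, 0.5, -0.8, 0.1]  # target M1's candidates
        model = build_neighbor_model(
            trimmed, OpptiConfig(k=2, min_pairwise_overlap=2), targets=["M1"], corr=corr
        )
        assert model.neighbor_ids["M1"] == ["M2", "M3"]
        assert np.allclose(model.weights["M1"], [0.81, 0.25])

    def test_exact_duplicate_ranks_first_with_unit_weight(self, make_matrix, rng):
        base = rng.normal(size=(6, 40))
        base[5] = base[0]  # M6 duplicates M1
        model = build_neighbor_model(
            make_matrix(base), OpptiConfig(k=1, min_pairwise_overlap=5)
        )
        assert model.neighbor_ids["M1"] == ["M6"]
        assert model.weights["M1"][0] == pytest.approx(1.0, abs=1e-12)

    def test_ties_broken_by_input_order(self, make_matrix):
        trimmed = self._trimmed(make_matrix)
        corr = np.full((5, 5), np.nan)
        corr[0, 1:] = [0.5, 0.5, 0.5, 0.5]
        model = build_neighbor_model(
            trimmed, OpptiConfig(k=2, min_pairwise_overlap=2), targets=["M1"], corr=corr
        )
        assert model.neighbor_ids["M1"] == ["M2", "M3"]

    def test_insufficient_overlap_flags_unusable(self, make_matrix):
        trimmed = self._trimmed(make_matrix)
        corr = np.full((5, 5), np.nan)
        corr[0, 1] = 0.9  # only one candidate has enough overlap
        model = build_neighbor_model(
            trimmed, OpptiConfig(k=2, min_pairwise_overlap=2), targets=["M1"], corr=corr
        )
        assert "M1" in model.unusable
        assert "M1" not in model.neighbor_ids

    def test_no_positive_candidates_flags_unusable(self, make_matrix):
        trimmed = self._trimmed(make_matrix)
        corr = np.full((5, 5), np.nan)
        corr[0, 1:] = [-0.9, -0.5, -0.8, -0.1]
        model = build_neighbor_model(
            trimmed, OpptiConfig(k=2, min_pairwise_overlap=2), targets=["M1"], corr=corr
        )
        assert model.unusable["M1"] == "no positively co-expressed neighbors"


class TestInferBackground:
    def test_single_duplicate_neighbor_identity(self, make_matrix, rng):
        arr = rng.normal(size=(3, 25))
        arr[1] = arr[0]
        m = make_matrix(arr)
        model = build_neighbor_model(m, OpptiConfig(k=1, min_pairwise_overlap=5), ["M1"])
        inferred = infer_background(m, model)
        assert np.array_equal(inferred.loc["M1"].to_numpy(), arr[1])

    def test_hand_weighted_mean(self, make_matrix):
        from oppti import NeighborModel

        m = make_matrix([[0.0], [2.0], [4.0]])
        model = NeighborModel(
            neighbor_ids={"M1": ["M2", "M3"]},
            weights={"M1": np.array([0.81, 0.09])},
        )
        inferred = infer_background(m, model)
        assert inferred.loc["M1"].to_numpy()[0] == pytest.approx(2.2)

    def test_missing_neighbor_renormalizes(self, make_matrix):
        from oppti import NeighborModel

        m = make_matrix([[0.0, 0.0], [2.0, np.nan], [4.0, 4.0]])
        model = NeighborModel(
            neighbor_ids={"M1": ["M2", "M3"]},
            weights={"M1": np.array([0.81, 0.09])},
        )
        inferred = infer_background(m, model)
        assert inferred.loc["M1"].to_numpy()[1] == 4.0  # only surviving neighbor

    def test_all_neighbors_missing_gives_missing(self, make_matrix):
        from oppti import NeighborModel

        m = make_matrix([[0.0, 1.0], [2.0, np.nan]])
        model = NeighborModel(
            neighbor_ids={"M1": ["M2"]}, weights={"M1": np.array([1.0])}
        )
        inferred = infer_background(m, model)
        assert np.isnan(inferred.loc["M1"].to_numpy()[1])


class TestDeviationScores:
    def test_identity_line_zero_scores(self, rng):
        x = rng.normal(size=10)
        scores, line = deviation_scores(x, x)
        assert np.allclose(scores, 0.0)
        slope, b, intercept = line
        assert (slope, b) == (1.0, -1.0) and intercept == 0.0

    def test_outlier_gets_largest_positive_score(self):
        x = np.array([0, 1, 2, 3, 4.0])
        y = np.array([0.1, 0.9, 2.0, 3.1, 8.0])
        scores, _ = deviation_scores(y, x)
        assert np.argmax(scores) == 4 and scores[4] > 0

    def test_translation_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        s0, _ = deviation_scores(y, x)
        s1, _ = deviation_scores(y + 7.3, x)
        assert np.allclose(s0, s1, atol=1e-10)

    def test_scale_equivariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        s0, _ = deviation_scores(y, x)
        s3, _ = deviation_scores(3.0 * y, 3.0 * x)
        assert np.allclose(s3, 3.0 * s0, atol=1e-10)

    def test_signed_distance_matches_pointwise_oracle(self):
        # naive |a x + b y + c| / sqrt(a^2 + b^2) with sign from the residual
        g = np.random.default_rng(99)
        for _ in range(100):
            n = int(g.integers(5, 30))
            x = g.normal(size=n)
            y = 0.5 * x + g.normal(size=n)
            scores, (a, b, c) = deviation_scores(y, x)
            for i in range(n):
                dist = abs(a * x[i] + b * y[i] + c) / math.hypot(a, b)
                slope, intercept = a, c  # b == -1 representation
                sign = 1.0 if y[i] > slope * x[i] + intercept else -1.0
                if y[i] == slope * x[i] + intercept:
                    sign = 0.0
                assert abs(scores[i] - sign * dist) < 1e-10

    def test_fit_mask_excludes_trimmed_points_from_line(self):
        x = np.array([0, 1, 2, 3, 4.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 50.0])
        y_trim = y.copy()
        y_trim[4] = np.nan
        scores, (slope, _, intercept) = deviation_scores(y, x, fit_observed=y_trim)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)
        assert scores[4] == pytest.approx((50.0 - 4.0) / math.sqrt(2.0))

    def test_too_few_pairs_all_missing(self):
        scores, line = deviation_scores(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert line is None and np.isnan(scores).all()

    def test_zero_variance_falls_back_to_median(self):
        y = np.array([1.0, 2.0, 3.0, 10.0])
        x = np.zeros(4)
        with pytest.warns(UserWarning, match="zero variance"):
            scores, line = deviation_scores(y, x)
        assert np.allclose(scores, y - 2.5)
        assert line == (0.0, -1.0, 2.5)


class TestBackgroundThreshold:
    def test_standard_normal_quantile(self, make_matrix, rng):
        # 100 perfectly inferred markers supply the background; their pooled
        # 10,000 scores are standard normal -> tau ~ 1.645
        obs = rng.normal(size=(100, 100))
        m = make_matrix(obs)
        inferred = m.values.copy()  # observed == inferred -> KS p = 1
        scores = pd.DataFrame(
            rng.normal(size=(100, 100)), index=m.values.index, columns=m.values.columns
        )
        tau, background = background_threshold(m, inferred, scores, OpptiConfig())
        assert len(background) == 100
        assert tau == pytest.approx(1.645, abs=0.08)

    def test_fraction_above_tau_bounded(self, make_matrix, rng):
        obs = rng.normal(size=(50, 40))
        m = make_matrix(obs)
        scores = pd.DataFrame(
            rng.normal(size=(50, 40)), index=m.values.index, columns=m.values.columns
        )
        tau, background = background_threshold(m, m.values.copy(), scores, OpptiConfig())
        pooled = scores.loc[background].to_numpy().ravel()
        assert (pooled > tau).mean() <= 0.05 + 1.0 / len(pooled)

    def test_shifted_marker_excluded_from_background(self, make_matrix, rng):
        obs = rng.normal(size=(30, 50))
        m = make_matrix(obs)
        inferred = m.values.copy()
        inferred.iloc[0] -= 5.0  # observed deviates +5 from inferred
        scores = pd.DataFrame(
            rng.normal(size=(30, 50)), index=m.values.index, columns=m.values.columns
        )
        _, background = background_threshold(m, inferred, scores, OpptiConfig())
        assert "M1" not in background and len(background) == 29

    def test_empty_background_is_error(self, make_matrix, rng):
        obs = rng.normal(size=(5, 40))
        m = make_matrix(obs)
        inferred = m.values + 50.0  # every marker deviates wildly
        scores = pd.DataFrame(
            rng.normal(size=(5, 40)), index=m.values.index, columns=m.values.columns
        )
        with pytest.raises(DataError, match="normalization"):
            background_threshold(m, inferred, scores, OpptiConfig())


class TestDetect:
    def test_duplicate_cohort_all_zero_scores_no_calls(self, make_matrix, rng):
        base = rng.normal(size=(20, 30))
        arr = np.vstack([base, base])  # every marker has an exact copy
        m = make_matrix(arr)
        res = detect(m, OpptiConfig(k=1, min_pairwise_overlap=5))
        vals = res.scores.to_numpy()
        assert np.nanmax(np.abs(vals)) == 0.0
        assert not res.calls.to_numpy().any()

    def test_deterministic(self):
        cohort = simulate_cohort(120, 40, mu_protrude=5, pos_fraction=0.2, seed=9)
        m = mad_normalize(cohort.matrix)
        cfg = OpptiConfig(k=4)
        r1, r2 = detect(m, cfg), detect(m, cfg)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        assert r1.threshold == r2.threshold
        assert r1.background_markers == r2.background_markers

    def test_calls_match_threshold_rule(self):
        cohort = simulate_cohort(150, 40, mu_protrude=5, pos_fraction=0.2, seed=2)
        m = mad_normalize(cohort.matrix)
        res = detect(m, OpptiConfig(k=4))
        s = res.scores.to_numpy()
        expected = np.zeros_like(s, dtype=bool)
        np.greater(s, res.threshold, out=expected, where=np.isfinite(s))
        assert np.array_equal(res.calls.to_numpy(), expected)

    def test_protruded_biomarker_recovered(self):
        cohort = simulate_cohort(300, 60, mu_protrude=5, pos_fraction=0.2, seed=4)
        m = mad_normalize(cohort.matrix)
        res = detect(m, OpptiConfig(k=4))
        calls = res.calls.loc[cohort.biomarker_id]
        labels = cohort.labels
        tp = int((calls & labels).sum())
        assert tp / labels.sum() >= 0.5  # majority of positives recovered
        assert res.scores.loc[cohort.biomarker_id][labels].mean() > res.threshold

    def test_marker_observed_shift_leaves_own_scores_unchanged(self, rng):
        # adding a constant to one marker's observed vector is absorbed by the
        # intercept of its fitted line
        cohort = simulate_cohort(80, 40, mu_protrude=0, pos_fraction=0, seed=12)
        m = cohort.matrix
        res0 = detect(m, OpptiConfig(k=3))
        shifted = m.copy()
        shifted.values.iloc[0] += 4.0
        res1 = detect(shifted, OpptiConfig(k=3))
        tid = m.marker_ids[0]
        assert np.allclose(
            res0.scores.loc[tid].to_numpy(), res1.scores.loc[tid].to_numpy(), atol=1e-8
        )
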