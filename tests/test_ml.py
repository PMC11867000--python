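"""Feature assembly, mRMR selection, LOO kNN grid search, evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier

from neurocrit.criticality import BandRegistry
from neurocrit.ml import (FeatureMatrix, assemble_features, derive_parcel_mask,
                          evaluate, knn_grid_search, loo_scores, mrmr_select,
                          _mutual_information, _discretize, _zscale,
                          permutation_importance, stratified_split)


class TestAssembleFeatures:
    def test_default_feature_count(self, small_cohort):
        fm = assemble_features(small_cohort, ("HC", "MCI"))
        functional = [c for c in fm.X.columns if not c.startswith("vol_")]
        structural = [c for c in fm.X.columns if c.startswith("vol_")]
        assert len(functional) == 42  # 2 metrics x 3 bands x 7 systems
        assert len(structural) == 6
        assert fm.n_features == 48
        assert not fm.X.isna().any().any()

    def test_minimal_configuration(self, small_cohort):
        bands = BandRegistry(bands={"alpha": (7.0, 12.0)})
        fm = assemble_features(small_cohort, ("HC", "MCI"), bands=bands,
                               systems=("DMN",), include_volumes=False)
        assert fm.n_features == 2

    def test_labels_follow_pair_order(self, small_cohort):
        fm = assemble_features(small_cohort, ("HC", "MCI"))
        groups = small_cohort.subjects["group"]
        assert fm.y.sum() == (groups == "MCI").sum()

    def test_empty_mask_falls_back_to_all_parcels(self, small_cohort, caplog):
        mask = np.zeros(len(small_cohort.system_ids), dtype=bool)
        with caplog.at_level("WARNING"):
            fm = assemble_features(small_cohort, ("HC", "MCI"), parcel_mask=mask)
        assert fm.n_features == 48
        assert "falling back" in caplog.text

    def test_train_derived_mask_shape(self, small_cohort):
        pair_rows = np.flatnonzero(small_cohort.subjects["group"].isin(["HC", "MCI"]))
        mask = derive_parcel_mask(small_cohort, ("HC", "MCI"), pair_rows)
        assert mask.shape == (small_cohort.maps[0].n_parcels,)
        assert mask.any()


class TestMRMR:
    def test_label_identical_feature_selected_first(self, rng):
        y = rng.integers(0, 2, 200)
        X = np.column_stack([rng.normal(size=200), y.astype(float),
                             y + rng.normal(0, 2, 200)])
        assert mrmr_select(X, y, 3)[0] == 1

    def test_duplicate_penalized_by_redundancy(self, rng):
        # strong feature + its copy + weaker independent feature: the copy
        # must rank below the weaker feature; verified against exhaustive
        # computation of the greedy criterion
        y = rng.integers(0, 2, 400)
        strong = y + rng.normal(0, 0.5, 400)
        weaker = y + rng.normal(0, 2.0, 400)
        X = np.column_stack([strong, strong.copy(), weaker])
        order = mrmr_select(X, y, 3)
        assert order[0] == 0
        assert order[1] == 2  # redundancy pushes the duplicate last

        # exhaustive oracle for step 2: score_j = rel_j - MI(j, selected_0)
        n_bins = max(2, int(np.sqrt(400)))
        disc = np.column_stack([_discretize(X[:, j], n_bins) for j in range(3)])
        rel = [_mutual_information(disc[:, j], y) for j in range(3)]
        scores = {j: rel[j] - _mutual_information(disc[:, j], disc[:, 0]) for j in (1, 2)}
        assert order[1] == max(scores, key=scores.get)

    def test_full_selection_is_permutation(self, rng):
        X = rng.normal(size=(50, 7))
        y = rng.integers(0, 2, 50)
        assert sorted(mrmr_select(X, y, 7)) == list(range(7))

    def test_constant_feature_never_beats_informative(self, rng):
        y = rng.integers(0, 2, 300)
        X = np.column_stack([np.ones(300), y + rng.normal(0, 1, 300)])
        assert mrmr_select(X, y, 2)[0] == 1

    def test_too_many_requested(self, rng):
        with pytest.raises(ValueError):
            mrmr_select(rng.normal(size=(20, 3)), rng.integers(0, 2, 20), 5)


def _toy_feature_matrix(rng, n=28, n_features=6, separation=2.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, n_features))
    X[:, 0] += separation * y
    X[:, 1] -= separation * y
    return FeatureMatrix(
        X=pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)]),
        y=y, classes=("A", "B"), subject_ids=[f"s{i}" for i in range(n)],
    )


class TestLOOGridSearch:
    def test_separable_data_perfect_loo(self, rng):
        fm = _toy_feature_matrix(rng, n=40, separation=8.0)
        model = knn_grid_search(fm, range(11, 14), range(2, 4))
        assert model.loo_auc == 1.0

    def test_matches_brute_force_refit(self, rng):
        # n <= 30: compare fast incremental LOO against per-row sklearn refits
        fm = _toy_feature_matrix(rng, n=26, separation=1.0)
        X, y = fm.X.to_numpy(), fm.y
        k_range, nf_range = range(11, 14), range(2, 5)
        fast = loo_scores(X, y, k_range, nf_range)
        for k in k_range:
            for nf in nf_range:
                brute = np.empty(len(y))
                for i in range(len(y)):
                    tr = np.delete(np.arange(len(y)), i)
                    mu, sd = _zscale(X[tr])
                    order = mrmr_select(X[tr], y[tr], max(nf_range))
                    cols = order[:nf]
                    knn = KNeighborsClassifier(n_neighbors=k)
                    knn.fit((X[tr][:, cols] - mu[cols]) / sd[cols], y[tr])
                    z = ((X[i] - mu) / sd)[cols][None, :]
                    brute[i] = knn.predict_proba(z)[0, 1]
                np.testing.assert_allclose(fast[(k, nf)], brute, atol=1e-12)

    def test_permuted_labels_auc_near_half(self):
        # mean LOO AUC over grid cells under label permutation, at a training
        # size matching the pipeline's cohorts (LOO-kNN carries a small
        # pessimistic deletion bias of order 1/(n-1) that shrinks with n)
        aucs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            fm = _toy_feature_matrix(rng, n=120, separation=2.0)
            y_perm = rng.permutation(fm.y)
            scores = loo_scores(fm.X.to_numpy(), y_perm, range(11, 14), range(2, 4))
            aucs.extend(roc_auc_score(y_perm, s_) for s_ in scores.values())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_all_k_too_large_raises(self, rng):
        fm = _toy_feature_matrix(rng, n=10)
        with pytest.raises(ValueError, match="empty LOO grid"):
            knn_grid_search(fm, range(11, 14), range(2, 3))

    def test_tie_break_prefers_fewer_features_then_smaller_k(self, rng):
        fm = _toy_feature_matrix(rng, n=40, separation=8.0)
        model = knn_grid_search(fm, range(11, 14), range(2, 4))
        # perfectly separable: every cell has AUC 1, so ties resolve minimal
        assert model.n_features == 2
        assert model.k == 11


class TestEvaluate:
    def test_no_leakage_guard(self, rng):
        fm = _toy_feature_matrix(rng, n=40)
        model = knn_grid_search(fm, range(11, 12), range(2, 3))
        with pytest.raises(ValueError, match="overlap"):
            evaluate(model, fm)

    def test_perfect_and_chance_auc(self, rng):
        assert roc_auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        fm_train = _toy_feature_matrix(rng, n=40, separation=8.0)
        model = knn_grid_search(fm_train, range(11, 12), range(2, 3))
        test = _toy_feature_matrix(rng, n=20, separation=8.0)
        test.subject_ids = [f"t{i}" for i in range(20)]
        report = evaluate(model, test)
        assert report.auc == 1.0
        assert report.accuracy == 1.0

    def test_contingency_arithmetic(self):
        # forced predictions: TP=9 FN=1 TN=8 FP=2
        y = np.array([1] * 10 + [0] * 10)
        yhat = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        tp = int(((yhat == 1) & (y == 1)).sum())
        fp = int(((yhat == 1) & (y == 0)).sum())
        tn = int(((yhat == 0) & (y == 0)).sum())
        fn = int(((yhat == 0) & (y == 1)).sum())
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        balanced = 0.5 * (recall + tn / (tn + fp))
        assert precision == pytest.approx(9 / 11)
        assert recall == pytest.approx(0.9)
        assert balanced == pytest.approx(0.85)

    def test_single_class_test_auc_undefined(self, rng):
        fm = _toy_feature_matrix(rng, n=40, separation=8.0)
        model = knn_grid_search(fm, range(11, 12), range(2, 3))
        test = _toy_feature_matrix(rng, n=12, separation=8.0)
        test.subject_ids = [f"t{i}" for i in range(12)]
        test.y = np.zeros(12, dtype=int)
        report = evaluate(model, test)
        assert np.isnan(report.auc)


class TestPermutationImportance:
    @pytest.fixture()
    def fitted(self, rng):
        fm = _toy_feature_matrix(rng, n=40, separation=3.0)
        model = knn_grid_search(fm, range(11, 12), range(2, 3))
        test = _toy_feature_matrix(rng, n=24, separation=3.0)
        test.subject_ids = [f"t{i}" for i in range(24)]
        return model, test

    def test_unused_feature_zero(self, fitted):
        model, test = fitted
        imp = permutation_importance(model, test, seed=0)
        used = set(model.feature_order[: model.n_features])
        for j, name in enumerate(test.X.columns):
            if j not in used:
                assert imp[name] == 0.0

    def test_informative_feature_dominates(self, fitted):
        model, test = fitted
        imp = permutation_importance(model, test, seed=0)
        assert imp.idxmax() in ("f0", "f1")
        assert imp.max() > 0

    def test_deterministic_under_seed(self, fitted):
        model, test = fitted
        a = permutation_importance(model, test, seed=5)
        b = permutation_importance(model, test, seed=5)
        pd.testing.assert_series_equal(a, b)


class TestSplit:
    def test_stratified_proportions(self, rng):
        y = np.array([0] * 60 + [1] * 20)
        tr, te = stratified_split(y, 0.25, seed=0)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == 80
        assert (y[te] == 1).sum() == 5

    def test_synthetic_cohort_separates_hc_mci(self, small_cohort):
        # end-to-end sanity: volumes + criticality separate HC from MCI
        fm = assemble_features(small_cohort, ("HC", "MCI"))
        tr, te = stratified_split(fm.y, 0.25, seed=2)
        model = knn_grid_search(fm.rows(tr), range(11, 14), range(6, 12))
        report = evaluate(model, fm.rows(te))
        assert report.auc > 0.7
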