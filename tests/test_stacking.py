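"""Two-fold stacking, Pearson pruning and the stacked classifier facade."""

import numpy as np
import pandas as pd
import pytest

from histostack.fusion import FeatureTable
from histostack.stacking import (
    BaseLearnerSpec,
    CorrelationMatrix,
    MetaFeatureTable,
    StackedClassifier,
    StackedModel,
    default_roster,
    fit_meta,
    pearson_matrix,
    predict,
    select_complementary,
    stage1_stack,
    stratified_split,
)

FAST_ROSTER = ("RF", "ET")


def meta_table(columns: dict, labels=None) -> MetaFeatureTable:
    return MetaFeatureTable(pd.DataFrame(columns), labels=labels)


class TestStratifiedSplit:
    def test_proportions_preserved(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        assert np.bincount(train.y).tolist() == [9, 9]
        assert np.bincount(test.y).tolist() == [3, 3]
        assert not set(train.source_ids) & set(test.source_ids)

    def test_deterministic_per_seed(self, small_haralick_table):
        a = stratified_split(small_haralick_table, 0.25, seed=3)
        b = stratified_split(small_haralick_table, 0.25, seed=3)
        assert a[0].source_ids == b[0].source_ids
        assert a[1].source_ids == b[1].source_ids

    def test_zero_fraction_rejected(self, small_haralick_table):
        with pytest.raises(ValueError):
            stratified_split(small_haralick_table, 0.0, seed=0)

    def test_single_class_rejected(self, small_haralick_table):
        df = small_haralick_table.df
        single = FeatureTable(df[df.label == 1].reset_index(drop=True))
        with pytest.raises(ValueError):
            stratified_split(single, 0.25, seed=0)


class TestStage1:
    def test_column_count_matches_roster(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        roster = default_roster(0, FAST_ROSTER)
        meta_train, meta_test = stage1_stack(train, test, roster, seed=0)
        assert meta_train.columns == list(FAST_ROSTER)
        assert meta_test.columns == list(FAST_ROSTER)
        assert len(meta_train.df) == len(train) // 2
        assert len(meta_test.df) == len(test)
        for m in (meta_train, meta_test):
            vals = m.df.to_numpy()
            assert vals.min() >= 0 and vals.max() <= 1

    def test_roster_of_one_degenerates_to_holdout(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        meta_train, _ = stage1_stack(train, test, default_roster(0, ("RF",)), seed=0)
        assert meta_train.columns == ["RF"]

    def test_deterministic_per_seed(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        roster = default_roster(5, FAST_ROSTER)
        a = stage1_stack(train, test, roster, seed=5)
        b = stage1_stack(train, test, roster, seed=5)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        pd.testing.assert_frame_equal(a[1].df, b[1].df)

    def test_empty_roster_rejected(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        with pytest.raises(ValueError):
            stage1_stack(train, test, [], seed=0)

    def test_no_test_label_leakage(self, small_haralick_table):
        """Poisoning the test labels must not change stage-1 scores."""
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        poisoned = FeatureTable(test.df.copy())
        poisoned.df["label"] = 1 - poisoned.df["label"]
        roster = default_roster(0, FAST_ROSTER)
        _, clean = stage1_stack(train, test, roster, seed=0)
        _, dirty = stage1_stack(train, poisoned, roster, seed=0)
        pd.testing.assert_frame_equal(clean.df, dirty.df)


class TestPearson:
    def test_column_with_itself(self):
        R = pearson_matrix(meta_table({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9]}))
        assert R.R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_worked_three_point_example(self):
        """x = [1,2,3], y = [1,2,4]: r = 3 / sqrt(2 * 14/3), evaluated by hand."""
        x = np.array([1, 2, 3]) / 4.0  # scores must lie in [0, 1]; r is scale-invariant
        y = np.array([1, 2, 4]) / 4.0
        R = pearson_matrix(meta_table({"a": x, "b": y}))
        assert R.R[0, 1] == pytest.approx(3.0 / np.sqrt(2.0 * 14.0 / 3.0), abs=1e-9)

    def test_antisymmetric_columns(self):
        x = np.array([0.1, 0.4, 0.8])
        R = pearson_matrix(meta_table({"a": x, "b": 1 - x}))
        assert R.R[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_column_is_zero_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            R = pearson_matrix(meta_table({"a": [0.5, 0.5, 0.5], "b": [0.1, 0.2, 0.9]}))
        assert R.R[0, 1] == 0.0 and R.R[0, 0] == 1.0
        assert any("constant" in r.message for r in caplog.records)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(meta_table({"a": [0.5], "b": [0.1]}))


def corr(R):
    R = np.asarray(R, dtype=float)
    return CorrelationMatrix(R, [f"c{i}" for i in range(len(R))])


class TestSelectComplementary:
    def test_all_below_threshold_keeps_everything(self):
        R = corr([[1, 0.3, 0.2], [0.3, 1, 0.1], [0.2, 0.1, 1]])
        assert select_complementary(R, 0.95, [0.9, 0.8, 0.7]) == [0, 1, 2]

    def test_duplicated_pair_drops_higher_index_on_full_tie(self):
        """Columns 0 and 1 identical, column 2 independent, equal accuracies."""
        R = corr([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        assert select_complementary(R, 0.95, [0.8, 0.8, 0.8]) == [0, 2]

    def test_accuracy_breaks_mean_r_tie(self):
        R = corr([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        assert select_complementary(R, 0.95, [0.6, 0.9, 0.8]) == [1, 2]

    def test_tau_one_with_no_exact_duplicates_keeps_all(self):
        R = corr([[1, 0.999, 0.5], [0.999, 1, 0.5], [0.5, 0.5, 1]])
        assert select_complementary(R, 1.0, [0.5, 0.5, 0.5]) == [0, 1, 2]

    def test_never_empty(self):
        R = corr([[1, 1], [1, 1]])
        assert select_complementary(R, 0.01, [0.5, 0.5]) == [0]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 5))
        X[:, 3] = X[:, 0] * 0.98 + 0.01  # near-duplicate pair
        R = np.corrcoef(X, rowvar=False)
        acc = rng.random(5)
        kept = select_complementary(corr(R), 0.9, acc)
        perm = np.array([4, 2, 0, 1, 3])
        Rp = R[np.ix_(perm, perm)]
        kept_p = select_complementary(corr(Rp), 0.9, acc[perm])
        assert sorted(perm[kept_p]) == sorted(kept)

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            select_complementary(corr([[1]]), 0.0, [0.5])


class TestMetaAndPredict:
    @pytest.fixture()
    def clean_meta(self):
        rng = np.random.default_rng(0)
        labels = np.array([0, 1] * 20)
        noise = rng.uniform(0, 0.3, 40)
        col = np.where(labels == 1, 1 - noise, noise)
        return meta_table({"RF": col, "ET": col * 0.9 + 0.05}, labels=labels)

    def test_meta_width_equals_kept(self, clean_meta):
        model = fit_meta(clean_meta, [0, 1], BaseLearnerSpec("RF", seed=0))
        assert model.kept_names == ["RF", "ET"]
        model1 = fit_meta(clean_meta, [0], BaseLearnerSpec("RF", seed=0))
        assert model1.kept_names == ["RF"]

    def test_extreme_rows_classify_to_their_side(self, clean_meta):
        model = fit_meta(clean_meta, [0, 1], BaseLearnerSpec("RF", seed=0))
        labels, scores = predict(model, meta_table({"RF": [0.0, 1.0], "ET": [0.0, 1.0]}))
        assert labels.tolist() == [0, 1]
        assert np.all((scores >= 0) & (scores <= 1))

    def test_missing_kept_column_rejected(self, clean_meta):
        model = fit_meta(clean_meta, [0, 1], BaseLearnerSpec("RF", seed=0))
        with pytest.raises(ValueError):
            predict(model, meta_table({"RF": [0.5]}))

    def test_invalid_kept_indices(self, clean_meta):
        with pytest.raises(ValueError):
            fit_meta(clean_meta, [], BaseLearnerSpec("RF"))
        with pytest.raises(ValueError):
            fit_meta(clean_meta, [5], BaseLearnerSpec("RF"))

    def test_refit_same_seed_identical(self, clean_meta):
        a = fit_meta(clean_meta, [0, 1], BaseLearnerSpec("RF", seed=4))
        b = fit_meta(clean_meta, [0, 1], BaseLearnerSpec("RF", seed=4))
        probe = meta_table({"RF": np.linspace(0, 1, 9), "ET": np.linspace(1, 0, 9)})
        assert np.array_equal(predict(a, probe)[1], predict(b, probe)[1])


class TestStackedClassifier:
    def test_fit_predict_deterministic(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        preds = []
        for _ in range(2):
            clf = StackedClassifier(roster_names=FAST_ROSTER, meta="RF", seed=9)
            clf.fit(train.X, train.y)
            preds.append(clf.predict(test.X))
        assert np.array_equal(preds[0], preds[1])
        proba = clf.predict_proba(test.X)
        assert proba.shape == (len(test), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_tiny_tau_still_runs_with_one_column(self, small_haralick_table):
        train, test = stratified_split(small_haralick_table, 0.25, seed=0)
        clf = StackedClassifier(roster_names=FAST_ROSTER, meta="RF", tau=0.01, seed=0)
        clf.fit(train.X, train.y)
        assert len(clf.model_.kept_indices) >= 1
        assert clf.predict(test.X).shape == (len(test),)

    def test_unknown_roster_name_rejected(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("SVM")


def test_model_persistence_roundtrip(small_haralick_table, tmp_path):
    train, test = stratified_split(small_haralick_table, 0.25, seed=0)
    clf = StackedClassifier(roster_names=FAST_ROSTER, meta="RF", seed=1)
    clf.fit(train.X, train.y)
    clf.model_.save(tmp_path / "model")
    loaded = StackedModel.load(tmp_path / "model")
    assert loaded.kept_indices == clf.model_.kept_indices
    assert [s.name for s in loaded.roster] == list(FAST_ROSTER)
    from histostack.stacking import MetaFeatureTable as MFT, _stage1_scores

    meta = MFT(_stage1_scores(loaded.learners, FAST_ROSTER, test.X, False))
    labels, _ = predict(loaded, meta)
    assert np.array_equal(labels, clf.predict(test.X))
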