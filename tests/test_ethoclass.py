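import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bovilick.core import BEHAVIOURS
from bovilick.ethoclass import (
    ETHOGRAMS,
    ModelSpec,
    apply_ethogram,
    predict,
    rank_features_gini,
    select_features,
    stratified_split,
    train_model,
)
from bovilick.featex import FEATURE_COLUMNS
from bovilick.pipeline import run_pipeline, study_feature_table
from bovilick.synthio import StudyConfig, default_regimes, scaled_regimes


def toy_table(n_per_class=30, classes=BEHAVIOURS, seed=0):
    """A feature table whose classes differ by a shift on every feature."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, cls in enumerate(classes):
        data = rng.normal(i, 0.3, size=(n_per_class, len(FEATURE_COLUMNS)))
        df = pd.DataFrame(data, columns=FEATURE_COLUMNS)
        df.insert(0, "animal_id", "a00")
        df.insert(1, "deployment", "collar")
        df.insert(2, "epoch_start", pd.Timestamp("2021-03-01 10:00:00"))
        df["label"] = cls
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestApplyEthogram:
    def test_identity_ethogram_unchanged(self):
        table = toy_table()
        out = apply_ethogram(table, 1)
        assert out["label"].equals(table["label"])

    def test_binary_ethogram_counts(self):
        table = toy_table(n_per_class=10)
        out = apply_ethogram(table, 3)
        assert set(out["label"]) == {"licking", "non-licking"}
        assert (out["label"] == "non-licking").sum() == 30  # eating+standing+lying
        assert len(out) == len(table)

    def test_inactive_merges_standing_and_lying(self):
        table = pd.concat(
            [
                toy_table(10, classes=["standing"]),
                toy_table(5, classes=["lying"]),
                toy_table(4, classes=["licking"]),
                toy_table(4, classes=["eating"]),
            ],
            ignore_index=True,
        )
        out = apply_ethogram(table, 2)
        assert (out["label"] == "inactive").sum() == 15

    def test_unknown_label_rejected(self):
        table = toy_table(4)
        table.loc[0, "label"] = "walking"
        with pytest.raises(ValueError, match="walking"):
            apply_ethogram(table, 1)

    def test_class_counts_per_ethogram(self):
        assert len(ETHOGRAMS[1].classes) == 4
        assert len(ETHOGRAMS[2].classes) == 3
        assert len(ETHOGRAMS[3].classes) == 2


class TestStratifiedSplit:
    def test_proportional_rounding_100_per_class(self):
        table = toy_table(n_per_class=100)
        train, test = stratified_split(table, 0.70, seed=1)
        for cls in BEHAVIOURS:
            n_train = (train["label"] == cls).sum()
            assert abs(n_train - 70) <= 1
        assert len(train) + len(test) == len(table)

    def test_same_seed_identical_partition(self):
        table = toy_table(50)
        a_train, a_test = stratified_split(table, seed=5)
        b_train, b_test = stratified_split(table, seed=5)
        assert a_train.equals(b_train) and a_test.equals(b_test)

    def test_partition_disjoint_exhaustive(self):
        table = toy_table(31)
        table["row_id"] = np.arange(len(table))
        train, test = stratified_split(table, seed=2)
        ids = set(train["row_id"]) | set(test["row_id"])
        assert ids == set(table["row_id"])
        assert not set(train["row_id"]) & set(test["row_id"])

    def test_small_class_rejected_by_name(self):
        table = pd.concat(
            [toy_table(20, classes=["licking"]), toy_table(1, classes=["lying"])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="lying"):
            stratified_split(table)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            stratified_split(toy_table(10), train_fraction=1.0)


class TestFeatureRanking:
    def test_ranking_shape_and_nonnegativity(self):
        ranking = rank_features_gini(toy_table(20), ntree=50, seed=0)
        assert len(ranking) == len(FEATURE_COLUMNS)
        assert (ranking["mgv"] >= 0).all()
        assert ranking["mgv"].is_monotonic_decreasing

    def test_same_seed_identical_ranking(self):
        table = toy_table(20)
        a = rank_features_gini(table, ntree=50, seed=3)
        b = rank_features_gini(table, ntree=50, seed=3)
        assert a.equals(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            rank_features_gini(toy_table(20, classes=["licking"]))

    def test_mva_top2_when_classes_differ_only_in_intensity(self):
        """Two behaviours with identical orientation and amplitude but
        different oscillation frequency: movement variation is the
        discriminating feature and must rank in the top two."""
        regimes = default_regimes()
        lick = regimes[("licking", "collar")]
        for dep in ("collar", "ear"):
            for b in BEHAVIOURS:
                freq = 4.0 if b in ("licking", "eating") else 1.0
                regimes[(b, dep)] = dataclasses.replace(
                    lick,
                    behaviour=b,
                    deployment=dep,
                    osc_frequency_hz=freq,
                    orient_jitter_sd=0.0,
                    amp_jitter=0.0,
                )
        cfg = StudyConfig(
            n_animals=1,
            seed=17,
            regimes=regimes,
            observation_window=(dt.time(10, 0), dt.time(10, 30)),
        )
        table = study_feature_table(cfg, "collar")
        ranking = rank_features_gini(table, seed=0)
        assert "MVA" in ranking["feature"].head(2).tolist()


class TestSelectFeatures:
    @pytest.fixture()
    def ranking(self):
        return rank_features_gini(toy_table(20), ntree=50, seed=0)

    def test_dt_and_knn_get_top3(self, ranking):
        top3 = ranking["feature"].head(3).tolist()
        assert select_features(ranking, "DT") == top3
        assert select_features(ranking, "kNN") == top3

    def test_rf_and_svm_get_all(self, ranking):
        assert select_features(ranking, "RF") == FEATURE_COLUMNS
        assert select_features(ranking, "SVM") == FEATURE_COLUMNS

    def test_ties_break_by_canonical_feature_order(self):
        ranking = pd.DataFrame({"feature": FEATURE_COLUMNS, "mgv": [0.05] * 20})
        ranking = ranking.sort_values("mgv", ascending=False, kind="mergesort").reset_index(drop=True)
        assert select_features(ranking, "DT") == FEATURE_COLUMNS[:3]

    def test_unknown_algorithm_rejected(self, ranking):
        with pytest.raises(ValueError, match="algorithm"):
            select_features(ranking, "MLP")


class TestTrainPredict:
    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_model(toy_table(20, classes=["licking"]),
                        ModelSpec("RF", cv_folds=2))

    def test_same_seed_identical_predictions(self):
        table = toy_table(30)
        train, test = stratified_split(table, seed=0)
        preds = []
        for _ in range(2):
            model = train_model(train, ModelSpec("RF", seed=4, cv_folds=5))
            preds.append(predict(model, test))
        assert (preds[0] == preds[1]).all()

    def test_knn_ignores_unselected_features(self):
        table = toy_table(30)
        train, test = stratified_split(table, seed=0)
        ranking = rank_features_gini(train, ntree=50, seed=0)
        top3 = select_features(ranking, "kNN")
        model = train_model(train, ModelSpec("kNN", features=top3, cv_folds=5, seed=0))
        base = predict(model, test)
        perturbed = test.copy()
        rest = [f for f in FEATURE_COLUMNS if f not in top3]
        perturbed[rest] += np.random.default_rng(0).normal(0, 100, size=(len(test), len(rest)))
        assert (predict(model, perturbed) == base).all()

    def test_missing_feature_column_named(self):
        table = toy_table(20)
        model = train_model(table, ModelSpec("RF", cv_folds=2, seed=0))
        with pytest.raises(KeyError, match="MVA"):
            predict(model, table.drop(columns=["MVA"]))

    def test_empty_test_empty_predictions(self):
        table = toy_table(20)
        model = train_model(table, ModelSpec("RF", cv_folds=2, seed=0))
        assert len(predict(model, table.iloc[0:0])) == 0

    def test_predicted_labels_subset_of_training_labels(self):
        table = toy_table(20)
        model = train_model(table, ModelSpec("DT", cv_folds=5, seed=0))
        assert set(predict(model, table)) <= set(BEHAVIOURS)

    def test_rf_resubstitution_near_perfect(self, small_tables):
        table = small_tables["collar"]
        model = train_model(table, ModelSpec("RF", seed=0))
        preds = predict(model, table)
        assert (preds == table["label"].to_numpy()).mean() >= 0.99

    @pytest.mark.parametrize("algorithm", ["DT", "kNN", "SVM"])
    def test_tuned_algorithms_fit_and_report_params(self, algorithm):
        table = toy_table(25)
        model = train_model(table, ModelSpec(algorithm, cv_folds=5, seed=1))
        assert model.tuned_params
        assert model.cv_accuracy is not None and model.cv_accuracy > 0.8


class TestPipelineProperties:
    def test_rf_training_cv_accuracy_high_on_ethogram3(self, small_tables):
        from bovilick.ethoclass import cross_validated_accuracy

        mapped = apply_ethogram(small_tables["collar"], 3)
        train, _ = stratified_split(mapped, seed=0)
        model = train_model(train, ModelSpec("RF", seed=0))
        assert cross_validated_accuracy(model, train) >= 0.9

    def test_rf_at_least_as_accurate_as_dt_and_knn_majority_of_seeds(self, small_tables):
        """The random forest should match or beat the simpler DT/kNN models
        on the four-class problem for most seeds."""
        table = small_tables["collar"]
        wins = 0
        seeds = [0, 1, 2, 3, 4]
        for seed in seeds:
            accs = {
                algo: run_pipeline(table, 1, algo, seed=seed, cv_folds=5).test_accuracy
                for algo in ("RF", "DT", "kNN")
            }
            if accs["RF"] >= accs["DT"] and accs["RF"] >= accs["kNN"]:
                wins += 1
        assert wins > len(seeds) / 2

    def test_accuracy_monotone_in_class_separation(self):
        """RF test accuracy must not decrease as the generator's
        between-class separation grows."""
        accs = []
        for sep in (0.0, 0.3, 1.0):
            cfg = StudyConfig(
                n_animals=2,
                seed=23,
                regimes=scaled_regimes(sep),
                observation_window=(dt.time(10, 0), dt.time(10, 30)),
            )
            table = study_feature_table(cfg, "collar")
            accs.append(run_pipeline(table, 1, "RF", seed=23).test_accuracy)
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[0] < accs[2]  # separation genuinely matters
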