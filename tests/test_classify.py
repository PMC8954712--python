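"""Classifier grid: model construction, pooled CV, held-out evaluation, ranking."""

import numpy as np
import pytest

from fragminer.classify import (
    AlgorithmSpec,
    cross_validate,
    default_specs,
    evaluate_on_split,
    make_model,
    run_grid,
)
from fragminer.dataset_core import DatasetSplit, FingerprintMatrix, label_records, stratified_split
from fragminer.metrics import ConfusionTable, MetricsBundle


def _xy(n_p=40, n_n=20, n_feat=12, seed=0, margin=3.0):
    """Linearly separated two-class data with a controllable margin."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_p + n_n, n_feat))
    x[:n_p, 0] += margin
    y = np.array(["P"] * n_p + ["N"] * n_n)
    return x, y


class TestMakeModel:
    def test_rf_defaults_pinned(self):
        model = make_model(AlgorithmSpec("RF"), seed=0)
        assert model.n_estimators == 20
        assert model.max_depth == 15

    def test_unknown_algorithm_lists_valid_names(self):
        with pytest.raises(ValueError, match="SVM"):
            AlgorithmSpec("XGB")

    @pytest.mark.parametrize("name", ["SVM", "LR", "kNN", "ANN", "NB", "RF", "DT"])
    def test_each_algorithm_trains_and_scores(self, name):
        from fragminer.classify import _scores

        x, y = _xy(n_p=30, n_n=15, margin=8.0)
        if name == "NB":  # Bernoulli NB expects presence/absence features;
            # thresholding at half the margin keeps the separation perfect
            x = (x > 4).astype(float)
        model = make_model(AlgorithmSpec(name), seed=1)
        model.fit(x, y)
        scores = _scores(model, x)
        assert scores.shape == (45,)
        # separable data: scores must rank the potent class on top
        assert scores[:30].min() > scores[30:].max()

    def test_same_seed_same_predictions(self):
        x, y = _xy(seed=3, margin=0.5)
        p1 = make_model(AlgorithmSpec("RF"), seed=5).fit(x, y).predict(x)
        p2 = make_model(AlgorithmSpec("RF"), seed=5).fit(x, y).predict(x)
        assert (p1 == p2).all()


class TestCrossValidate:
    def test_pooled_confusion_sums_to_training_size(self):
        x, y = _xy(n_p=69, n_n=19, margin=1.0)
        cv = cross_validate(AlgorithmSpec("LR"), x, y, folds=5, seed=0)
        ct = ConfusionTable.from_predictions(y, cv.oof_pred)
        assert ct.total == 88

    def test_every_sample_predicted_out_of_fold(self):
        x, y = _xy(n_p=20, n_n=10)
        cv = cross_validate(AlgorithmSpec("DT"), x, y, folds=5, seed=1)
        for f, (_, model) in enumerate(zip(range(5), cv.models)):
            held = np.nonzero(cv.fold_assignment == f)[0]
            assert len(held) > 0

    def test_leave_one_out_degenerate(self):
        x, y = _xy(n_p=8, n_n=4)
        cv = cross_validate(AlgorithmSpec("NB"), x, y, folds=12, seed=0)
        assert len(np.unique(cv.fold_assignment)) == 12

    def test_class_smaller_than_folds_rejected(self):
        x, y = _xy(n_p=10, n_n=3)
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(AlgorithmSpec("LR"), x, y, folds=5, seed=0)

    def test_separable_data_classified_perfectly(self):
        x, y = _xy(n_p=40, n_n=20, margin=8.0)
        cv = cross_validate(AlgorithmSpec("RF"), x, y, folds=5, seed=2)
        assert (cv.oof_pred == y).all()


class TestEvaluateOnSplit:
    def test_confusion_and_metrics_on_untouched_data(self):
        x, y = _xy(n_p=60, n_n=30, margin=4.0)
        train = np.r_[0:40, 60:80]
        test = np.r_[40:60, 80:90]
        model = make_model(AlgorithmSpec("LR"), seed=0).fit(x[train], y[train])
        row = evaluate_on_split(model, x[test], y[test], "FP", "LR")
        assert row.confusion.total == 30
        recomputed = MetricsBundle.from_confusion(row.confusion, auc=row.metrics.auc)
        assert recomputed == row.metrics

    def test_column_mismatch_rejected(self):
        x, y = _xy()
        model = make_model(AlgorithmSpec("LR"), seed=0).fit(x, y)
        with pytest.raises(ValueError, match="feature mismatch"):
            evaluate_on_split(model, x[:, :5], y)

    def test_random_scores_give_chance_auc(self, rng):
        x = rng.random((200, 4))
        y = np.array(["P"] * 120 + ["N"] * 80)
        model = make_model(AlgorithmSpec("NB"), seed=0)
        model.fit(rng.random((50, 4)), np.array(["P", "N"] * 25))
        row = evaluate_on_split(model, x, y)
        assert 0.3 <= row.metrics.auc <= 0.7


@pytest.fixture(scope="module")
def small_grid(train_shaped_dataset):
    fm, records = train_shaped_dataset
    labels = {r.compound_id: r.potency_class for r in records}
    split = stratified_split(label_records(records), ratio="3:1", seed=0)
    fps = {
        "FPa": fm,
        "FPb": FingerprintMatrix(
            fm.compound_ids, fm.bit_names[:100], fm.values[:, :100]
        ),
    }
    specs = [AlgorithmSpec("LR"), AlgorithmSpec("NB"), AlgorithmSpec("DT")]
    return run_grid(fps, labels, split, specs=specs, seed=0)


class TestRunGrid:

    def test_cardinality_one_row_per_pair_and_split(self, small_grid):
        assert len(small_grid) == 2 * 3 * 2
        assert sum(r.split == "cv_train" for r in small_grid) == 6
        assert sum(r.split == "test" for r in small_grid) == 6

    def test_ranked_descending_by_auc_then_ca(self, small_grid):
        keys = [(r.metrics.auc, r.metrics.ca) for r in small_grid]
        assert keys == sorted(keys, reverse=True)

    def test_metrics_self_consistent_with_confusions(self, small_grid):
        for r in small_grid:
            assert MetricsBundle.from_confusion(r.confusion, auc=r.metrics.auc) == r.metrics

    def test_id_mismatch_rejected(self, train_shaped_dataset):
        fm, records = train_shaped_dataset
        labels = {r.compound_id: r.potency_class for r in records}
        bad_split = DatasetSplit(train_ids=["nope"], test_ids=[], stratification_ratio=1.0)
        with pytest.raises(ValueError, match="missing ids"):
            run_grid({"FP": fm}, labels, bad_split, specs=[AlgorithmSpec("NB")])

    def test_balancing_raises_specificity_in_most_seeds(self):
        """Training-set balancing should recover minority-class recall."""
        from fragminer.synthetic_data import (
            EnrichmentSpec,
            GeneratorConfig,
            generate_fingerprint_dataset,
        )

        wins = 0
        for seed in range(10):
            enriched = tuple(
                EnrichmentSpec(f"PubchemFP{i}", p, q)
                for i, (p, q) in enumerate([(0.5, 0.1), (0.45, 0.1), (0.4, 0.12), (0.35, 0.1)])
            )
            cfg = GeneratorConfig(
                n_compounds=88, n_potent=69, n_bits=150, enriched=enriched,
                background_p=0.2, seed=seed,
            )
            fm, records = generate_fingerprint_dataset(cfg)
            y = [r.potency_class for r in records]
            spec = AlgorithmSpec("kNN")
            from fragminer.balancing import smote_tomek
            from fragminer.metrics import specificity

            cv_raw = cross_validate(spec, fm.values, y, folds=5, seed=seed)
            sp_raw = specificity(ConfusionTable.from_predictions(y, cv_raw.oof_pred))
            res = smote_tomek(fm.values, y, seed=seed)
            cv_bal = cross_validate(spec, res.matrix, res.labels, folds=5, seed=seed)
            sp_bal = specificity(
                ConfusionTable.from_predictions(res.labels, cv_bal.oof_pred)
            )
            if sp_bal > sp_raw:
                wins += 1
        assert wins >= 7

    def test_default_specs_cover_all_seven(self):
        assert [s.name for s in default_specs()] == [
            "SVM", "LR", "kNN", "ANN", "NB", "RF", "DT",
        ]
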