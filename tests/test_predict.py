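"""Two-level outcome predictor: delta features, balancing, selection,
metrics, patient-level rule."""

import numpy as np
import pandas as pd
import pytest

from seegtc.predict import (
    DELTA_FEATURES,
    NEGATIVE,
    POSITIVE,
    OutcomeModel,
    SplitPlan,
    build_delta_samples,
    evaluate_sensor_level,
    predict_individuals,
    response_possibility,
    select_model,
    split_train_test,
    subdivide_positives,
)
from seegtc.signal import BAND_ORDER


def _delta_frame(rng, n_pos=60, n_neg=12, sep=3.0, n_patients_pos=8,
                 n_patients_neg=2):
    """Synthetic delta samples: positives shifted +sep/2, negatives -sep/2."""
    rows = []
    for i in range(n_pos):
        pid = f"P{(i % n_patients_pos) + 1:02d}"
        feats = rng.standard_normal(8) + sep / 2
        rows.append({"patient_id": pid, "channel_name": f"c{i}",
                     **dict(zip(DELTA_FEATURES, feats)), "label": POSITIVE})
    for i in range(n_neg):
        pid = f"N{(i % n_patients_neg) + 1:02d}"
        feats = rng.standard_normal(8) - sep / 2
        rows.append({"patient_id": pid, "channel_name": f"d{i}",
                     **dict(zip(DELTA_FEATURES, feats)), "label": NEGATIVE})
    return pd.DataFrame(rows)


class FixedModel:
    """Stub classifier with prescribed labels/scores."""

    def __init__(self, labels, scores=None):
        self.labels = np.asarray(labels)
        self.scores = (np.asarray(scores) if scores is not None
                       else self.labels.astype(float))

    def predict(self, X):
        return self.labels[: len(X)]

    def decision_function(self, X):
        return self.scores[: len(X)]


class TestDeltaSamples:
    def _inputs(self):
        rows = []
        for ch, is_tc in (("A1", False), ("A2", True)):
            for period in ("pre", "post"):
                if is_tc and period == "post":
                    continue
                for band in BAND_ORDER:
                    rows.append(("P01", ch, period, band,
                                 1.0 if period == "pre" else 0.4, 2.0))
        means = pd.DataFrame(rows, columns=[
            "patient_id", "channel_name", "period", "band", "ll", "apen"])
        contacts = pd.DataFrame({
            "patient_id": ["P01", "P01"], "channel_name": ["A1", "A2"],
            "electrode": ["A", "A"], "contact_index": [1, 2],
            "is_tc": [False, True]})
        outcomes = pd.Series({"P01": "responder"}, name="outcome")
        outcomes.index.name = "patient_id"
        return means, contacts, outcomes

    def test_subtraction_and_tc_exclusion(self):
        means, contacts, outcomes = self._inputs()
        samples = build_delta_samples(means, contacts, outcomes)
        assert len(samples) == 1  # the TC contact contributes nothing
        assert samples.iloc[0].ll_filtered == pytest.approx(0.6)
        assert samples.iloc[0].apen_ripple == pytest.approx(0.0)
        assert samples.iloc[0].label == POSITIVE
        assert list(samples.columns[2:10]) == list(DELTA_FEATURES)

    def test_contact_missing_period_excluded(self, caplog):
        means, contacts, outcomes = self._inputs()
        contacts.loc[1, "is_tc"] = False  # A2 now non-TC but lacks post rows
        with caplog.at_level("WARNING"):
            samples = build_delta_samples(means, contacts, outcomes)
        assert len(samples) == 1


class TestSplit:
    def test_study_scale_arithmetic(self):
        labels = [POSITIVE] * 834 + [NEGATIVE] * 163
        df = pd.DataFrame({
            "patient_id": "x", "channel_name": [f"c{i}" for i in
                                                range(len(labels))],
            **{f: 0.0 for f in DELTA_FEATURES}, "label": labels})
        train, test = split_train_test(df, SplitPlan(seed=0))
        assert (test.label == POSITIVE).sum() == 139
        assert (test.label == NEGATIVE).sum() == 27
        assert (train.label == POSITIVE).sum() == 695
        assert (train.label == NEGATIVE).sum() == 136

    def test_half_split(self, rng):
        df = _delta_frame(rng, n_pos=10, n_neg=10)
        train, test = split_train_test(
            df, SplitPlan(test_fraction=0.5, seed=1))
        assert (test.label == POSITIVE).sum() == 5
        assert (test.label == NEGATIVE).sum() == 5

    def test_single_class_errors(self, rng):
        df = _delta_frame(rng, n_pos=10, n_neg=0)
        with pytest.raises(ValueError):
            split_train_test(df, SplitPlan())


class TestSubdivision:
    @pytest.mark.parametrize("n,k,sizes", [
        (695, 5, [139] * 5),
        (7, 5, [2, 2, 1, 1, 1]),
        (9, 1, [9]),
    ])
    def test_partition_sizes(self, n, k, sizes, rng):
        df = _delta_frame(rng, n_pos=n, n_neg=0) if n else None
        subsets = subdivide_positives(df, k=k, seed=3)
        assert sorted((len(s) for s in subsets), reverse=True) == sizes
        combined = pd.concat(subsets)
        assert combined.index.is_unique and len(combined) == n

    def test_too_few_errors(self, rng):
        with pytest.raises(ValueError):
            subdivide_positives(_delta_frame(rng, n_pos=3, n_neg=0), k=5)


class TestSelection:
    def test_separable_classes_tiebreak(self, rng):
        df = _delta_frame(rng, n_pos=30, n_neg=12, sep=12.0)
        subsets = subdivide_positives(df[df.label == POSITIVE], k=3, seed=0)
        sel = select_model(subsets, df[df.label == NEGATIVE],
                           grid=[{"C": 0.1, "gamma": "scale"},
                                 {"C": 1.0, "gamma": "scale"}],
                           folds=4, seed=0)
        assert sel["cv_mean_auc"] == pytest.approx(1.0)
        assert sel["chosen_subset_index"] == 0
        assert sel["chosen_params"]["C"] == 0.1

    def test_shuffled_labels_near_chance(self, rng):
        aucs = []
        for seed in range(6):
            df = _delta_frame(np.random.default_rng(seed), n_pos=40,
                              n_neg=40, sep=0.0)
            subsets = subdivide_positives(df[df.label == POSITIVE], k=2,
                                          seed=seed)
            sel = select_model(subsets, df[df.label == NEGATIVE],
                               grid=[{"C": 1.0, "gamma": "scale"}],
                               folds=4, seed=seed)
            aucs.append(sel["cv_mean_auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_empty_grid_errors(self, rng):
        df = _delta_frame(rng)
        with pytest.raises(ValueError):
            select_model([df[df.label == POSITIVE]],
                         df[df.label == NEGATIVE], grid=[], folds=3)


class TestSensorMetrics:
    def test_hand_computed_confusion(self):
        # TP=3 FP=1 FN=1 TN=5
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, -0.1, 0.6, -0.2, -0.3, -0.4, -0.5, -0.6]
        test = pd.DataFrame({
            "patient_id": "x", "channel_name": [f"c{i}" for i in range(10)],
            **{f: 0.0 for f in DELTA_FEATURES}, "label": y_true})
        m = evaluate_sensor_level(FixedModel(y_pred, scores), test)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.75)

    def test_auc_equals_scaled_mann_whitney_u(self, rng):
        """AUC from scores equals U / (n+ * n-) on the same scores."""
        from scipy.stats import mannwhitneyu

        y = rng.integers(0, 2, 60)
        y[:5], y[-5:] = 1, 0
        scores = rng.standard_normal(60) + y
        test = pd.DataFrame({
            "patient_id": "x", "channel_name": [f"c{i}" for i in range(60)],
            **{f: 0.0 for f in DELTA_FEATURES}, "label": y})
        m = evaluate_sensor_level(FixedModel(y, scores), test)
        u = mannwhitneyu(scores[y == 1], scores[y == 0],
                         alternative="two-sided").statistic
        assert m["auc"] == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_single_class_test_errors(self, rng):
        df = _delta_frame(rng, n_pos=5, n_neg=0)
        with pytest.raises(ValueError, match="AUC"):
            evaluate_sensor_level(FixedModel(np.ones(5)), df)


class TestIndividualLevel:
    def test_possibility_proportion(self, rng):
        df = _delta_frame(rng, n_pos=10, n_neg=0, n_patients_pos=1)
        model = FixedModel([1] * 7 + [0] * 3)
        assert response_possibility(model, df) == pytest.approx(0.7)

    def test_threshold_is_strict(self, rng):
        df = _delta_frame(rng, n_pos=10, n_neg=0, n_patients_pos=1)
        table = predict_individuals(FixedModel([1] * 5 + [0] * 5), df)
        assert table.response_possibility.iloc[0] == pytest.approx(0.5)
        assert table.predicted.iloc[0] == "non_responder"

    def test_all_positive_classifier(self, rng):
        df = _delta_frame(rng, n_pos=12, n_neg=0, n_patients_pos=3)
        table = predict_individuals(FixedModel(np.ones(12, dtype=int)), df)
        assert (table.predicted == "responder").all()
        assert (table.response_possibility == 1.0).all()


class TestOutcomeModel:
    def test_fit_deterministic_and_accurate_on_separable_data(self, rng):
        df = _delta_frame(rng, n_pos=48, n_neg=12, sep=4.0)
        model = OutcomeModel(df, plan=SplitPlan(seed=3), folds=5,
                             grid=[{"C": 1.0, "gamma": "scale"}])
        a = model.fit(seed=3)
        b = model.fit(seed=3)
        assert a.sensor_metrics == b.sensor_metrics
        pd.testing.assert_frame_equal(a.patient_table, b.patient_table)
        assert a.sensor_metrics["auc"] > 0.95
        assert a.individual_accuracy == 1.0
        assert "response possibility" in a.summary()
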