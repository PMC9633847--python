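"""Severity truth rule, baseline sweep, classifiers, and window routing."""

import numpy as np
import pandas as pd
import pytest

from eosmap.severity import (
    EvalProtocol,
    HSS_FEATURES,
    MultiClassifierSpec,
    _summarize,
    baseline_sweep,
    best_baseline_threshold,
    confusion_metrics,
    evaluate,
    hss_total_from_row,
    predict_multi,
    route_window,
    severity_truth,
    sweep_delta,
    train_feature_classifier,
    train_multi_classifier,
)
from eosmap.synthetic import CohortSpec, generate_cohort


def record(pec=0, **scores):
    """A slide record with all 16 EoEHSS fields, zero unless overridden."""
    row = {"pec": pec}
    for f in HSS_FEATURES:
        row[f"{f}_grade"] = scores.get(f"{f}_grade", 0)
        row[f"{f}_stage"] = scores.get(f"{f}_stage", 0)
    return row


class TestSeverityTruth:
    def test_high_pec_alone_is_severe(self):
        assert severity_truth(record(pec=20)) is True

    def test_total_exactly_three_is_not_severe(self):
        r = record(pec=10, ei_grade=1, bzh_grade=1, dis_grade=1)
        assert hss_total_from_row(r) == 3
        assert severity_truth(r) is False

    def test_total_above_three_is_severe(self):
        r = record(pec=10, ei_grade=2, bzh_grade=2, dis_grade=1)
        assert severity_truth(r) is True

    def test_separate_convention_fires_on_stage_sum_alone(self):
        r = record(pec=0, ei_stage=2, bzh_stage=2)
        assert severity_truth(r) is True  # stage sum 4 > 3, grade sum 0

    def test_combined_convention_single_sum(self):
        r = record(pec=0, ei_grade=1, ei_stage=1, bzh_grade=1, bzh_stage=1)
        # separate: max(2, 2) = 2 -> not severe; combined: 4 -> severe
        assert severity_truth(r) is False
        assert severity_truth(r, convention="combined") is True

    def test_missing_hss_fields_error(self):
        with pytest.raises(ValueError, match="EoEHSS"):
            severity_truth({"pec": 10, "ei_grade": 1})

    def test_boundary_pec_cut(self):
        assert severity_truth(record(pec=15)) is True
        assert severity_truth(record(pec=14)) is False


class TestEvaluate:
    def test_hand_built_confusion(self):
        m = confusion_metrics(tp=3, fn=1, tn=4, fp=2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.miss_rate == pytest.approx(0.25)
        assert m.false_alarm_rate == pytest.approx(1 / 3)

    def test_perfect_predictions(self):
        y = [True, False, True, False]
        m = evaluate(y, y)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_all_positive_predictor(self):
        m = evaluate([True, False, True, False], [True] * 4)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


class TestBaselineSweep:
    def test_threshold_matching_truth_is_perfect(self):
        df = pd.DataFrame({"pec": [0, 5, 14, 15, 20, 100]})
        df["severe"] = df["pec"] >= 15
        sweep = baseline_sweep(df, range(0, 30))
        t, acc = best_baseline_threshold(sweep)
        assert t == 15 and acc == 1.0

    def test_bz_driven_severity_pulls_threshold_below_15(self):
        df = generate_cohort(CohortSpec(n_patients=300, seed=5))
        sweep = baseline_sweep(df, range(0, 31))
        t, acc = best_baseline_threshold(sweep)
        assert t < 15
        # brute-force confirmation of the argmax
        accs = [(df["severe"] == (df["pec"] >= th)).mean() for th in range(0, 31)]
        assert acc == pytest.approx(max(accs))

    def test_empty_threshold_range(self):
        df = pd.DataFrame({"pec": [1, 2], "severe": [False, True]})
        assert len(baseline_sweep(df, [])) == 0

    def test_single_class_truth_warns_not_crashes(self):
        df = pd.DataFrame({"pec": [20, 30], "severe": [True, True]})
        with pytest.warns(UserWarning, match="single-class"):
            sweep = baseline_sweep(df, [15])
        assert np.isnan(sweep["specificity"].iloc[0])


@pytest.fixture(scope="module")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(n_patients=150, seed=17))


class TestFeatureClassifier:
    def test_leaked_label_reaches_ceiling(self, small_cohort):
        df = small_cohort.copy()
        df["leak"] = df["severe"].astype(float)
        _, summary = train_feature_classifier(
            df, "lda", protocol=EvalProtocol(n_repeats=5), features=("leak",)
        )
        assert summary.median_accuracy == 1.0

    def test_deterministic_under_fixed_seed(self, small_cohort):
        protocol = EvalProtocol(n_repeats=1, base_seed=7)
        _, s1 = train_feature_classifier(small_cohort, "lda", protocol=protocol)
        _, s2 = train_feature_classifier(small_cohort, "lda", protocol=protocol)
        assert s1.median.as_dict() == s2.median.as_dict()

    @pytest.mark.parametrize("kind", ["svm", "lda", "mlp"])
    def test_all_model_kinds_train_and_beat_chance(self, small_cohort, kind):
        arch = (8,) if kind == "mlp" else (20, 50, 100)
        _, summary = train_feature_classifier(
            small_cohort, kind, arch, EvalProtocol(n_repeats=3)
        )
        prevalence = small_cohort["severe"].mean()
        chance = max(prevalence, 1 - prevalence)
        assert summary.median_accuracy >= chance - 0.05

    def test_unknown_model_kind(self, small_cohort):
        with pytest.raises(ValueError, match="model_kind"):
            train_feature_classifier(small_cohort, "forest")

    def test_median_is_permutation_invariant(self):
        reps = [confusion_metrics(tp, 1, 5, 1) for tp in (2, 7, 4, 9, 5)]
        fwd = _summarize(reps)
        rev = _summarize(list(reversed(reps)))
        assert fwd.median.as_dict() == rev.median.as_dict()

    def test_patient_grouped_split_keeps_patients_whole(self, small_cohort):
        from eosmap.severity import _split_indices

        protocol = EvalProtocol(n_repeats=1, group_by_patient=True)
        tr, te = _split_indices(small_cohort, protocol, seed=0)
        tr_p = set(small_cohort["patient_id"].iloc[tr])
        te_p = set(small_cohort["patient_id"].iloc[te])
        assert not tr_p & te_p


class TestWindowRouting:
    def test_partition_for_every_delta(self, small_cohort):
        pec = small_cohort["pec"].to_numpy()
        for delta in range(1, 13):
            inside = route_window(pec, 15, delta)
            outside = ~inside
            assert (inside ^ outside).all()  # exactly one region per record

    @pytest.mark.parametrize(
        "pec,inside", [(6, True), (5, False), (24, True), (25, False), (15, True)]
    )
    def test_delta_9_window_is_6_to_24(self, pec, inside):
        assert bool(route_window([pec], 15, 9)[0]) is inside

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            MultiClassifierSpec(delta=13)
        with pytest.raises(ValueError, match="delta"):
            MultiClassifierSpec(delta=0)

    def test_identical_models_make_routing_vacuous(self, small_cohort):
        from eosmap.severity import make_classifier

        X = small_cohort[["pec", "sec", "pbz", "sbz"]].to_numpy(float)
        y = small_cohort["severe"].to_numpy(bool)
        model = make_classifier("lda")
        model.fit(X, y)
        routed = predict_multi(small_cohort, model, model, delta=9)
        direct = np.asarray(model.predict(X), dtype=bool)
        assert np.array_equal(routed, direct)

    def test_degenerate_delta_skipped_in_sweep(self, small_cohort):
        # keep only in-window records so every delta leaves C_out empty
        trapped = small_cohort[(small_cohort["pec"] >= 14) & (small_cohort["pec"] <= 16)]
        trapped = pd.concat([trapped] * 10, ignore_index=True)
        with pytest.raises(ValueError, match="no delta"):
            sweep_delta(
                trapped,
                deltas=[1],
                spec=MultiClassifierSpec(model_kind_in="lda", model_kind_out="lda"),
                protocol=EvalProtocol(n_repeats=2),
            )

    def test_multi_classifier_trains_with_lda(self, small_cohort):
        spec = MultiClassifierSpec(delta=9, model_kind_in="lda", model_kind_out="lda")
        (m_in, m_out), summary = train_multi_classifier(
            small_cohort, spec, EvalProtocol(n_repeats=3)
        )
        assert 0.5 <= summary.median_accuracy <= 1.0
        pred = predict_multi(small_cohort, m_in, m_out, spec.delta)
        assert pred.shape == (len(small_cohort),)
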