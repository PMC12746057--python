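"""Discrimination, calibration, decision-curve and feature-level metrics."""

import numpy as np
import pandas as pd
import pytest

from vsgrowth.evaluation import (calibration_metrics, cohens_d,
                                 confusion_metrics, default_feature_grouping,
                                 group_features, net_benefit,
                                 operating_point, paired_bootstrap_auc,
                                 permutation_importance, roc_auc,
                                 stable_feature_set)
from vsgrowth.pipeline import PipelineConfig, train_svm


def auc_pair_counting(probs, labels):
    """Mann-Whitney oracle: concordant pairs + half ties over all
    positive-negative pairs."""
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    total = conc = ties = 0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                ties += 1
    return (conc + 0.5 * ties) / total


class TestConfusion:
    def test_hand_table(self):
        probs = np.array([0.9] * 9 + [0.1] + [0.9] + [0.1] * 9)
        labels = np.array([1] * 10 + [0] * 10)
        m = confusion_metrics(probs, labels, 0.5)
        assert (m["tp"], m["fn"], m["fp"], m["tn"]) == (9, 1, 1, 9)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["dor"] == pytest.approx(81.0)
        assert not m["dor_corrected"]

    def test_all_correct_uses_haldane_correction(self):
        m = confusion_metrics(np.array([0.9, 0.9, 0.1, 0.1]),
                              np.array([1, 1, 0, 0]), 0.5)
        assert m["dor_corrected"]
        assert m["dor"] == pytest.approx((2.5 * 2.5) / (0.5 * 0.5))

    def test_zero_cutoff_gives_full_sensitivity(self):
        m = confusion_metrics(np.array([0.2, 0.8]), np.array([0, 1]), 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_dor_cell_identity_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            probs = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            m = confusion_metrics(probs, labels, 0.5)
            if not m["dor_corrected"]:
                assert m["dor"] * m["fp"] * m["fn"] == pytest.approx(
                    m["tp"] * m["tn"])


class TestAuc:
    def test_perfect_probs(self):
        assert roc_auc([0.0, 1.0, 0.1, 0.9], [0, 1, 0, 1]) == 1.0

    def test_constant_probs_tie_convention(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_hand_example(self):
        probs = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(probs, labels) == pytest.approx(0.75)
        assert auc_pair_counting(probs, labels) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(10, 50)
            probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(probs, labels) == pytest.approx(
                auc_pair_counting(probs, labels), abs=1e-12)


class TestCalibration:
    def test_prevalence_constant_predictor_identity(self):
        for pi, n1, n0 in ((0.5, 5, 5), (0.25, 3, 9), (0.64, 16, 9)):
            labels = np.array([1] * n1 + [0] * n0)
            probs = np.full(labels.size, labels.mean())
            out = calibration_metrics(probs, labels)
            assert out["calibration_in_the_large"] == pytest.approx(0.0,
                                                                    abs=1e-12)
            assert out["brier"] == pytest.approx(
                labels.mean() * (1 - labels.mean()), abs=1e-12)

    def test_perfect_probs_zero_brier(self):
        labels = np.array([0, 1, 1, 0])
        out = calibration_metrics(labels.astype(float), labels)
        assert out["brier"] == 0.0

    def test_curve_bins_cover_all_samples(self):
        rng = np.random.default_rng(2)
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        curve = calibration_metrics(probs, labels)["curve"]
        assert curve["count"].sum() == 50


class TestNetBenefit:
    def test_perfect_classifier_equals_prevalence(self):
        labels = np.array([1] * 4 + [0] * 6)
        probs = labels.astype(float)
        nb = net_benefit(probs, labels, np.arange(0.05, 0.95, 0.1))
        assert np.allclose(nb["net_benefit"], 0.4)

    def test_treat_all_is_zero_at_prevalence_threshold(self):
        labels = np.array([1] * 3 + [0] * 7)
        nb = net_benefit(labels.astype(float), labels, [0.3])
        assert nb["treat_all"].iloc[0] == pytest.approx(0.0)

    def test_ten_patient_hand_example(self):
        # 4 events; at t=0.3 the classifier calls 3 TP and 1 FP
        probs = np.array([0.9, 0.8, 0.7, 0.1, 0.6, 0.2, 0.2, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        nb = net_benefit(probs, labels, [0.3])
        assert nb["net_benefit"].iloc[0] == pytest.approx(
            0.3 - 0.1 * (3.0 / 7.0))

    def test_threshold_of_one_rejected(self):
        with pytest.raises(ValueError):
            net_benefit([0.5], [1], [1.0])


class TestOperatingPoints:
    def test_separated_probs_meet_any_constraint(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        for mode in ("rule_in", "rule_out"):
            op = operating_point(probs, labels, mode, 0.95)
            assert op["feasible"]
            assert op["sensitivity"] == 1.0 and op["specificity"] == 1.0

    def test_full_sensitivity_constraint_drops_cutoff_below_positives(self):
        probs = np.array([0.3, 0.5, 0.4, 0.6])
        labels = np.array([0, 0, 1, 1])
        op = operating_point(probs, labels, "rule_out", 0.999)
        assert op["feasible"] and op["cutoff"] <= 0.4
        assert op["sensitivity"] == 1.0

    def test_infeasible_constraint_reported(self):
        probs = np.array([0.5, 0.5, 0.5, 0.5])
        labels = np.array([0, 0, 1, 1])
        op = operating_point(probs, labels, "rule_in", 0.99)
        assert not op["feasible"]


class TestPairedBootstrap:
    def test_identical_models_give_p_one(self):
        rng = np.random.default_rng(3)
        probs = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        out = paired_bootstrap_auc(probs, probs, labels, n_boot=200, seed=1)
        assert out["mean_diff"] == 0.0 and out["p_value"] == 1.0

    def test_perfect_vs_antiperfect_hits_p_floor(self):
        labels = np.array([0, 1] * 10)
        a = labels.astype(float)
        b = 1.0 - labels
        out = paired_bootstrap_auc(a, b, labels, n_boot=200, seed=1)
        assert out["p_value"] == pytest.approx(1.0 / 200)
        lo, hi = out["ci95"]
        assert lo > 0.0 and out["mean_diff"] == pytest.approx(1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        probs_a = rng.random(25)
        probs_b = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        o1 = paired_bootstrap_auc(probs_a, probs_b, labels, 100, seed=7)
        o2 = paired_bootstrap_auc(probs_a, probs_b, labels, 100, seed=7)
        assert o1 == o2


class TestPermutationImportance:
    def _model_and_data(self):
        rng = np.random.default_rng(5)
        n = 60
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        labels = (signal > 0).astype(int)
        x = np.column_stack([signal, noise])
        cfg = PipelineConfig("linear", 1.0, "scale", 16, 20, 2)
        return train_svm(x, labels, cfg, seed=0), x, labels

    def test_sole_predictive_component_importance_near_auc_excess(self):
        model, x, labels = self._model_and_data()
        imp = permutation_importance(model, x, labels, seed=0)
        base_auc = roc_auc(model.predict_proba(x)[:, 1], labels)
        assert imp[0] == pytest.approx(base_auc - 0.5, abs=0.1)
        assert abs(imp[1]) < 0.05

    def test_seed_determinism(self):
        model, x, labels = self._model_and_data()
        i1 = permutation_importance(model, x, labels, seed=3)
        i2 = permutation_importance(model, x, labels, seed=3)
        assert np.array_equal(i1, i2)

    def test_sign_tracks_association_direction(self):
        model, x, labels = self._model_and_data()
        imp = permutation_importance(model, x, labels, seed=0)
        assert imp[0] > 0  # positively associated with growth probability


class TestFeatureAnalysis:
    def test_stable_set_of_identical_sets(self):
        sets = [["a", "b", "c"]] * 5
        assert stable_feature_set(sets) == ["a", "b", "c"]

    def test_stable_set_of_disjoint_sets_is_empty(self):
        assert stable_feature_set([["a"], ["b"], ["c"], ["d"], ["e"]]) == []

    def test_partial_overlap(self):
        sets = [["a", "b", "c"], ["b", "c", "d"], ["c", "b", "e"],
                ["b", "c", "x"], ["y", "b", "c"]]
        assert set(stable_feature_set(sets)) == {"b", "c"}

    def test_cohens_d_hand_values(self):
        vals = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert cohens_d(vals, labels) == pytest.approx(-2.0)
        assert cohens_d(vals, 1 - labels) == pytest.approx(2.0)

    def test_zero_pooled_sd_flagged_nan(self):
        d = cohens_d(np.array([0.0, 0.0, 1.0, 1.0]),
                     np.array([1, 1, 0, 0]))
        assert np.isnan(d)

    def test_equal_group_means_give_zero(self):
        d = cohens_d(np.array([1.0, 3.0, 1.0, 3.0]),
                     np.array([1, 1, 0, 0]))
        assert d == 0.0

    def test_group_representative_is_argmax_of_abs_d(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([1, 0], 20)
        df = pd.DataFrame({
            "t2_firstorder_Mean": labels + rng.normal(0, 1.0, 40),
            "t2_firstorder_Median": labels * 3 + rng.normal(0, 0.5, 40),
        })
        effects = group_features(list(df.columns), df, labels)
        grp = [e for e in effects if e.group == "t2:value"][0]
        d_by_hand = {c: cohens_d(df[c].values, labels) for c in df.columns}
        best = max(d_by_hand, key=lambda c: abs(d_by_hand[c]))
        assert grp.feature == best

    def test_unmapped_feature_raises_with_names(self):
        df = pd.DataFrame({"mystery": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="mystery"):
            group_features(["mystery"], df, np.array([0, 0, 1, 1]),
                           grouping={})

    def test_default_grouping_covers_every_manifest_feature(self):
        from vsgrowth.radiomics import feature_names

        grouping = default_feature_grouping(feature_names())
        assert set(grouping) == set(feature_names())
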