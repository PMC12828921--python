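"""Metrics: AUC pair-count oracle, regression closed forms, Bland-Altman,
plan agreement, decision curve, subgroups, permutation importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strabplan import (
    bland_altman,
    classification_metrics,
    decision_curve,
    plan_agreement,
    regression_metrics,
    subgroup_report,
    permutation_importance,
)
from strabplan.evaluation import (
    DECISION_COLUMNS,
    PRED_DOSE_COLUMNS,
    PROB_COLUMNS,
    quick_summary,
)
from strabplan.simulate import DOSE_COLUMNS, LABEL_COLUMNS


def tile8(col):
    return np.tile(np.asarray(col, dtype=float)[:, None], (1, 8))


class TestClassificationMetrics:
    def test_perfect_ranking_auc_1(self):
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        p = np.linspace(0.1, 0.9, 10)
        m = classification_metrics(tile8(p), tile8(y).astype(int), tile8(y).astype(int))
        assert m["macro_auc"] == pytest.approx(1.0)

    def test_auc_equals_pair_count_oracle(self):
        """4-point toy: AUC = concordant pairs / total pairs = 0.75."""
        p = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        m = classification_metrics(
            tile8(p), tile8(y).astype(int), tile8(y).astype(int)
        )
        # brute-force pair count
        pairs = [
            (pi, pj) for (pi, yi), (pj, yj) in
            itertools.product(zip(p, y), repeat=2) if yi == 0 and yj == 1
        ]
        conc = np.mean([0.5 if a == b else float(b > a) for a, b in pairs])
        assert conc == pytest.approx(0.75)
        assert m["per_label"][0]["auc"] == pytest.approx(conc)

    def test_identity_decisions_give_perfect_scores(self):
        rng = np.random.default_rng(0)
        y = (rng.random((30, 8)) < 0.4).astype(int)
        y[:, 7] = np.r_[np.ones(15), np.zeros(15)]  # keep both classes
        p = np.where(y == 1, 0.9, 0.1)
        m = classification_metrics(p, y, y)
        assert m["macro_f1"] == 1.0 and m["macro_mcc"] == 1.0
        assert m["exact_match"] == 1.0

    def test_single_class_label_excluded_from_macro(self):
        y = np.zeros((10, 8), dtype=int)
        y[:5, 0] = 1
        p = np.where(y == 1, 0.9, 0.1)
        m = classification_metrics(p, y, y)
        assert len(m["undefined_auc_labels"]) == 7
        assert m["macro_auc"] == pytest.approx(1.0)  # only label 0 defined

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.01, 0.99, 40)
        y = (rng.random(40) < p).astype(int)
        if y.min() == y.max():
            return
        from sklearn.metrics import roc_auc_score

        before = roc_auc_score(y, p)
        after = roc_auc_score(y, np.log(p / (1 - p)) * 3 + 1)
        assert after == pytest.approx(before, abs=1e-12)


class TestRegressionMetrics:
    def test_identity(self):
        d = np.array([1.0, 4.0, 7.0])
        m = regression_metrics(d, d)
        assert m["mae"] == m["rmse"] == 0.0
        assert m["r2"] == 1.0 and m["fraction_within_tolerance"] == 1.0

    def test_constant_shift(self):
        d = np.array([1.0, 4.0, 7.0])
        m = regression_metrics(d + 0.5, d)
        assert m["mae"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(0.5)
        assert m["fraction_within_tolerance"] == 0.0  # default 0.30 mm

    def test_five_point_hand_arithmetic(self):
        pred = np.array([2.0, 3.0, 5.0, 4.0, 6.0])
        true = np.array([2.5, 3.0, 4.0, 5.0, 6.2])
        err = pred - true
        m = regression_metrics(pred, true)
        assert m["mae"] == pytest.approx(np.abs(err).mean())
        assert m["rmse"] == pytest.approx(np.sqrt((err ** 2).mean()))
        sst = ((true - true.mean()) ** 2).sum()
        assert m["r2"] == pytest.approx(1 - (err ** 2).sum() / sst)
        assert m["fraction_within_tolerance"] == pytest.approx(2 / 5)

    def test_zero_variance_truth_flagged(self):
        m = regression_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert np.isnan(m["r2"]) and m["r2_undefined"]


class TestBlandAltman:
    def test_identical_predictions(self):
        d = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(d, d)
        assert ba["bias"] == ba["loa_lower"] == ba["loa_upper"] == 0.0

    def test_constant_offset(self):
        d = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(d + 1, d)
        assert ba["bias"] == pytest.approx(1.0)
        assert ba["loa_lower"] == pytest.approx(1.0)
        assert ba["loa_upper"] == pytest.approx(1.0)

    def test_closed_form_sd(self):
        """Differences {-0.2, 0, 0.2}: bias 0, LoA = +/-1.96 * 0.2."""
        true = np.zeros(3)
        pred = np.array([-0.2, 0.0, 0.2])
        ba = bland_altman(pred, true)
        assert ba["bias"] == pytest.approx(0.0)
        assert ba["loa_upper"] == pytest.approx(1.96 * 0.2)
        assert ba["loa_lower"] == pytest.approx(-1.96 * 0.2)


class TestPlanAgreement:
    def plans(self, n):
        rng = np.random.default_rng(0)
        labels = (rng.random((n, 8)) < 0.4).astype(int)
        doses = np.where(labels == 1, rng.uniform(3, 8, (n, 8)), 0.0)
        return labels, doses

    def test_identical_plans_all_tier1(self):
        labels, doses = self.plans(10)
        pa = plan_agreement(labels, doses, labels, doses)
        assert pa["tier1_exact"] == 1.0 and pa["tier2_within_1mm"] == 0.0

    def test_single_08mm_deviation_is_tier2(self):
        labels = np.ones((1, 8), dtype=int) * np.array([1, 0, 1, 0, 1, 0, 1, 0])
        doses = np.where(labels == 1, 6.0, 0.0).astype(float)
        pred = doses.copy()
        pred[0, 0] += 0.8  # > 0.5 mm quantum but <= 1 mm, one muscle only
        pa = plan_agreement(labels, pred, labels, doses)
        assert pa["tier1_exact"] == 0.0
        assert pa["tier2_within_1mm"] == 1.0
        assert pa["clinically_acceptable"] == 1.0

    def test_tier_counts_match_enumeration_oracle(self):
        """10 constructed plans classified by exhaustive manual rules."""
        base = np.array([1, 0, 1, 0, 0, 0, 1, 0])
        labels = np.tile(base, (10, 1))
        doses = np.where(labels == 1, 6.0, 0.0).astype(float)
        pred_doses = doses.copy()
        pred_labels = labels.copy()
        pred_doses[1, 0] += 0.3                      # tier 1 (within quantum)
        pred_doses[2, 0] += 0.9                      # tier 2
        pred_labels[3] = 1 - pred_labels[3]          # decision mismatch
        pred_doses[4, 0] += 0.9
        pred_doses[4, 2] += 0.7                      # two muscles off: neither
        pred_doses[5, 6] += 2.0                      # > 1 mm: neither
        pa = plan_agreement(pred_labels, pred_doses, labels, doses)
        # manual classification: rows 0,1,6,7,8,9 tier1; row 2 tier2; 3,4,5 fail
        assert pa["tier1_exact"] == pytest.approx(6 / 10)
        assert pa["tier2_within_1mm"] == pytest.approx(1 / 10)
        assert pa["clinically_acceptable"] == pytest.approx(7 / 10)

    def test_majority_baseline(self):
        labels = np.zeros((10, 8), dtype=int)
        labels[:3, 0] = 1  # 7 identical all-zero vectors
        pa = plan_agreement(labels, np.zeros((10, 8)), labels, np.zeros((10, 8)))
        assert pa["majority_baseline"] == pytest.approx(0.7)


class TestDecisionCurve:
    def test_treat_none_is_zero(self):
        rng = np.random.default_rng(0)
        table = decision_curve(rng.uniform(0, 1, 50), (rng.random(50) < 0.4).astype(int))
        assert (table["nb_treat_none"] == 0).all()

    def test_treat_all_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        table = decision_curve(np.full(100, 0.5), y, thresholds=[0.25])
        pi = 0.3
        expected = pi - (1 - pi) * 0.25 / 0.75
        assert table["nb_treat_all"][0] == pytest.approx(expected)

    def test_direct_arithmetic(self):
        """TP=30, FP=10, n=100 at p_t = 0.5 -> NB = 0.30 - 0.10 = 0.20."""
        y = np.r_[np.ones(40), np.zeros(60)].astype(int)
        p = np.r_[np.full(30, 0.9), np.full(10, 0.1),   # 30 TP, 10 FN
                  np.full(10, 0.9), np.full(50, 0.1)]   # 10 FP, 50 TN
        table = decision_curve(p, y, thresholds=[0.5])
        assert table["nb_model"][0] == pytest.approx(0.20)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]), thresholds=[1.0])


def build_oof(n=60, seed=0, flip=0.0):
    """Synthetic out-of-fold table with known structure."""
    rng = np.random.default_rng(seed)
    dev = rng.normal(0, 25, n)
    labels = np.zeros((n, 8), dtype=int)
    labels[dev > 0, 2] = 1
    labels[dev <= 0, 0] = 1
    doses = np.where(labels == 1, np.abs(dev)[:, None] / 4, 0.0)
    probs = np.clip(np.where(labels == 1, 0.9, 0.1)
                    + rng.normal(0, 0.02, (n, 8)), 0.01, 0.99)
    decisions = (probs > 0.5).astype(int)
    data = {"patient_id": np.arange(n), "fold": 0, "deviation_angle": dev}
    for j in range(8):
        data[PROB_COLUMNS[j]] = probs[:, j]
        data[DECISION_COLUMNS[j]] = decisions[:, j]
        data[PRED_DOSE_COLUMNS[j]] = doses[:, j]
        data[LABEL_COLUMNS[j]] = labels[:, j]
        data[DOSE_COLUMNS[j]] = doses[:, j]
    return pd.DataFrame(data)


class TestSubgroups:
    def test_symmetric_generator_gives_small_gaps(self):
        oof = build_oof(n=400, seed=1)
        sg = subgroup_report(oof)
        assert sg["gap"]["mae_operated"] == pytest.approx(0.0, abs=1e-9)
        assert sg["exotropia"]["n"] + sg["esotropia"]["n"] == 400

    def test_gap_equals_hand_arithmetic(self):
        oof = build_oof(n=100, seed=2)
        oof.loc[oof["deviation_angle"] > 0, PRED_DOSE_COLUMNS] += 0.2
        sg = subgroup_report(oof)
        assert sg["gap"]["mae_operated"] == pytest.approx(
            abs(sg["exotropia"]["mae_operated"] - sg["esotropia"]["mae_operated"])
        )
        assert sg["exotropia"]["mae_operated"] == pytest.approx(0.2)


class TestPermutationImportance:
    def test_deviation_angle_dominates(self, fitted_split):
        """The simulator's plans are driven by the deviation angle, so
        permuting it must degrade discrimination most."""
        results, val = fitted_split
        table = permutation_importance(results, val, n_repeats=3, seed=0)
        assert table.iloc[0]["feature"] == "deviation_angle"
        assert table.iloc[0]["importance_mean"] > 0.1

    def test_null_feature_near_zero(self, fitted_split):
        """Age does not enter the plan rule: importance ~0."""
        results, val = fitted_split
        table = permutation_importance(results, val, n_repeats=3, seed=0)
        age = table.set_index("feature").loc["age", "importance_mean"]
        assert abs(age) < 0.02


def test_quick_summary_renders(fitted_split):
    results, val = fitted_split
    plan = results.predict(val)
    oof = plan.to_frame()
    for col in LABEL_COLUMNS + DOSE_COLUMNS:
        oof[col] = val[col].to_numpy()
    oof["deviation_angle"] = val["deviation_angle"].to_numpy()
    text = quick_summary(oof)
    assert "macro-AUC" in text and "MAE" in text
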