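"""Evaluation metrics against independent brute-force oracles, plus the
cross-validation plumbing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from fluidevents import FluidEventsModel
from fluidevents.evaluation import (
    ModelVariant,
    UndefinedMetricError,
    calibration_bins,
    evaluate_cohort,
    fit_logit,
    lopo_cv,
    point_biserial,
    precision_recall,
    predict_logit,
    randomized_baseline,
    roc_auc,
    roc_points,
    switch_rate_correlation,
)


def _pearson_by_hand(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def _auc_pairwise(p, h):
    """O(n^2) oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counted half."""
    p, h = np.asarray(p, float), np.asarray(h, int)
    pos, neg = p[h == 1], p[h == 0]
    wins = sum((x > y) + 0.5 * (x == y) for x in pos for y in neg)
    return wins / (len(pos) * len(neg))


class TestPointBiserial:
    def test_perfect_agreement(self):
        h = np.array([0, 1, 0, 1, 1, 0])
        assert point_biserial(h.astype(float), h) == pytest.approx(1.0)

    def test_matches_hand_pearson_on_six_points(self):
        p = [0.1, 0.4, 0.35, 0.8, 0.6, 0.2]
        h = [0, 1, 0, 1, 0, 0]
        assert point_biserial(p, h) == pytest.approx(_pearson_by_hand(p, h),
                                                     abs=1e-12)

    def test_independent_outcomes_give_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 10_000)
        h = rng.integers(0, 2, 10_000)
        assert abs(point_biserial(p, h)) < 0.05

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            point_biserial([0.2, 0.4, 0.6], [1, 1, 1])

    def test_randomized_baseline_is_seeded_and_near_zero(self):
        rng = np.random.default_rng(0)
        h = rng.integers(0, 2, 10_000)
        p = h + rng.normal(0, 0.4, h.size)  # strongly related
        assert point_biserial(p, h) > 0.5
        r1 = randomized_baseline(p, h, seed=7)
        r2 = randomized_baseline(p, h, seed=7)
        assert r1 == r2
        assert abs(r1) < 0.05


class TestCalibration:
    def test_binning_rule_edges(self):
        # predictions at 0.35 and 0.44999... both land in the 0.4 bin
        p = [0.35, 0.44999, 0.05, 0.349, 1.0, 0.0]
        h = [1, 0, 0, 1, 1, 0]
        table = calibration_bins(p, h).table
        assert table.loc[4, "n"] == 2          # bin centred on 0.4
        assert table.loc[1, "n"] == 1          # 0.05 -> bin 0.1
        assert table.loc[3, "n"] == 1          # 0.349 -> bin 0.3
        assert table.loc[10, "n"] == 1 and table.loc[0, "n"] == 1

    def test_known_rates_give_unit_slope(self):
        rng = np.random.default_rng(3)
        p = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 4000)
        h = rng.random(p.size) < p
        res = calibration_bins(p, h.astype(int))
        assert res.slope == pytest.approx(1.0, abs=0.05)
        assert res.intercept == pytest.approx(0.0, abs=0.03)

    def test_single_bin_fit_flagged_undefined(self):
        res = calibration_bins([0.25] * 8, [0, 1, 0, 0, 1, 0, 0, 1])
        assert res.slope is None and res.note is not None
        assert res.table["n"].sum() == 8


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_predictions_are_chance(self):
        assert roc_auc([0.4] * 10, [0, 1] * 5) == 0.5

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for n in (2, 7, 20, 113, 200):
            p = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n)
            h = rng.integers(0, 2, n)
            if len(np.unique(h)) < 2:
                continue
            assert roc_auc(p, h) == pytest.approx(_auc_pairwise(p, h), abs=1e-12)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        h = (rng.random(200) < p).astype(int)
        pts = roc_points(p, h)
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()


class TestPrecisionRecall:
    def test_all_correct(self):
        cm = precision_recall([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (cm.precision, cm.recall) == (1.0, 1.0)
        assert cm.switch_rate == 0.5

    def test_hand_counted_confusion_table(self):
        p = [0.9, 0.6, 0.4, 0.2, 0.8, 0.3, 0.7, 0.1, 0.55, 0.45]
        h = [1, 0, 1, 0, 1, 1, 0, 0, 1, 0]
        # predicted switches: indices 0,1,4,6,8 -> TP {0,4,8}, FP {1,6}
        # actual switches: {0,2,3?,...}: h==1 at 0,2,4,5,8 -> FN {2,5}
        cm = precision_recall(p, h)
        assert cm.precision == pytest.approx(3 / 5)
        assert cm.recall == pytest.approx(3 / 5)
        assert cm.switch_rate == pytest.approx(0.5)

    def test_threshold_boundary_inclusive(self):
        cm = precision_recall([0.5, 0.49999], [1, 0])
        assert cm.precision == 1.0 and cm.recall == 1.0

    def test_no_predicted_switches_reported(self):
        cm = precision_recall([0.1, 0.2, 0.3], [1, 0, 1])
        assert cm.precision is None
        assert "undefined" in cm.note
        assert cm.recall == 0.0


class TestLogisticFit:
    def test_independent_outcome_recovers_base_rate(self):
        rng = np.random.default_rng(8)
        n = 4000
        records = pd.DataFrame({
            "trial_number": np.arange(1, n + 1),
            "shift": rng.random(n) < 0.3,
        })
        records["shift"] = records["shift"].astype(int)
        params = fit_logit(records, ModelVariant.from_name("null"))
        base = records["shift"].mean()
        assert params["const"] == pytest.approx(math.log(base / (1 - base)),
                                                abs=0.15)
        assert params["trial_number"] == pytest.approx(0.0, abs=1e-3)

    def test_eight_row_fit_matches_brute_force_likelihood(self):
        """Newton MLE agrees with direct numeric maximization of the
        Bernoulli log-likelihood on a tiny hand dataset."""
        records = pd.DataFrame({
            "x": [0.1, 0.3, 0.2, 0.8, 0.7, 0.9, 0.4, 0.6],
            "shift": [0, 0, 1, 1, 0, 1, 0, 1],
        })
        variant = ModelVariant("tiny", ("x",))
        params = fit_logit(records, variant)

        X = np.column_stack([np.ones(8), records["x"]])
        y = records["shift"].to_numpy()

        def nll(beta):
            z = X @ beta
            return np.sum(np.log1p(np.exp(z)) - y * z)

        oracle = minimize(nll, x0=np.zeros(2), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 10_000}).x
        assert params.to_numpy() == pytest.approx(oracle, abs=1e-6)

    def test_sum_variant_gets_positive_weight_on_model_driven_data(self, small_cohort):
        records = FluidEventsModel().run_cohort(small_cohort)
        params = fit_logit(records, ModelVariant.from_name("sum"))
        assert params["p_sum"] > 0

    def test_separable_data_reported_as_fit_error(self):
        from fluidevents.evaluation import FitError
        records = pd.DataFrame({"x": [0.0, 0.1, 0.9, 1.0],
                                "shift": [0, 0, 1, 1]})
        with pytest.raises(FitError):
            fit_logit(records, ModelVariant("sep", ("x",)))


class TestLOPO:
    def _records(self, n_participants=3, bins=40, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(n_participants):
            p = rng.uniform(0, 1, bins)
            frames.append(pd.DataFrame({
                "participant": f"p{i}",
                "bin": np.arange(1, bins + 1),
                "trial_number": np.arange(1, bins + 1),
                "p_sum": p,
                "shift": (rng.random(bins) < p).astype(int),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_every_bin_predicted_exactly_once(self):
        records = self._records()
        pooled, warnings = lopo_cv(records, ModelVariant.from_name("sum"))
        assert warnings == []
        assert len(pooled) == len(records)
        counts = pooled.groupby(["participant", "bin"]).size()
        assert (counts == 1).all()

    def test_held_out_participant_never_in_training(self):
        """Fold predictions must be blind to the held-out participant:
        making one participant's data wildly unrepresentative should not
        change the *other* participants' pooled predictions."""
        records = self._records()
        variant = ModelVariant.from_name("sum")
        pooled_a, _ = lopo_cv(records, variant)
        tweaked = records.copy()
        mask = tweaked["participant"] == "p0"
        tweaked.loc[mask, "shift"] = 1 - tweaked.loc[mask, "shift"]
        pooled_b, _ = lopo_cv(tweaked, variant)
        a0 = pooled_a[pooled_a["participant"] == "p0"]["p_model"].to_numpy()
        b0 = pooled_b[pooled_b["participant"] == "p0"]["p_model"].to_numpy()
        np.testing.assert_allclose(a0, b0)  # p0's fold trained without p0
        a1 = pooled_a[pooled_a["participant"] == "p1"]["p_model"].to_numpy()
        b1 = pooled_b[pooled_b["participant"] == "p1"]["p_model"].to_numpy()
        assert not np.allclose(a1, b1)

    def test_fewer_than_two_participants_rejected(self):
        records = self._records(n_participants=1)
        with pytest.raises(ValueError):
            lopo_cv(records, ModelVariant.from_name("sum"))


class TestSwitchRateCorrelation:
    def _pooled(self, rates_pred, rates_obs, bins=100):
        rng = np.random.default_rng(1)
        frames = []
        for i, (rp, ro) in enumerate(zip(rates_pred, rates_obs)):
            frames.append(pd.DataFrame({
                "participant": f"p{i}",
                "p_model": np.where(rng.random(bins) < rp, 0.9, 0.1),
                "shift": (rng.random(bins) < ro).astype(int),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_identity_case(self):
        pooled = self._pooled([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert switch_rate_correlation(pooled) > 0.95

    def test_matches_direct_formula_on_four_participants(self):
        pooled = self._pooled([0.2, 0.4, 0.6, 0.8], [0.25, 0.35, 0.7, 0.75])
        grouped = pooled.groupby("participant")
        x = grouped["p_model"].apply(lambda p: np.mean(p >= 0.5))
        y = grouped["shift"].mean()
        assert switch_rate_correlation(pooled) == pytest.approx(
            _pearson_by_hand(x, y), abs=1e-12)

    def test_shuffled_pairing_near_zero(self):
        rng = np.random.default_rng(12)
        rates = rng.uniform(0.1, 0.9, 40)
        pooled = self._pooled(rates, rng.permutation(rates), bins=50)
        assert abs(switch_rate_correlation(pooled)) < 0.35

    def test_zero_variance_undefined(self):
        pooled = self._pooled([0.5, 0.5, 0.5], [0.2, 0.5, 0.8])
        pooled["p_model"] = 0.9
        with pytest.raises(UndefinedMetricError):
            switch_rate_correlation(pooled)


class TestEvaluateCohort:
    def test_full_report_on_synthetic_cohort(self, small_cohort):
        report = evaluate_cohort(small_cohort, seed=3)
        assert set(report.variants) == {"null", "sum", "individual",
                                        "event_structure", "experience"}
        aucs = {k: v.auc for k, v in report.variants.items()}
        assert aucs["sum"] > aucs["null"]
        assert aucs["individual"] >= aucs["sum"] - 0.02
        assert report.point_biserial > 0.3
        assert abs(report.randomized_r) < 0.05
        assert report.calibration.slope == pytest.approx(1.0, abs=0.1)

    def test_report_serializes_to_json(self, small_cohort, tmp_path):
        import json

        report = evaluate_cohort(small_cohort, variants=("sum",), seed=0)
        out = tmp_path / "report.json"
        report.to_json(out)
        data = json.loads(out.read_text())
        assert data["variants"]["sum"]["auc"] == pytest.approx(
            report.variants["sum"].auc)
        assert len(data["calibration"]["table"]) == 11

    def test_single_participant_in_sample(self, small_cohort):
        report = evaluate_cohort(small_cohort[:1], variants=("sum",),
                                 cv=False, seed=0)
        assert report.n_participants == 1
        assert report.variants["sum"].auc is not None

    def test_folded_bad_shift_variant(self, small_cohort):
        report = evaluate_cohort(small_cohort, variants=("individual",),
                                 separate_bad_shift=False, seed=0)
        assert report.variants["individual"].auc > 0.5
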