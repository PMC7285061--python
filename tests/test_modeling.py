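import numpy as np
import pandas as pd
import pytest
from scipy import stats

from solestress import (
    GroundTruthRule,
    SessionMeta,
    StressProfile,
    build_lab_dataset,
    fit_lda,
    label_windows,
    leave_one_user_out,
    model_grid,
    predict,
    separation_test,
)
from solestress.io import FEATURE_COLUMNS, Segment
from solestress.modeling import LeakageError, assert_no_leakage


def _table(X, y, pid="P01", features=("A1",)):
    n = len(y)
    df = pd.DataFrame(0.0, index=range(n), columns=FEATURE_COLUMNS)
    df["participant_id"] = pid if isinstance(pid, str) else pid
    df["task_id"] = "T01"
    df["window_start_s"] = np.arange(n) * 10.0
    df["label"] = y
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != n:
        X = X.T
    for j, f in enumerate(features):
        df[f] = X[:, j]
    return df


class TestLabelWindows:
    def _meta(self, rating_stress, rating_relax):
        return SessionMeta(
            "P01",
            [Segment("T01", 0, 300, "stress"), Segment("T02", 300, 600, "relax")],
            {"T01": {"stress": rating_stress}, "T02": {"stress": rating_relax}},
        )

    def _two_task_table(self):
        a = _table(np.zeros(4), ["stress"] * 4)
        b = _table(np.zeros(4), ["relax"] * 4)
        b["task_id"] = "T02"
        return pd.concat([a, b], ignore_index=True)

    def test_stress_task_rated_5_kept(self):
        out = label_windows(self._two_task_table(), self._meta(5, 2))
        assert (out["label"] == "stress").sum() == 4
        assert (out["label"] == "relax").sum() == 4

    def test_relax_task_rated_5_dropped(self):
        out = label_windows(self._two_task_table(), self._meta(6, 5))
        assert set(out["task_id"]) == {"T01"}

    @pytest.mark.parametrize("cond_ratings", [(4, 2), (6, 4)])
    def test_rating_exactly_4_always_excluded(self, cond_ratings):
        out = label_windows(self._two_task_table(), self._meta(*cond_ratings))
        assert len(set(out["task_id"])) == 1

    def test_missing_rating_excludes_task(self):
        meta = self._meta(6, 2)
        del meta.ratings["T02"]
        out = label_windows(self._two_task_table(), meta)
        assert set(out["task_id"]) == {"T01"}


class TestFitPredict:
    def test_separated_gaussians_boundary_at_midpoint(self, rng):
        """1-D two-class LDA with equal priors puts the decision boundary at
        the midpoint of the class means (closed form (mu1+mu2)/2)."""
        mu1, mu2, sigma = 0.0, 4.0, 1.0
        x = np.r_[rng.normal(mu1, sigma, 500), rng.normal(mu2, sigma, 500)]
        y = ["relax"] * 500 + ["stress"] * 500
        model = fit_lda(_table(x, y), ["A1"])
        grid = np.linspace(0, 4, 4001)
        _, scores = predict(model, _table(grid, ["relax"] * len(grid)))
        boundary = grid[np.argmin(np.abs(scores))]
        midpoint = (x[:500].mean() + x[500:].mean()) / 2
        assert boundary == pytest.approx(midpoint, abs=0.1 * sigma)

    def test_identical_classes_near_chance(self, rng):
        x = rng.normal(size=400)
        y = ["stress"] * 200 + ["relax"] * 200
        t = _table(x, y)
        model = fit_lda(t, ["A1"])
        labels, _ = predict(model, t)
        acc = (labels == np.array(y)).mean()
        assert 0.35 <= acc <= 0.65

    def test_row_at_class_mean_classified_to_it(self, rng):
        x = np.r_[rng.normal(0, 1, 100), rng.normal(5, 1, 100)]
        y = ["relax"] * 100 + ["stress"] * 100
        model = fit_lda(_table(x, y), ["A1"])
        raw_means = {c: model.class_means[i] * model.scaler_scale + model.scaler_mean
                     for i, c in enumerate(model.classes)}
        for cls, m in raw_means.items():
            labels, _ = predict(model, _table(m, ["relax"]))
            assert labels[0] == cls

    def test_exact_tie_predicts_relax(self):
        x = np.array([-1.0, -2.0, 1.0, 2.0])
        y = ["relax", "relax", "stress", "stress"]
        model = fit_lda(_table(x, y), ["A1"], standardize=False)
        labels, scores = predict(model, _table([0.0], ["relax"]))
        assert scores[0] == pytest.approx(0.0, abs=1e-12)
        assert labels[0] == "relax"

    def test_agrees_with_gaussian_bayes_oracle(self, rng):
        """Predictions must equal the Bayes rule under the fitted Gaussians,
        computed by an independent density-ratio evaluation."""
        X = np.c_[rng.normal(0, 1, 300), rng.normal(0, 2, 300)]
        X[:150] += [2.5, 1.0]
        y = ["stress"] * 150 + ["relax"] * 150
        feats = ["A1", "C3"]
        t = _table(X, y, features=feats)
        model = fit_lda(t, feats)
        rows = _table(rng.normal(1.0, 2.0, (100, 2)), ["relax"] * 100, features=feats)
        labels, _ = predict(model, rows)
        Z = (rows[feats].to_numpy() - model.scaler_mean) / model.scaler_scale
        oracle = []
        for z in Z:
            dens = [
                stats.multivariate_normal.logpdf(z, model.class_means[i], model.covariance)
                + np.log(model.priors[i])
                for i in range(2)
            ]
            oracle.append(model.classes[0] if dens[0] > dens[1] else model.classes[1])
        assert list(labels) == oracle

    def test_agrees_with_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(400, 3))
        X[:200] += [1.0, -0.5, 0.3]
        y = ["stress"] * 200 + ["relax"] * 200
        feats = ["A1", "B2", "C3"]
        t = _table(X, y, features=feats)
        model = fit_lda(t, feats, standardize=False)
        labels, _ = predict(model, t)
        sk = LinearDiscriminantAnalysis().fit(X, y)
        assert (labels == sk.predict(X)).mean() > 0.99

    def test_singular_covariance_regularised(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = _table(np.c_[x, x], ["relax", "relax", "stress", "stress"],
                   features=("A1", "A2"))
        model = fit_lda(t, ["A1", "A2"])  # duplicated feature: singular
        assert model.ridge_applied
        labels, _ = predict(model, t)
        assert len(labels) == 4

    def test_duplicate_subset_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_lda(_table(np.zeros(4), ["relax"] * 2 + ["stress"] * 2), ["A1", "A1"])

    def test_missing_feature_named_in_error(self, rng):
        t = _table(rng.normal(size=(10, 2)), ["relax"] * 5 + ["stress"] * 5,
                   features=("A1", "B2"))
        model = fit_lda(t, ["A1", "B2"])
        with pytest.raises(ValueError, match="B2"):
            predict(model, t.drop(columns=["B2"]))

    def test_round_trip_json(self, rng, tmp_path):
        t = _table(rng.normal(size=20), ["relax"] * 10 + ["stress"] * 10)
        model = fit_lda(t, ["A1"])
        p = tmp_path / "model.json"
        model.to_json(p)
        from solestress import TrainedModel

        back = TrainedModel.from_json(p)
        l1, s1 = predict(model, t)
        l2, s2 = predict(back, t)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)


class TestLeaveOneUserOut:
    def test_folds_are_user_disjoint_and_accurate(self):
        table = build_lab_dataset(n_users=4, seed=21,
                                  task_plan=[(180.0, "stress"), (180.0, "relax")] * 2)
        report = leave_one_user_out(table, ["A1", "B2", "C3", "D1"])
        assert set(report.per_user_accuracy) == set(table["participant_id"].unique())
        assert report.mean_accuracy >= 90.0
        assert all(0 <= a <= 100 for a in report.per_user_accuracy.values())
        assert report.sd_accuracy >= 0

    def test_leakage_fixture_is_caught(self):
        train = _table(np.zeros(4), ["relax"] * 4, pid="P01")
        test = _table(np.zeros(4), ["stress"] * 4, pid="P02")
        assert_no_leakage(train, test)  # disjoint: passes
        corrupted = pd.concat([train, test.iloc[:1]], ignore_index=True)
        with pytest.raises(LeakageError, match="P02"):
            assert_no_leakage(corrupted, test)

    def test_single_class_user_still_evaluated(self):
        table = build_lab_dataset(n_users=3, seed=33,
                                  task_plan=[(180.0, "stress"), (180.0, "relax")] * 2)
        solo = table["participant_id"] == "P01"
        table = table[~(solo & (table["label"] == "relax"))].reset_index(drop=True)
        report = leave_one_user_out(table, ["A1", "C3"])
        assert "P01" in report.per_user_accuracy

    def test_fewer_than_three_users_rejected(self):
        t = pd.concat(
            [_table(np.zeros(4), ["relax"] * 2 + ["stress"] * 2, pid=p) for p in ("P01", "P02")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="3 users"):
            leave_one_user_out(t, ["A1"])

    def test_accuracy_curve_indexed_by_window_position(self):
        table = build_lab_dataset(n_users=3, seed=12,
                                  task_plan=[(180.0, "stress"), (180.0, "relax")] * 2)
        report = leave_one_user_out(table, ["A1", "C3"])
        n_windows_per_task = 6  # (180 - 120) / 10
        assert len(report.accuracy_curve) == n_windows_per_task
        assert all(0 <= v <= 100 for v in report.accuracy_curve)


class TestSeparationTest:
    def _preds(self, stress_fracs, relax_fracs):
        rows = []
        for i, (fs, fr) in enumerate(zip(stress_fracs, relax_fracs)):
            pid = f"P{i:02d}"
            for cond, frac in (("stress", fs), ("relax", fr)):
                n = 100
                k = round(frac * n)
                rows += [
                    {"participant_id": pid, "label": cond,
                     "predicted": "stress" if j < k else "relax"}
                    for j in range(n)
                ]
        return pd.DataFrame(rows)

    def test_identical_pairs_give_p_one(self):
        res = separation_test(self._preds([0.5] * 5, [0.5] * 5))
        assert res.p == pytest.approx(1.0)

    def test_constant_difference_with_jitter_is_significant(self, rng):
        fs = 0.8 + rng.uniform(-0.01, 0.01, 8)
        fr = 0.2 + rng.uniform(-0.01, 0.01, 8)
        res = separation_test(self._preds(fs, fr))
        assert res.p < 0.001

    def test_fewer_than_three_users_flagged(self):
        res = separation_test(self._preds([0.8, 0.7], [0.2, 0.3]))
        assert res.flagged and res.n_users == 2

    def test_null_p_values_uniform(self, rng):
        """Shuffled-label nulls: the paired-t p-value should be uniform."""
        ps = []
        for _ in range(200):
            fracs = rng.uniform(0.3, 0.7, (8, 2))
            res = separation_test(self._preds(fracs[:, 0], fracs[:, 1]))
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestModelGrid:
    def test_signal_only_in_c3_ranks_c3_over_d1(self):
        profile = StressProfile.null(posture_delta_g=0.3)
        table = build_lab_dataset(n_users=3, seed=77, profile=profile,
                                  task_plan=[(180.0, "stress"), (180.0, "relax")] * 2)
        ranked = model_grid(table, {"C3": ["C3"], "D1": ["D1"]})
        assert ranked[0][0] == "C3"
        assert ranked[0][1].mean_accuracy > ranked[1][1].mean_accuracy

    def test_duplicate_subset_request_rejected(self):
        table = build_lab_dataset(n_users=3, seed=1,
                                  task_plan=[(180.0, "stress"), (180.0, "relax")])
        with pytest.raises(ValueError, match="duplicate"):
            model_grid(table, {"bad": ["A1", "A1"]})

    def test_all_features_run_reports_sd(self):
        table = build_lab_dataset(n_users=3, seed=2,
                                  task_plan=[(180.0, "stress"), (180.0, "relax")] * 2)
        ranked = model_grid(table, {"ALL": ["A1", "A2", "A3", "B1", "B2",
                                            "C1", "C2", "C3", "D1", "D2"]})
        assert ranked[0][1].sd_accuracy >= 0
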