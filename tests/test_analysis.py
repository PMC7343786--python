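"""PCA selection, ADASYN balancing, LOOCV evaluation and rank-sum tests."""

import numpy as np
import pandas as pd
import pytest

import plaquesync as ps
from plaquesync.analysis import classification_metrics

from oracles import exact_ranksum_p


def cohort_with_effect(n_a=10, n_b=14, seed=0, delta=0.3, sd=0.1):
    feats = {f"f{i}": (0.5, 0.2) for i in range(6)}
    spec = ps.CohortSpec(
        n_per_group={"neg": n_a, "pos": n_b},
        feature_dists={
            "neg": {**feats, "f0": (0.2, sd)},
            "pos": {**feats, "f0": (0.2 + delta, sd)},
        },
        seed=seed,
    )
    return ps.generate_cohort(spec)


class TestPcaSelect:
    def test_duplicated_features_do_not_add_components(self):
        df = cohort_with_effect()
        doubled = pd.concat(
            [df.drop(columns="label"),
             df.drop(columns="label").add_suffix("_copy")],
            axis=1,
        )
        doubled["label"] = df["label"]
        red1, _ = ps.pca_select(df)
        red2, _ = ps.pca_select(doubled)
        n1 = len([c for c in red1.columns if c.startswith("PC")])
        n2 = len([c for c in red2.columns if c.startswith("PC")])
        assert n1 == n2

    def test_isotropic_features_need_all_components(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        df = pd.DataFrame(pts, columns=["a", "b", "c"])
        df["label"] = [0, 1, 0, 1, 0, 1]
        red, loadings = ps.pca_select(df)
        assert len(loadings) == 3

    def test_zero_variance_feature_dropped_with_warning(self):
        df = cohort_with_effect()
        df["dead"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            red, loadings = ps.pca_select(df)
        assert "dead" not in loadings.columns

    def test_variance_threshold_respected(self):
        df = cohort_with_effect(n_a=20, n_b=20, seed=5)
        red, _ = ps.pca_select(df, variance=0.95)
        n = len([c for c in red.columns if c.startswith("PC")])
        assert 1 <= n <= 7


class TestBalanceTraining:
    def make_table(self, n_min, n_maj, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(n_min, 3))
        b = rng.normal(3.0, 1.0, size=(n_maj, 3))
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"])
        df["label"] = ["min"] * n_min + ["maj"] * n_maj
        return df

    def test_already_balanced_unchanged(self):
        df = self.make_table(12, 12)
        out = ps.balance_training(df, seed=0)
        assert len(out) == len(df)

    def test_minority_grown_to_near_balance(self):
        df = self.make_table(10, 40)
        out = ps.balance_training(df, seed=0)
        counts = out.label.value_counts()
        assert counts["min"] == 40  # G = n_maj - n_min with beta = 1
        assert counts["maj"] == 40

    def test_synthetic_points_interpolate_minority_neighbourhoods(self):
        df = self.make_table(10, 40, seed=3)
        out = ps.balance_training(df, seed=1)
        minority = df[df.label == "min"][["x", "y", "z"]]
        synth = out.iloc[len(df):][["x", "y", "z"]]
        assert len(synth) > 0
        for col in ("x", "y", "z"):
            assert synth[col].min() >= minority[col].min() - 1e-9
            assert synth[col].max() <= minority[col].max() + 1e-9

    def test_tiny_minority_falls_back_to_duplication(self):
        df = self.make_table(3, 20)
        with pytest.warns(UserWarning, match="duplicating"):
            out = ps.balance_training(df, seed=0, k=5)
        assert out.label.value_counts()["min"] == 20


class TestMetrics:
    def test_confusion_counts_example(self):
        # TP=8 FP=1 FN=2 TN=9
        y = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.9] * 1 + [0.1] * 9)
        m = classification_metrics(y, scores)
        assert m["ACC"] == pytest.approx(0.85)
        assert m["SENS"] == pytest.approx(0.8)
        assert m["SPEC"] == pytest.approx(0.9)
        assert m["PREC"] == pytest.approx(8 / 9)
        assert m["NPV"] == pytest.approx(9 / 11)
        assert m["F1SC"] == pytest.approx(16 / 19)

    def test_f1_consistent_with_precision_and_recall(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=50)
        s = rng.uniform(size=50)
        m = classification_metrics(y, s)
        f1 = 2 * m["PREC"] * m["SENS"] / (m["PREC"] + m["SENS"])
        assert m["F1SC"] == pytest.approx(f1)

    def test_auc_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=60)
        s = rng.uniform(size=60)
        a1 = classification_metrics(y, s)["AUC"]
        a2 = classification_metrics(y, 1 / (1 + np.exp(-8 * (s - 0.5))))["AUC"]
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestEvaluateLoocv:
    def separable_cohort(self):
        spec = ps.CohortSpec(
            n_per_group={"neg": 8, "pos": 8},
            feature_dists={
                "neg": {"f0": (0.1, 0.0), "f1": (1.0, 0.0)},
                "pos": {"f0": (0.9, 0.0), "f1": (2.0, 0.0)},
            },
            seed=0,
        )
        return ps.generate_cohort(spec)

    def test_separable_cohort_is_perfectly_classified(self):
        report = ps.evaluate_loocv(self.separable_cohort(), seed=0)
        assert report["ACC"] == 1.0
        assert report["AUC"] == 1.0

    def test_deterministic_for_fixed_seed(self):
        df = cohort_with_effect(seed=2)
        r1 = ps.evaluate_loocv(df, seed=5)
        r2 = ps.evaluate_loocv(df, seed=5)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_tuning_grid_machinery(self):
        df = cohort_with_effect(n_a=10, n_b=10, seed=3, delta=0.6, sd=0.05)
        report = ps.evaluate_loocv(
            df, seed=0, tune=True, trees_grid=(50,), max_features_grid=(1, 2),
            inner_cv=3,
        )
        assert report["AUC"] > 0.9
        assert all(p["n_estimators"] == 50 for p in report.tuned_params)
        assert all(p["max_features"] in (1, 2) for p in report.tuned_params)

    def test_labels_must_be_binary(self):
        df = cohort_with_effect()
        df.loc[df.index[:3], "label"] = "third"
        with pytest.raises(ValueError, match="binary"):
            ps.evaluate_loocv(df, seed=0)


class TestWilcoxon:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        p = ps.wilcoxon_compare(v, v)
        assert p > 0.9

    def test_small_sample_matches_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = ps.wilcoxon_compare(a, b)
        assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-9)

    def test_threshold_is_inclusive(self):
        table = ps.wilcoxon_table(
            pd.DataFrame({"f": [1.0, 2, 3, 4]}),
            pd.DataFrame({"f": [10.0, 11, 12, 13]}),
        )
        # exact two-sided p for complete separation of 4 vs 4 is 2/70
        assert table.loc["f", "significant"]

    def test_all_tied_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            p = ps.wilcoxon_compare([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0
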