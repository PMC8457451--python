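import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleoscore import model_selection as ms
from nucleoscore.model_selection import (
    Chi2Selector,
    PipelineConfig,
    SequentialForwardSelector,
    baseline_config,
    derive_seed,
    fit_preprocessors,
    majority_vote,
    metrics,
    nested_cv,
    select_chi2,
    select_sfs,
)


def _gaussian_patients(n_per_class=10, n_features=72, gap=4.0, seed=0):
    """Two well-separated Gaussian classes in feature space."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    X1 = rng.normal(gap, 1.0, size=(n_per_class, n_features))
    X = np.vstack([X0, X1])
    y = ["nonPTC"] * n_per_class + ["PTC"] * n_per_class
    cols = [f"mean_f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "patient_id", [f"p{i}" for i in range(len(y))])
    df.insert(1, "class_label", y)
    return df


class TestPreprocessors:
    def test_both_off_is_identity(self, rng):
        X = rng.normal(size=(20, 5))
        cfg = PipelineConfig(quantile_transform=False, standard_scale=False)
        pre = fit_preprocessors(X, cfg)
        assert np.allclose(pre.transform(X), X)

    def test_standard_scale_statistics(self, rng):
        X = rng.normal(3, 7, size=(50, 4))
        cfg = PipelineConfig(quantile_transform=False, standard_scale=True)
        Xt = fit_preprocessors(X, cfg).transform(X)
        assert np.allclose(Xt.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Xt.std(axis=0), 1, atol=1e-9)

    def test_constant_feature_under_scaling(self):
        X = np.column_stack([np.full(10, 5.0), np.arange(10.0)])
        cfg = PipelineConfig(quantile_transform=False, standard_scale=True)
        Xt = fit_preprocessors(X, cfg).transform(X)
        assert np.allclose(Xt[:, 0], 0)  # centered, scale 1

    def test_quantile_preserves_ranks(self, rng):
        X = rng.lognormal(size=(40, 3))
        cfg = PipelineConfig(quantile_transform=True, standard_scale=False)
        Xt = fit_preprocessors(X, cfg).transform(X)
        for j in range(3):
            rho = stats.spearmanr(X[:, j], Xt[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_order_quantile_then_scale(self, rng):
        X = rng.lognormal(size=(40, 2))
        cfg = PipelineConfig(quantile_transform=True, standard_scale=True)
        pre = fit_preprocessors(X, cfg)
        assert [s[0] for s in pre.steps] == ["impute", "quantile", "scale"]


class TestChi2Selection:
    def test_k_equals_all_features(self, rng):
        X = pd.DataFrame(rng.uniform(size=(30, 6)), columns=list("abcdef"))
        y = rng.integers(0, 2, 30)
        assert set(select_chi2(X, y, 6)) == set("abcdef")

    def test_informative_feature_ranked_above_constant(self):
        y = np.array([0] * 15 + [1] * 15)
        X = pd.DataFrame(
            {"informative": y * 5.0, "constant": np.ones(30)}
        )
        assert select_chi2(X, y, 1) == ["informative"]

    def test_returns_exactly_k_names(self, rng):
        X = pd.DataFrame(
            rng.uniform(size=(40, 30)), columns=[f"f{i}" for i in range(30)]
        )
        y = rng.integers(0, 2, 40)
        assert len(select_chi2(X, y, 22)) == 22

    def test_negative_input_fatal_without_mapping(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValueError, match="non-negative"):
            Chi2Selector(k=2, scale_nonneg=False).fit(X, y)


class TestSequentialForwardSelection:
    def test_dominant_feature_selected_first(self, rng):
        y = np.array([0] * 12 + [1] * 12)
        X = pd.DataFrame(
            {
                "noise1": rng.normal(size=24),
                "signal": y + rng.normal(0, 0.05, 24),
                "noise2": rng.normal(size=24),
            }
        )
        assert select_sfs(X, y, 1)[0] == "signal"

    def test_selected_sets_are_nested(self, rng):
        X = rng.normal(size=(24, 8))
        y = rng.integers(0, 2, 24)
        a = SequentialForwardSelector(k=3, random_state=5).fit(X, y)
        b = SequentialForwardSelector(k=4, random_state=5).fit(X, y)
        assert b.selected_order_[:3] == a.selected_order_

    def test_returns_exactly_k_names(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(24, 25)), columns=[f"f{i}" for i in range(25)]
        )
        y = np.array([0, 1] * 12)
        names = select_sfs(X, y, 22)
        assert len(names) == 22 and len(set(names)) == 22


class TestMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 0, 1]
        out = metrics(y, y, scores=[0.1, 0.9, 0.2, 0.8])
        assert out["accuracy"] == 1.0
        assert out["kappa"] == 1.0
        assert out["auc"] == 1.0

    def test_one_class_predictions_give_zero_kappa(self):
        out = metrics([0, 0, 1, 1], [1, 1, 1, 1])
        assert out["kappa"] == 0.0
        assert out["accuracy"] == 0.5

    def test_confusion_sums_to_n(self, rng):
        y = rng.integers(0, 2, 25)
        p = rng.integers(0, 2, 25)
        assert metrics(y, p)["confusion"].sum() == 25

    def test_auc_matches_mann_whitney_pair_counting(self, rng):
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.normal(size=30)
        out = metrics(y, (s > 0).astype(int), scores=s)
        pos, neg = s[y == 1], s[y == 0]
        pairs = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert out["auc"] == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_truth_undefined(self):
        out = metrics([1, 1, 1], [1, 0, 1], scores=[1.0, 0.0, 2.0])
        assert np.isnan(out["kappa"]) and np.isnan(out["auc"])


class TestMajorityVote:
    def test_strict_majority_wins(self):
        assert majority_vote(["P", "P", "N"], true_class="N") == "P"

    def test_tie_assumes_wrong_class(self):
        assert majority_vote(["P", "N"], true_class="P") == "N"
        assert majority_vote(["P", "N"], true_class="N") == "P"

    def test_unanimous(self):
        assert majority_vote(["N", "N", "N", "N"], true_class="N") == "N"

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            majority_vote([], true_class="P")


class TestNestedCV:
    def test_separable_classes_recovered(self, fast_cv_config):
        df = _gaussian_patients(n_per_class=10, gap=4.0, seed=1)
        report = nested_cv(df, fast_cv_config)
        assert report.pooled_accuracy >= 0.95
        assert report.outer_folds == 5 and report.inner_folds == 4

    def test_determinism_under_seed(self, fast_cv_config):
        df = _gaussian_patients(n_per_class=8, gap=1.0, seed=2)
        a = nested_cv(df, fast_cv_config)
        b = nested_cv(df, fast_cv_config)
        assert a.pooled_accuracy == b.pooled_accuracy
        assert a.pooled_kappa == b.pooled_kappa
        for fa, fb in zip(a.folds, b.folds):
            assert fa.test_patient_ids == fb.test_patient_ids
            assert fa.chosen_hyperparams == fb.chosen_hyperparams
            assert fa.scores == fb.scores

    def test_stratified_outer_folds(self, fast_cv_config):
        df = _gaussian_patients(n_per_class=10, gap=0.5, seed=3)
        report = nested_cv(df, fast_cv_config)
        truth = dict(zip(df["patient_id"], df["class_label"]))
        for fold in report.folds:
            labels = [truth[p] for p in fold.test_patient_ids]
            assert abs(labels.count("PTC") - labels.count("nonPTC")) <= 1

    def test_too_few_patients_fatal(self, fast_cv_config):
        df = _gaussian_patients(n_per_class=3, seed=4)
        with pytest.raises(ValueError, match="per class"):
            nested_cv(df, fast_cv_config)

    def test_no_information_leak_from_fold_canary(self):
        # a feature encoding outer-test-fold membership must not lift
        # accuracy: preprocessing/selection/tuning see only training data
        df = _gaussian_patients(n_per_class=10, n_features=10, gap=0.0, seed=5)
        cfg = baseline_config(seed=9)
        base = nested_cv(df, cfg)
        fold0 = set(base.folds[0].test_patient_ids)
        canary = df.copy()
        canary["mean_canary"] = [
            1.0 if p in fold0 else 0.0 for p in canary["patient_id"]
        ]
        with_canary = nested_cv(canary, cfg)
        noise = 3 * np.sqrt(0.25 / len(df))
        assert with_canary.pooled_accuracy <= base.pooled_accuracy + noise

    def test_chi2_selection_inside_cv(self):
        df = _gaussian_patients(n_per_class=8, n_features=20, gap=3.0, seed=6)
        cfg = PipelineConfig(
            selector="chi2", k_features=5, hyper_grid={"C": [1.0]}, seed=11
        )
        report = nested_cv(df, cfg)
        assert all(len(f.chosen_features) == 5 for f in report.folds)
        assert report.pooled_accuracy >= 0.9


class TestBaselineConfig:
    def test_grid_of_size_one(self):
        cfg = baseline_config()
        assert cfg.grid() == {}
        assert cfg.standard_scale and not cfg.quantile_transform
        assert cfg.selector is ms.Selector.NONE

    def test_marks_optimization_disabled(self):
        df = _gaussian_patients(n_per_class=6, gap=3.0, seed=7)
        report = nested_cv(df, baseline_config(seed=3))
        assert report.hyperparameter_optimization is False
        assert all(f.chosen_hyperparams == {} for f in report.folds)

    def test_outer_splits_match_tuned_run(self, fast_cv_config):
        df = _gaussian_patients(n_per_class=8, gap=1.0, seed=8)
        tuned_cfg = PipelineConfig(
            quantile_transform=True,
            standard_scale=True,
            hyper_grid={"C": [1.0, 10.0]},
            seed=13,
        )
        tuned = nested_cv(df, tuned_cfg)
        base = nested_cv(df, baseline_config(seed=13))
        for ft, fb in zip(tuned.folds, base.folds):
            assert ft.test_patient_ids == fb.test_patient_ids


class TestSeedDerivation:
    def test_distinct_streams(self):
        seeds = {derive_seed(42, s) for s in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)

    def test_reproducible(self):
        assert derive_seed(7, 3) == derive_seed(7, 3)
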