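"""Cross-validation, ROC/AUC oracles, operating points, importances."""
import numpy as np
import pandas as pd
import pytest

from tnepredict import errors
from tnepredict import oct_features as of
from tnepredict import predict_eval as pe


def brute_force_auc(probs, labels):
    """All-pairs concordance with ties counted one half."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = probs[labels], probs[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def toy_features(n, n_features=5, seed=0, signal=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    cols = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols, index=[f"e{i}" for i in range(n)])
    if signal is not None:
        y = (X[:, signal] > 0).astype(int)
    else:
        y = rng.integers(0, 2, size=n)
    return df, pd.Series(y, index=df.index)


class TestStratifiedKFold:
    def test_exact_divisibility_gives_balanced_folds(self):
        y = np.array([0] * 50 + [1] * 50)
        folds = pe.stratified_kfold(y, k=10, seed=0)
        for j in range(10):
            sel = folds == j
            assert sel.sum() == 10
            assert y[sel].sum() == 5

    def test_fold_sizes_for_228_samples(self):
        y = np.array([0] * 103 + [1] * 125)
        folds = pe.stratified_kfold(y, k=10, seed=1)
        sizes = np.bincount(folds)
        assert set(sizes) <= {22, 23}
        # per-fold class counts within 1 of proportional allocation
        for j in range(10):
            assert abs(y[folds == j].sum() - 12.5) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(errors.ContractError):
            pe.stratified_kfold(np.array([0] * 95 + [1] * 5), k=10)

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 30)
        assert np.array_equal(
            pe.stratified_kfold(y, k=5, seed=3), pe.stratified_kfold(y, k=5, seed=3)
        )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = pe.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_fully_tied_scores_give_half(self):
        auc, _ = pe.roc_auc([0.6, 0.4, 0.6, 0.4], [1, 1, 0, 0])
        assert auc == 0.5

    def test_label_flip_symmetry(self, rng):
        p = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a1, _ = pe.roc_auc(p, y)
        a2, _ = pe.roc_auc(p, 1 - y)
        assert a1 == pytest.approx(1.0 - a2)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_concordance(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 200))
        p = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        auc, _ = pe.roc_auc(p, y)
        assert auc == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(errors.ContractError):
            pe.roc_auc([0.1, 0.9], [1, 1])


class TestBootstrapCi:
    def test_perfect_separation_collapses(self):
        p = np.r_[np.full(100, 0.9), np.full(100, 0.1)]
        y = np.r_[np.ones(100), np.zeros(100)]
        lo, hi = pe.bootstrap_auc_ci(p, y, n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_ordering_and_determinism(self, rng):
        p, y = rng.random(80), rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        a = pe.bootstrap_auc_ci(p, y, n_boot=300, seed=5)
        b = pe.bootstrap_auc_ci(p, y, n_boot=300, seed=5)
        assert a == b
        assert a[0] <= a[1]

    def test_interval_contains_point_auc_typically(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            y = rng.integers(0, 2, 120)
            y[:2] = [0, 1]
            p = np.clip(0.5 + 0.3 * (y - 0.5) + rng.normal(0, 0.25, 120), 0, 1)
            auc, _ = pe.roc_auc(p, y)
            lo, hi = pe.bootstrap_auc_ci(p, y, n_boot=300, seed=rep)
            hits += lo <= auc <= hi
        assert hits >= 19


class TestOperatingPoints:
    def test_perfect_classifier(self):
        _, roc = pe.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        ops = pe.operating_points(roc)
        assert ops["youden"] == (1.0, 1.0)

    def test_youden_matches_exhaustive_threshold_search(self, rng):
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        _, roc = pe.roc_auc(p, y)
        ops = pe.operating_points(roc)
        best_j, best = -np.inf, None
        for thr in np.unique(np.r_[p, 0.0, 1.1]):
            sens = np.mean(p[y == 1] >= thr)
            spec = np.mean(p[y == 0] < thr)
            j = sens + spec - 1
            if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and best and spec > best[1]):
                best_j, best = j, (sens, spec)
        assert ops["youden"][0] + ops["youden"][1] - 1 == pytest.approx(best_j, abs=1e-12)

    def test_spec80_definition(self, rng):
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        _, roc = pe.roc_auc(p, y)
        sens, spec = pe.operating_points(roc)["spec80"]
        assert spec >= 0.80
        # no admissible point has smaller specificity still >= 0.80
        admissible = roc[1.0 - roc["fpr"] >= 0.80]
        assert spec == pytest.approx(float((1.0 - admissible["fpr"]).min()))


class TestCvPredict:
    RF = pe.RfConfig(n_trees=200, seed=0)

    def test_separable_data_perfect_out_of_fold_accuracy(self):
        X, y = toy_features(100, seed=1, signal=0)
        X["f0"] = y * 10.0  # feature equals (a scaling of) the label
        ev = pe.cv_predict(X, y, rf=self.RF, k=5, n_boot=50, seed=1)
        assert np.mean((ev.probs > 0.5) == y) == 1.0
        assert ev.auc == 1.0

    def test_every_sample_predicted_once(self):
        X, y = toy_features(90, seed=2, signal=1)
        ev = pe.cv_predict(X, y, rf=self.RF, k=5, n_boot=50, seed=2)
        assert not np.isnan(ev.probs).any()
        assert len(ev.oob_errors) == 5

    def test_permuted_labels_give_chance_auc(self):
        X, y = toy_features(200, seed=3, signal=0)
        rng = np.random.default_rng(3)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        ev = pe.cv_predict(X, y_perm, rf=self.RF, k=5, n_boot=50, seed=3)
        assert 0.4 <= ev.auc <= 0.6

    def test_missing_values_rejected(self):
        X, y = toy_features(60, seed=4, signal=0)
        X.iloc[0, 0] = np.nan
        with pytest.raises(errors.MissingDataError):
            pe.cv_predict(X, y, rf=self.RF, k=5)

    def test_feature_set_selection_counts(self):
        names = of.feature_names()
        assert len(pe.select_features(names, "all")) == 50
        assert len(pe.select_features(names, "imaging_only")) == 45
        baseline = pe.select_features(names, "baseline_only")
        assert len(baseline) == 18
        assert {"bcva_M0", "age", "sex"} <= set(baseline)
        assert not any(n.endswith(("_M1", "_change")) for n in baseline)


class TestPermutationImportance:
    def test_informative_feature_ranks_first_and_noise_near_zero(self):
        X, y = toy_features(300, n_features=6, seed=5, signal=2)
        ev = pe.cv_predict(X, y, rf=pe.RfConfig(n_trees=300, seed=5), k=5, n_boot=50, seed=5)
        imp = pe.permutation_importance(ev, X, seed=5, n_perm=5)
        assert imp.index[0] == "f2"
        assert (imp.drop("f2").abs() < 0.02).all()

    def test_deterministic_given_seed(self):
        X, y = toy_features(120, seed=6, signal=0)
        ev = pe.cv_predict(X, y, rf=pe.RfConfig(n_trees=100, seed=6), k=4, n_boot=20, seed=6)
        a = pe.permutation_importance(ev, X, seed=9, n_perm=3)
        b = pe.permutation_importance(ev, X, seed=9, n_perm=3)
        pd.testing.assert_series_equal(a, b)


class TestRunExperiment:
    def test_report_contains_one_evaluation_per_feature_set(self):
        X, y = toy_features(80, n_features=50, seed=7, signal=0)
        X.columns = of.feature_names()
        res = pe.run_experiment(
            X, y, target="toy", feature_sets=("all", "imaging_only"),
            rf=pe.RfConfig(n_trees=100, seed=7), k=4, n_boot=20, seed=7,
            compute_importance=False,
        )
        assert set(res) == {"all", "imaging_only"}
        report = pe.experiment_report(res, "toy")
        assert set(report["feature_sets"]) == {"all", "imaging_only"}

    def test_join_mismatch_lists_orphans(self):
        X, y = toy_features(40, seed=8, signal=0)
        y_bad = y.iloc[:-3]
        with pytest.raises(errors.MissingDataError, match="e37"):
            pe.run_experiment(X, y_bad, target="toy", feature_sets=("all",))
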