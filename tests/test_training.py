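import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from conftest import make_rings
from icages.errors import (
    CollinearityError,
    ConfigurationError,
    ConvergenceError,
    TrainingError,
)
from icages.fixtures import FixtureSpec, draw_class_predictors, make_labeled_gene_set
from icages.training import (
    backward_select,
    fit_platt,
    logistic_loss,
    roc_auc,
    train_ensemble,
    train_logistic,
)
from icages.variant_layer import SvmHyperparams


def brute_force_auc(scores, labels):
    """Oracle: all TP x TN pairwise comparisons, ties credited 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], replicates=50, seed=0)
        assert r.auc == 1.0

    def test_all_ties(self):
        r = roc_auc([0.5] * 10, [1, 0] * 5, replicates=50, seed=0)
        assert r.auc == 0.5

    def test_single_class_error(self):
        with pytest.raises(TrainingError):
            roc_auc([0.1, 0.2], [1, 1], replicates=10, seed=0)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            # discretized scores force ties
            scores = np.round(rng.uniform(size=n), 1)
            r = roc_auc(scores, labels, replicates=10, seed=0)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels),
                                          abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 2000
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        scores = rng.uniform(size=n)
        r = roc_auc(scores, labels, replicates=100, seed=0)
        assert r.auc == pytest.approx(0.5, abs=0.03)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=100)
        labels = (rng.uniform(size=100) < 0.5).astype(int)
        r = roc_auc(scores, labels, replicates=200, seed=0)
        assert r.ci_low <= r.auc <= r.ci_high


class TestTrainEnsemble:
    def test_singleton_grid_selected(self):
        rng = np.random.default_rng(4)
        X = np.vstack([draw_class_predictors(rng, 50, True, 3.0),
                       draw_class_predictors(rng, 50, False, 3.0)])
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        grid = (SvmHyperparams(c=10.0, gamma=0.001),)
        model, _ = train_ensemble(X, y, grid=grid, seed=0, replicates=20)
        assert model.hyperparams == grid[0]

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        X = np.vstack([draw_class_predictors(rng, 60, True, 2.0),
                       draw_class_predictors(rng, 60, False, 2.0)])
        y = np.r_[np.ones(60, int), np.zeros(60, int)]
        grid = tuple(SvmHyperparams(c, g) for c in (1.0, 10.0) for g in (1e-3, 1e-2))
        m1, r1 = train_ensemble(X, y, grid=grid, seed=9, replicates=50)
        m2, r2 = train_ensemble(X, y, grid=grid, seed=9, replicates=50)
        assert m1.hyperparams == m2.hyperparams
        assert r1.auc == r2.auc
        assert np.array_equal(m1.support_vectors, m2.support_vectors)
        assert (m1.prob_a, m1.prob_b) == (m2.prob_a, m2.prob_b)

    def test_single_class_error(self):
        X = np.random.default_rng(0).uniform(size=(20, 11))
        with pytest.raises(TrainingError):
            train_ensemble(X, np.ones(20, int))

    def test_fold_count_error(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(8, 11))
        y = np.r_[np.ones(3, int), np.zeros(5, int)]
        with pytest.raises(ConfigurationError):
            train_ensemble(X, y, folds=5)

    def test_rings_radial_beats_linear(self):
        rng = np.random.default_rng(7)
        X, y = make_rings(rng, n=400)
        grid = tuple(SvmHyperparams(c, g) for c in (1.0, 10.0)
                     for g in (0.1, 1.0, 10.0, 100.0, 1000.0))
        _, roc = train_ensemble(X, y, grid=grid, folds=5, seed=7, replicates=50)
        assert roc.auc > 0.95
        # linear comparator on the identical folds
        skf = StratifiedKFold(5, shuffle=True, random_state=7)
        from icages.training import _auc
        aucs = []
        for tr, te in skf.split(X, y):
            clf = SVC(C=10.0, kernel="linear").fit(X[tr], y[tr])
            aucs.append(_auc(clf.decision_function(X[te]), y[te]))
        assert np.mean(aucs) < 0.6


class TestBackwardSelect:
    def _informative(self, rng, n=150, p=4):
        y = rng.integers(0, 2, size=n)
        X = rng.uniform(size=(n, p)) * 0.4 + 0.6 * y[:, None] * rng.uniform(
            0.5, 1.0, size=(n, p))
        return X, y

    def test_noise_feature_dropped_first(self):
        rng = np.random.default_rng(8)
        X, y = self._informative(rng, p=3)
        X = np.c_[X, rng.uniform(size=len(y))]  # pure-noise column
        names = ("f0", "f1", "f2", "noise")
        hp = SvmHyperparams(c=10.0, gamma=1.0)
        retained, trace = backward_select(X, y, feature_names=names,
                                         hyperparams=hp, folds=3, seed=0)
        dropped = set(names) - set(retained)
        if dropped:  # greedy may stop immediately if no removal improves AUC
            assert "f0" in retained and "f1" in retained and "f2" in retained
        assert trace[0][0] == list(names)

    def test_all_informative_features_survive(self):
        rng = np.random.default_rng(9)
        X, y = self._informative(rng, p=4)
        hp = SvmHyperparams(c=10.0, gamma=1.0)
        retained, trace = backward_select(X, y, feature_names=("a", "b", "c", "d"),
                                         hyperparams=hp, folds=3, seed=0)
        assert set(retained) == {"a", "b", "c", "d"}
        assert len(trace) == 1

    def test_label_copy_retained(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, size=80)
        X = np.c_[y.astype(float), rng.uniform(size=80)]
        hp = SvmHyperparams(c=10.0, gamma=1.0)
        retained, _ = backward_select(X, y, feature_names=("copy", "junk"),
                                      hyperparams=hp, folds=3, seed=0)
        assert "copy" in retained

    def test_requires_two_features(self):
        with pytest.raises(ConfigurationError):
            backward_select(np.zeros((10, 1)), np.r_[np.ones(5), np.zeros(5)])


class TestTrainLogistic:
    def test_parameter_recovery(self):
        spec = FixtureSpec(seed=4)
        X, y = make_labeled_gene_set(spec, n=5000)
        w, b = train_logistic(X, y)
        target = np.r_[spec.planted_lr_weights, spec.planted_lr_bias]
        rel = np.abs(np.r_[w, b] - target) / np.abs(target)
        assert rel.max() < 0.10

    def test_recovery_error_shrinks_with_n(self):
        spec = FixtureSpec(seed=4)
        target = np.r_[spec.planted_lr_weights, spec.planted_lr_bias]
        errs = {}
        for n in (500, 5000):
            X, y = make_labeled_gene_set(spec, n=n)
            w, b = train_logistic(X, y)
            errs[n] = float(np.sqrt(np.mean((np.r_[w, b] - target) ** 2)))
        assert errs[5000] < errs[500]

    def test_gradient_norm_at_optimum(self):
        spec = FixtureSpec(seed=0)
        X, y = make_labeled_gene_set(spec, n=2000)
        w, b = train_logistic(X, y)
        Xb = np.hstack([X, np.ones((len(y), 1))])
        mu = 1 / (1 + np.exp(-(Xb @ np.r_[w, b])))
        grad = Xb.T @ (mu - y) / len(y)
        assert np.linalg.norm(grad) <= 1e-8
        assert logistic_loss(w, b, X, y) <= logistic_loss(np.zeros(4), 0.0, X, y)

    def test_single_class_error(self):
        X = np.random.default_rng(0).uniform(size=(30, 4))
        with pytest.raises(TrainingError):
            train_logistic(X, np.zeros(30))

    def test_collinearity_error(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=200)
        X = np.c_[a, a + 0.02 * rng.standard_normal(200),
                  rng.uniform(size=200), rng.uniform(size=200)]
        y = (rng.uniform(size=200) < 0.5).astype(float)
        with pytest.raises(CollinearityError):
            train_logistic(X, y)

    def test_perfect_separation_reported(self):
        X = np.r_[np.full((20, 1), 0.9), np.full((20, 1), 0.1)]
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(ConvergenceError) as err:
            train_logistic(X, y)
        assert err.value.direction is not None
        assert err.value.direction[0] > 0  # diverges toward the separating axis


class TestFitPlatt:
    def test_recovers_sigmoid_direction(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-3.0 * d))
        y = (rng.uniform(size=2000) < p).astype(int)
        a, b = fit_platt(d, y)
        # model is P = 1/(1+exp(a*d+b)) so a should be about -3
        assert a == pytest.approx(-3.0, abs=0.5)
        assert abs(b) < 0.3
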