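"""Feature extraction, cross-validated SVM evaluation, permutation test."""

import numpy as np
import pandas as pd
import pytest

from perceptgamma import classify as cl
from perceptgamma import timefreq as tf
from perceptgamma.classify import FeatureMatrix
from perceptgamma.containers import BehaviourLog, InvariantError

from conftest import SEED


def _tfr(power, freqs=None, labels=None, channel_labels=None):
    power = np.asarray(power, np.float32)
    n_tr, n_ch, n_f, n_t = power.shape
    return tf.TFR(
        power=power,
        freqs=freqs if freqs is not None else np.arange(n_f) + 60.0,
        times=np.linspace(-3.0, 0.0, n_t),
        channel_labels=channel_labels or ["O1", "OZ"][:n_ch],
        labels=labels or (["perceived"] * (n_tr // 2)
                          + ["unperceived"] * (n_tr - n_tr // 2)),
        normalized=True,
    )


def _fm(X, y, band="60-75"):
    return FeatureMatrix(X=np.asarray(X, float), y=np.asarray(y, bool),
                         band=band, roster=["O1"],
                         times=np.arange(np.asarray(X).shape[1]),
                         excluded_trials=[])


class TestExtractFeatures:
    def test_constant_power_gives_constant_features(self):
        t = _tfr(np.full((6, 2, 3, 20), 2.0))
        fm = cl.extract_features(t, "60-75", (-3.0, 0.0), feature_rate=None)
        np.testing.assert_allclose(fm.X, 2.0)

    def test_response_inside_window_excluded(self):
        t = _tfr(np.random.default_rng(SEED).random((6, 2, 3, 20)))
        rts = np.array([4.0, 10.5, 5.0, np.nan, np.nan, np.nan])
        fm = cl.extract_features(t, "60-75", (-3.0, 0.0),
                                 response_times=rts,
                                 window_in_trial=(9.0, 12.0))
        assert fm.excluded_trials == [1]
        assert len(fm.y) == 5

    def test_hand_computed_toy(self):
        """2 channels x 2 bins x 3 timepoints: equality with enumeration."""
        p = np.arange(1 * 2 * 2 * 3, dtype=float).reshape(1, 2, 2, 3)
        p = np.concatenate([p, 2 * p])
        t = _tfr(p, freqs=np.array([60.0, 70.0]))
        fm = cl.extract_features(t, "60-75", (-3.0, 0.0), feature_rate=None)
        np.testing.assert_allclose(fm.X, p.mean(axis=(1, 2)))

    def test_roster_outside_occipito_parietal_rejected(self):
        t = _tfr(np.random.default_rng(SEED).random((4, 2, 3, 10)),
                 channel_labels=["FP1", "FP2"])
        with pytest.raises(InvariantError, match="occipito-parietal"):
            cl.extract_features(t, "60-75", (-3.0, 0.0),
                                roster=["FP1", "FP2"])

    def test_unnormalized_tfr_rejected(self):
        t = _tfr(np.random.default_rng(SEED).random((4, 2, 3, 10)))
        t.normalized = False
        with pytest.raises(InvariantError, match="normalized"):
            cl.extract_features(t, "60-75", (-3.0, 0.0))


class TestTrainEvalCV:
    def test_separable_clusters_reach_perfect_accuracy(self):
        rng = np.random.default_rng(SEED)
        X = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(10, 1, (20, 5))])
        y = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        rep = cl.train_eval_cv(_fm(X, y), repetitions=5, seed=SEED)
        assert rep.accuracy == 100.0 and rep.balanced_accuracy == 100.0

    def test_random_labels_stay_at_chance(self):
        rng = np.random.default_rng(SEED)
        X = rng.standard_normal((200, 5))
        y = np.zeros(200, bool)
        y[:100] = True
        rep = cl.train_eval_cv(_fm(X, rng.permutation(y)),
                               repetitions=5, seed=SEED)
        assert 42.0 <= rep.accuracy <= 58.0

    def test_balanced_accuracy_identity(self):
        """Pooled-confusion metrics satisfy bal = (sens + spec)/2 exactly."""
        rng = np.random.default_rng(SEED)
        X = rng.standard_normal((60, 4))
        y = np.zeros(60, bool)
        y[:40] = True
        X[y] += 1.0
        rep = cl.train_eval_cv(_fm(X, y), repetitions=8, seed=SEED)
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2, abs=1e-9)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(SEED)
        X = rng.standard_normal((30, 4))
        y = np.zeros(30, bool)
        y[:15] = True
        r1 = cl.train_eval_cv(_fm(X, y), repetitions=5, seed=123)
        r2 = cl.train_eval_cv(_fm(X, y), repetitions=5, seed=123)
        assert r1.as_dict() == r2.as_dict()

    def test_too_few_trials_per_class_rejected(self):
        X = np.zeros((5, 2))
        y = np.array([True, True, False, False, False])
        with pytest.raises(InvariantError, match="folds"):
            cl.train_eval_cv(_fm(X, y), k_folds=3)

    def test_leakage_canary(self):
        """A feature equal to the label decodes perfectly; the same feature
        shuffled independently of the labels falls back to chance —
        standardization fit on training folds only cannot leak."""
        rng = np.random.default_rng(SEED)
        n = 60
        y = np.zeros(n, bool)
        y[:30] = True
        leak = np.where(y, 1.0, -1.0)[:, None] + 0.01 * rng.standard_normal(
            (n, 1))
        rep = cl.train_eval_cv(_fm(leak, y), repetitions=3, seed=SEED)
        assert rep.balanced_accuracy == 100.0
        rep0 = cl.train_eval_cv(_fm(rng.permutation(leak), y),
                                repetitions=3, seed=SEED)
        assert rep0.balanced_accuracy < 70.0

    def test_effect_size_monotonicity(self):
        """Mean balanced accuracy does not decrease when the class
        separation grows (up to Monte-Carlo error)."""
        rng = np.random.default_rng(SEED)
        base = rng.standard_normal((40, 4))
        y = np.zeros(40, bool)
        y[:20] = True
        scores = []
        for effect in (0.0, 1.0, 3.0):
            X = base.copy()
            X[y] += effect
            rep = cl.train_eval_cv(_fm(X, y), repetitions=5, seed=SEED)
            scores.append(rep.balanced_accuracy)
        assert scores[1] >= scores[0] - 5.0
        assert scores[2] >= scores[1] - 5.0


class TestCompiledSolverAgreesWithLibrary:
    def test_objective_at_least_as_optimal_and_decisions_correlate(self):
        """The dual-CD solver minimizes the identical primal objective as
        LinearSVC(dual=True); its solution must be at least as optimal,
        and decision values must agree closely."""
        from sklearn.svm import LinearSVC

        from perceptgamma._svm_cd import decision_function, fit_linear_svm

        def primal(w, b, X, y, C):
            yy = np.where(y, 1.0, -1.0)
            slack = np.maximum(1 - yy * (X @ w + b), 0.0)
            return 0.5 * (w @ w + b * b) + C * slack.sum()

        import warnings

        rng = np.random.default_rng(SEED)
        for _ in range(10):
            X = rng.standard_normal((24, 5))
            y = rng.random(24) < 0.5
            if y.all() or not y.any():
                continue
            for C in (0.01, 1.0, 100.0):
                w = fit_linear_svm(X, y, C, max_iter=20000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sk = LinearSVC(C=C, dual=True, max_iter=200000,
                                   tol=1e-10, random_state=0).fit(X, y)
                mine = primal(w[:-1], w[-1], X, y, C)
                theirs = primal(sk.coef_[0], sk.intercept_[0], X, y, C)
                assert mine <= theirs * (1 + 1e-6) + 1e-9
                if theirs <= mine * (1 + 1e-4):
                    # compare decisions only where liblinear actually
                    # reached the shared optimum (it sometimes stalls at a
                    # visibly worse objective on inseparable toys)
                    r = np.corrcoef(decision_function(X, w),
                                    sk.decision_function(X))[0, 1]
                    assert r > 0.99


class TestPermutationTest:
    def test_strong_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(SEED)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(8, 1, (10, 3))])
        y = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        p = cl.permutation_test(_fm(X, y), n_permutations=999, seed=SEED)
        assert p == pytest.approx(1 / 1000)

    def test_anti_informative_labels_give_large_p(self):
        """If every permutation scores at least as well as the observed
        labelling, p approaches 1."""
        rng = np.random.default_rng(SEED)
        X = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(6, 1, (8, 2))])
        # labels deliberately split each true cluster in half
        y = np.array([True, False] * 8)
        p = cl.permutation_test(_fm(X, y), n_permutations=199, seed=SEED)
        assert p > 0.5

    def test_too_few_permutations_rejected(self):
        with pytest.raises(InvariantError):
            cl.permutation_test(_fm(np.zeros((6, 2)),
                                    [True, False, True, False, True, False]),
                                n_permutations=10)


class TestSubjectEligibility:
    def _log(self, n_unperceived, n=20):
        perceived = [False] * n_unperceived + [True] * (n - n_unperceived)
        return BehaviourLog(pd.DataFrame({
            "trial": np.arange(n),
            "response_time": [np.nan if not p else 3.0 for p in perceived],
            "perceived": perceived, "correct": perceived}))

    def test_nine_unperceived_excluded_at_threshold_ten(self):
        logs = {"s1": self._log(9), "s2": self._log(10)}
        assert cl.subject_eligibility(logs, 10) == ["s2"]

    def test_zero_threshold_includes_all(self):
        logs = {"s1": self._log(0), "s2": self._log(5)}
        assert cl.subject_eligibility(logs, 0) == ["s1", "s2"]

    def test_cohort_style_roster(self):
        """14 synthetic subjects, 6 configured with >= 10 unperceived
        trials: exactly those pass the threshold."""
        rng = np.random.default_rng(SEED)
        counts = [12, 3, 15, 0, 10, 8, 11, 2, 14, 9, 5, 10, 7, 4]
        logs = {f"s{i:02d}": self._log(c) for i, c in enumerate(counts)}
        eligible = cl.subject_eligibility(logs, 10)
        assert len(eligible) == 6
        assert eligible == [f"s{i:02d}" for i, c in enumerate(counts)
                            if c >= 10]
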