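"""Linear maximum-margin decoding of perceptual states.

Features are band- and channel-averaged normalized power time courses over
the occipito-parietal roster within a fixed analysis window (the last 3 s
of the movie by default).  Model selection and evaluation mirror the
published scheme: a linear SVM, 3-fold stratified cross-validation over a
log-spaced C grid, thirty repetitions with re-randomized folds, metrics
from the pooled confusion matrix of each repetition, and a label-
permutation test whose observed and permuted scores both use leave-one-out
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import BehaviourLog, InvariantError
from .montage import OCCIPITO_PARIETAL, occipito_parietal_roster
from .timefreq import TFR, BandSpec

DEFAULT_C_GRID = tuple(10.0 ** np.arange(-3, 4))

POSITIVE_CLASS = "perceived"  # sensitivity = perceived recall


@dataclass
class FeatureMatrix:
    """Trials × time-point features for one band."""

    X: np.ndarray
    y: np.ndarray              # boolean, True = perceived
    band: str
    roster: list[str]
    times: np.ndarray
    excluded_trials: list[int]

    def __post_init__(self):
        if not np.all(np.isfinite(self.X)):
            raise InvariantError("features contain missing values")
        if self.X.shape[0] != len(self.y):
            raise InvariantError("label/feature length mismatch")
        if self.y.all() or not self.y.any():
            raise InvariantError("both classes must be represented")


@dataclass
class BandReport:
    """Per-band classifier metrics, mean ± sd over repetitions (%)."""

    band: str
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    balanced_accuracy: float
    balanced_accuracy_sd: float
    chosen_C: float
    permutation_p: float | None = None

    def __post_init__(self):
        for v in (self.accuracy, self.sensitivity, self.specificity,
                  self.balanced_accuracy):
            if not 0 <= v <= 100:
                raise InvariantError("metrics must lie in [0, 100]")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "band", "accuracy", "accuracy_sd", "sensitivity", "sensitivity_sd",
            "specificity", "specificity_sd", "balanced_accuracy",
            "balanced_accuracy_sd", "chosen_C", "permutation_p")}


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy = (sensitivity + specificity) / 2."""
    return (sensitivity + specificity) / 2.0


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    tfr: TFR, band: str, window: tuple[float, float],
    roster: list[str] | None = None,
    bands: BandSpec | None = None,
    response_times: np.ndarray | None = None,
    window_in_trial: tuple[float, float] | None = None,
    feature_rate: float | None = 10.0,
    collapse_time: bool = False,
) -> FeatureMatrix:
    """Band/channel-averaged normalized power time points as features.

    ``window`` is in epoch time.  If ``response_times`` and
    ``window_in_trial`` (the window's absolute position within the trial)
    are given, perceived trials whose response falls inside the window are
    excluded so motor activity cannot leak into the features.  The time
    axis is decimated to ``feature_rate`` Hz (or collapsed to one scalar
    with ``collapse_time=True``).
    """
    if not tfr.normalized:
        raise InvariantError("features must come from a normalized TFR")
    bands = bands or BandSpec.default()
    if roster is None:
        roster = occipito_parietal_roster(tfr.channel_labels)
    allowed = set(OCCIPITO_PARIETAL)
    if {str(r).upper() for r in roster} - allowed:
        raise InvariantError("roster must be a subset of the "
                             "occipito-parietal channel list")
    if not roster:
        raise InvariantError("empty channel roster")
    series = None
    fidx = bands.members(band, tfr.freqs)
    if len(fidx) == 0:
        raise InvariantError(f"band {band} has no frequency bins")
    ch_idx = np.array([tfr.channel_index(c) for c in roster])
    tmask = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not tmask.any():
        raise InvariantError("feature window outside the epochs")
    series = tfr.power[:, ch_idx][:, :, fidx][:, :, :, tmask].mean(axis=(1, 2))
    times = tfr.times[tmask]

    y = np.array([lab == POSITIVE_CLASS for lab in tfr.labels])
    keep = np.ones(len(y), bool)
    excluded = []
    if response_times is not None and window_in_trial is not None:
        lo, hi = window_in_trial
        rts = np.asarray(response_times, float)
        for i in range(len(y)):
            if y[i] and np.isfinite(rts[i]) and lo <= rts[i] <= hi:
                keep[i] = False
                excluded.append(i)
    series, y = series[keep], y[keep]
    if y.sum() == 0 or (~y).sum() == 0:
        raise InvariantError("response-overlap exclusions emptied a class")

    if collapse_time:
        X = series.mean(axis=1, keepdims=True)
        times = np.array([times.mean()])
    elif feature_rate is not None:
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        step = max(int(round(1.0 / (feature_rate * dt))), 1)
        X = series[:, ::step]
        times = times[::step]
    else:
        X = series
    return FeatureMatrix(X=X, y=y, band=band, roster=list(roster),
                         times=times, excluded_trials=excluded)


# ---------------------------------------------------------------------------
# Cross-validated training and evaluation
# ---------------------------------------------------------------------------

def _fit_predict(X_tr, y_tr, X_te, C):
    clf = LinearSVC(C=C, dual=True, max_iter=20000, random_state=0)
    with warnings.catch_warnings():
        # extreme C values on near-degenerate folds may stop at max_iter;
        # the grid search simply scores such fits as-is
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_tr, y_tr)
    return clf.predict(X_te)


def _standardize(X_tr, X_te):
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_tr - mu) / sd, (X_te - mu) / sd


def _confusion_metrics(y_true, y_pred):
    tp = np.sum(y_pred & y_true)
    tn = np.sum(~y_pred & ~y_true)
    fp = np.sum(y_pred & ~y_true)
    fn = np.sum(~y_pred & y_true)
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return 100 * acc, 100 * sens, 100 * spec


def _cv_predict(X, y, C, folds, standardize):
    pred = np.zeros(len(y), bool)
    for tr_idx, te_idx in folds:
        X_tr, X_te = X[tr_idx], X[te_idx]
        if standardize:
            X_tr, X_te = _standardize(X_tr, X_te)
        pred[te_idx] = _fit_predict(X_tr, y[tr_idx], X_te, C)
    return pred


def train_eval_cv(
    fm: FeatureMatrix, k_folds: int = 3, repetitions: int = 30,
    C_grid=DEFAULT_C_GRID, seed: int = 0, standardize: bool = True,
) -> BandReport:
    """Repeated stratified k-fold evaluation with inner C selection.

    Per repetition: re-randomized stratified folds; for each C on the grid
    the cross-validated predictions are pooled into one confusion matrix
    and C is chosen by balanced accuracy; that C's pooled metrics are the
    repetition's metrics.  Feature standardization is fit on training
    folds only.  Reported values are mean ± sd over repetitions.
    """
    X, y = fm.X, fm.y
    n_min = min(y.sum(), (~y).sum())
    if n_min < k_folds:
        raise InvariantError(
            f"smallest class has {n_min} trials < {k_folds} folds; "
            "use fewer folds")
    rng = np.random.default_rng(seed)
    accs, senss, specs, bals, cs = [], [], [], [], []
    for _ in range(repetitions):
        skf = StratifiedKFold(k_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        folds = list(skf.split(X, y))
        best = None
        for C in C_grid:
            pred = _cv_predict(X, y, C, folds, standardize)
            acc, sens, spec = _confusion_metrics(y, pred)
            bal = balanced_accuracy(sens, spec)
            if best is None or bal > best[0]:
                best = (bal, acc, sens, spec, C)
        bal, acc, sens, spec, C = best
        accs.append(acc); senss.append(sens); specs.append(spec)
        bals.append(bal); cs.append(C)
    cs = np.asarray(cs)
    chosen = float(spstats_mode(cs))
    return BandReport(
        band=fm.band,
        accuracy=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        sensitivity=float(np.mean(senss)), sensitivity_sd=float(np.std(senss)),
        specificity=float(np.mean(specs)), specificity_sd=float(np.std(specs)),
        balanced_accuracy=float(np.mean(bals)),
        balanced_accuracy_sd=float(np.std(bals)),
        chosen_C=chosen,
    )


def spstats_mode(values: np.ndarray) -> float:
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _loo_score(X, y, C, standardize):
    # leave-one-out via the compiled dual-CD solver (same objective as
    # LinearSVC; equivalence asserted in the test suite) — the permutation
    # loop runs tens of thousands of these fits
    from ._svm_cd import decision_function, fit_linear_svm

    pred = np.zeros(len(y), bool)
    idx = np.arange(len(y))
    for i in idx:
        tr = idx != i
        X_tr, X_te = X[tr], X[i:i + 1]
        if standardize:
            X_tr, X_te = _standardize(X_tr, X_te)
        w = fit_linear_svm(X_tr, y[tr], C)
        pred[i] = decision_function(X_te, w)[0] > 0
    _, sens, spec = _confusion_metrics(y, pred)
    return balanced_accuracy(sens, spec)


def permutation_test(
    fm: FeatureMatrix, n_permutations: int = 999, seed: int = 0,
    C: float = 1.0, standardize: bool = True,
) -> float:
    """Label-permutation significance of the leave-one-out score.

    p = (1 + #{permuted >= observed}) / (1 + n_permutations), with both
    the observed and permuted balanced accuracies computed under the same
    leave-one-out scheme at fixed C.
    """
    if n_permutations < 100:
        raise InvariantError("use at least 100 permutations")
    y = fm.y
    if y.all() or not y.any():
        raise InvariantError("degenerate single-class labels")
    rng = np.random.default_rng(seed)
    observed = _loo_score(fm.X, y, C, standardize)
    count = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        if yp.all() or not yp.any():
            continue
        if _loo_score(fm.X, yp, C, standardize) >= observed:
            count += 1
    return (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# Subject eligibility
# ---------------------------------------------------------------------------

def subject_eligibility(
    behaviour_logs: dict[str, BehaviourLog], min_unperceived: int = 10,
) -> list[str]:
    """Subjects with at least ``min_unperceived`` unperceived trials."""
    eligible = []
    for subject, log in behaviour_logs.items():
        n_unp = int((~log.df["perceived"]).sum())
        if n_unp >= min_unperceived:
            eligible.append(subject)
    return eligible
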