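"""Compiled dual coordinate-descent solver for the linear SVM.

Solves the L2-regularized L1-loss support vector machine

    min_w  0.5 ||w||^2 + C sum_i max(0, 1 - y_i w . x_i)

by coordinate descent on the dual (the liblinear algorithm), with the
intercept absorbed as a constant augmented feature — the same formulation
as ``LinearSVC(dual=True, fit_intercept=True, intercept_scaling=1)``.

This exists purely for throughput: the permutation significance test runs
tens of thousands of leave-one-out fits on tiny problems, where the
per-call overhead of the general-purpose estimator dwarfs the solve
itself.  Agreement with the library solver is asserted in the test suite;
everything outside the permutation loop uses scikit-learn directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dual_cd(X, y, C, max_iter, tol):  # pragma: no cover - compiled
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    Qd = np.empty(n)
    for i in range(n):
        s = 0.0
        for k in range(d):
            s += X[i, k] * X[i, k]
        Qd[i] = s
    for _ in range(max_iter):
        max_viol = 0.0
        for i in range(n):
            g = 0.0
            for k in range(d):
                g += w[k] * X[i, k]
            g = y[i] * g - 1.0
            # projected gradient for the box constraint 0 <= alpha <= C
            if alpha[i] == 0.0:
                pg = min(g, 0.0)
            elif alpha[i] == C:
                pg = max(g, 0.0)
            else:
                pg = g
            if abs(pg) > max_viol:
                max_viol = abs(pg)
            if pg != 0.0 and Qd[i] > 0.0:
                a_old = alpha[i]
                a_new = a_old - g / Qd[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                alpha[i] = a_new
                delta = (a_new - a_old) * y[i]
                for k in range(d):
                    w[k] += delta * X[i, k]
        if max_viol < tol:
            break
    return w


def fit_linear_svm(
    X: np.ndarray, y_bool: np.ndarray, C: float,
    max_iter: int = 2000, tol: float = 1e-6,
) -> np.ndarray:
    """Weight vector (last entry = intercept) for boolean labels."""
    Xa = np.ascontiguousarray(
        np.hstack([X, np.ones((X.shape[0], 1))]), dtype=np.float64)
    y = np.where(y_bool, 1.0, -1.0)
    return _dual_cd(Xa, y, C, max_iter, tol)


def decision_function(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return X @ w[:-1] + w[-1]
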