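"""Condition contrasts per band and time point, with Holm correction.

Paired contexts default to the Wilcoxon signed-rank test, independent
contexts to the rank-sum test; a paired t-test covers the normal-theory
band contrasts.  Per-timepoint p-maps are Holm-corrected over time points
within each band; band-level contrasts over the four-band family.
Contiguous significant windows are extracted with a minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .containers import BehaviourLog, InvariantError

#: rotation rate of the stimulus: 180 degrees over the 9 s rotation span
ROTATION_DEG_PER_S = 180.0 / 9.0
ROTATION_SPAN_S = 9.0


@dataclass
class ContrastResult:
    band: str
    statistic_type: str
    statistic: np.ndarray        # per time point (or scalar array)
    p: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray      # corrected mask at alpha
    alpha: float
    times: np.ndarray | None = None
    windows: list[tuple[float, float]] = field(default_factory=list)
    summary: float | None = None


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def signed_rank_wplus(diffs: np.ndarray) -> float:
    """W+ statistic with tie-averaged ranks (zeros dropped)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = spstats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def _wilcoxon_z(diffs: np.ndarray) -> float:
    """Normal-approximation z for the signed-rank test, continuity-corrected."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    w = signed_rank_wplus(d)
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    if sigma == 0:
        return 0.0
    corr = 0.5 * np.sign(w - mu)
    return float((w - mu - corr) / sigma)


def _one_wilcoxon(a, b, paired):
    if paired:
        d = np.asarray(a, float) - np.asarray(b, float)
        if np.all(d == 0):
            return 0.0, 1.0
        n = np.count_nonzero(d)
        method = "exact" if n <= 25 else "approx"
        try:
            res = spstats.wilcoxon(d, method=method,
                                   correction=(method == "approx"))
            p = float(res.pvalue)
        except ValueError:
            p = 1.0
        return _wilcoxon_z(d), p
    res = spstats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def rank_sum(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum (z, p) for two independent samples."""
    return _one_wilcoxon(np.asarray(a, float), np.asarray(b, float),
                         paired=False)


def wilcoxon_map(
    cond_a: np.ndarray, cond_b: np.ndarray, paired: bool = True,
    band: str = "", times: np.ndarray | None = None, alpha: float = 0.05,
    min_duration: float = 0.0,
) -> ContrastResult:
    """Per-timepoint Wilcoxon contrast of two (n_times, n_obs) series.

    With ``paired=True`` a signed-rank test on per-observation differences
    (exact p for n <= 25, normal approximation beyond); otherwise a
    rank-sum test.  The z statistic carries a continuity correction.
    p-values are Holm-corrected over time points.
    """
    a = np.atleast_2d(np.asarray(cond_a, float))
    b = np.atleast_2d(np.asarray(cond_b, float))
    if paired and a.shape != b.shape:
        raise InvariantError("paired conditions must have equal shapes")
    if min(a.shape[-1], b.shape[-1]) < 5:
        raise InvariantError("need at least 5 observations per condition")
    if paired and np.all(a == b) and np.ptp(a) == 0:
        # constant, fully tied data carries no rank information at all;
        # identical-but-varying conditions simply yield z = 0, p = 1
        raise InvariantError("all-tied data: conditions are identical constants")
    n_t = a.shape[0]
    z = np.empty(n_t)
    p = np.empty(n_t)
    for t in range(n_t):
        z[t], p[t] = _one_wilcoxon(a[t], b[t], paired)
    mask, p_adj = holm_correct(p, alpha)
    res = ContrastResult(
        band=band, statistic_type="wilcoxon_signed_rank" if paired else "rank_sum",
        statistic=z, p=p, p_adjusted=p_adj, significant=mask, alpha=alpha,
        times=times,
    )
    if times is not None:
        res.windows = significant_windows(mask, times, min_duration)
    res.summary = float(np.mean(z))
    return res


def paired_t_band(
    cond_a: np.ndarray, cond_b: np.ndarray,
    band_names: list[str] | None = None, alpha: float = 0.05,
) -> list[ContrastResult]:
    """Paired t-tests per band on (n_subjects, n_bands) window summaries.

    Sign convention: t is computed on (cond_a − cond_b), so with cond_a =
    no-perception and cond_b = perception a negative t means perception
    exceeded no perception.  The Holm family is the set of bands.
    """
    a = np.atleast_2d(np.asarray(cond_a, float))
    b = np.atleast_2d(np.asarray(cond_b, float))
    if a.shape != b.shape:
        raise InvariantError("paired conditions must have equal shapes")
    if a.shape[0] < 3:
        raise InvariantError("paired t-test needs n >= 3")
    n_bands = a.shape[1]
    d = a - b
    zero_sd = d.std(axis=0) == 0
    all_zero = np.all(d == 0, axis=0)
    if np.any(zero_sd & ~all_zero):
        # constant nonzero differences: t is infinite, not estimable
        raise InvariantError("zero variance of paired differences")
    with np.errstate(invalid="ignore"):
        res = spstats.ttest_rel(a, b, axis=0)
    t, p = np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    # exactly identical conditions: no effect, by convention t = 0, p = 1
    t = np.where(all_zero, 0.0, t)
    p = np.where(all_zero, 1.0, p)
    mask, p_adj = holm_correct(p, alpha)
    names = band_names or [f"band{i}" for i in range(n_bands)]
    return [
        ContrastResult(
            band=names[i], statistic_type="paired_t",
            statistic=np.array([t[i]]), p=np.array([p[i]]),
            p_adjusted=np.array([p_adj[i]]),
            significant=np.array([mask[i]]), alpha=alpha,
            summary=float(t[i]),
        )
        for i in range(n_bands)
    ]


def holm_correct(pvals, alpha: float = 0.05):
    """Step-down Holm correction: (rejection mask, adjusted p)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise InvariantError("empty p-value set")
    if np.any((p < 0) | (p > 1)):
        raise InvariantError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="holm")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)


def significant_windows(
    mask, times, min_duration: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive significant time points, in seconds.

    A run of k points at spacing dt has duration k*dt; shorter runs than
    ``min_duration`` are discarded.  Endpoints are (first, last) sample
    times of the run.
    """
    mask = np.asarray(mask, bool)
    times = np.asarray(times, float)
    if mask.shape != times.shape:
        raise InvariantError("mask and times must align")
    if not mask.any():
        return []
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    out = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        n = stop - start
        if n * dt >= min_duration:
            out.append((float(times[start]), float(times[stop - 1])))
    return out


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def behaviour_summary(log: BehaviourLog) -> dict:
    """Hit rate (%) and detection-time mean ± SD over perceived trials."""
    df = log.df
    total = len(df)
    hit_rate = 100.0 * df["correct"].sum() / total if total else np.nan
    perc = df[df["perceived"] & df["response_time"].notna()]
    if len(perc):
        dt_mean = float(perc["response_time"].mean())
        dt_sd = float(perc["response_time"].std(ddof=1)) if len(perc) > 1 else 0.0
    else:
        dt_mean = dt_sd = None
    return {
        "n_trials": total,
        "hit_rate_pct": float(hit_rate),
        "detection_mean_s": dt_mean,
        "detection_sd_s": dt_sd,
        "mean_angle_deg": None if dt_mean is None else time_to_angle(dt_mean),
    }


def time_to_angle(t: float) -> float:
    """Degrees rotated from the inverted position after ``t`` seconds.

    The stimulus rotates 180° over the 9 s span (20°/s) and then holds
    upright, so the angle saturates at 180°.
    """
    if t < 0:
        raise InvariantError("detection time must be non-negative")
    return min(t, ROTATION_SPAN_S) * ROTATION_DEG_PER_S
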