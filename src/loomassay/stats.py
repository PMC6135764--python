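"""Assay-specific statistics: speed-binned freezing probability, the
exponential deceleration-onset fit with its randomization test, walking-speed
deltas, response-fraction timecourses and normalized histograms.

Deceleration fit
----------------
The mean peri-looming speed trace of a trial group is fitted with

    f(x) = a**(b*x - c) + d

whose parameter ``c`` locates the point of deceleration.  Written as
``exp(beta*x - gamma) + d`` with ``beta = b*ln(a)`` and ``gamma = c*ln(a)``,
the base ``a`` is a pure gauge: only ``beta``, ``gamma`` and ``d`` are
identifiable from data.  The fitter therefore estimates (beta, gamma, d) by
variable projection — for any beta the optimal (amplitude, offset) pair is a
linear least-squares solve, so the problem reduces to a 1-D search over beta
(coarse log grid, parabolic refinement, then a bounded scalar polish) — and
reports (b, c) in a caller-chosen base (default e).  This is deterministic
and fast enough to refit thousands of shuffled group means.

Randomization test
------------------
Group labels of the pooled trial traces are shuffled (default 5000 times),
both group means refitted per shuffle, and the two-sided statistic
``|c_A - c_B|`` compared with its null distribution using the add-one
estimator p = (1 + #{null >= observed}) / (1 + n_shuffles).

Standard hypothesis tests (rank-sum, chi-square, Kruskal-Wallis) are
delegated to scipy and only exposed as thin conveniences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.proportion import proportion_confint

from .ethogram import RESPONSES, BinnedActivity, Ethogram, TrialResponse

__all__ = [
    "FreezeBySpeed",
    "DecelFit",
    "RandomizationResult",
    "freeze_prob_by_speed",
    "fit_deceleration",
    "randomization_test_c",
    "walking_speed_delta",
    "response_fractions_timecourse",
    "pdf_hist",
    "rank_sum_test",
    "chi2_proportions",
    "kruskal_wallis",
]


# ---------------------------------------------------------------------------
# Freezing probability by pre-stimulus speed
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreezeBySpeed:
    """Per-speed-bin freezing probability with Wilson 95% CIs.

    Only occupied bins are kept; ``bin_low``/``bin_high`` give each kept
    bin's edges.
    """

    bin_low: np.ndarray
    bin_high: np.ndarray
    n_trials: np.ndarray
    n_freeze: np.ndarray
    p_freeze: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    speed_sd: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "speed_low": self.bin_low,
                "speed_high": self.bin_high,
                "n_trials": self.n_trials,
                "n_freeze": self.n_freeze,
                "p_freeze": self.p_freeze,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "speed_sd": self.speed_sd,
            }
        )


DEFAULT_SPEED_EDGES = np.arange(0.0, 26.0, 2.0)


def freeze_prob_by_speed(
    trials: list[TrialResponse] | pd.DataFrame,
    bin_edges=DEFAULT_SPEED_EDGES,
) -> FreezeBySpeed:
    """Probability of freezing after looming, by pre-stimulus speed bin.

    Trials are restricted to transition trials (pre-stimulus state not
    freezing); per bin, the fraction of freezing responses is reported with a
    two-sided 95% Wilson score interval and the standard deviation of the
    pre-stimulus speeds sampled in that bin.  Empty bins are omitted.
    """
    if isinstance(trials, pd.DataFrame):
        speeds = trials["pre_speed"].to_numpy(float)
        froze = trials["response"].to_numpy() == "freeze"
        pre_state = trials["pre_state"].to_numpy()
    else:
        speeds = np.array([t.pre_speed_mm_s for t in trials])
        froze = np.array([t.response == "freeze" for t in trials])
        pre_state = np.array([t.pre_state for t in trials])
    keep = pre_state != "freeze"
    speeds, froze = speeds[keep], froze[keep]
    edges = np.asarray(bin_edges, float)
    idx = np.digitize(speeds, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        k = int(froze[sel].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            (
                edges[b],
                edges[b + 1],
                n,
                k,
                k / n,
                lo,
                hi,
                float(np.std(speeds[sel], ddof=1)) if n > 1 else 0.0,
            )
        )
    if not rows:
        raise ValueError("no transition trials fall inside the speed bins")
    cols = list(zip(*rows))
    return FreezeBySpeed(*(np.asarray(c) for c in cols))


# ---------------------------------------------------------------------------
# Deceleration-onset fit (variable projection)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecelFit:
    """Result of the exponential deceleration fit a**(b*x - c) + d."""

    a: float
    b: float
    c: float
    d: float
    residual: float
    success: bool

    def predict(self, x):
        return self.a ** (self.b * np.asarray(x, float) - self.c) + self.d


def _linear_pair(e: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Best (A, d) for y ~ A*e + d with A >= 0; returns (A, d, rss)."""
    T = len(y)
    se, see = e.sum(), (e * e).sum()
    sy, sey = y.sum(), (e * y).sum()
    det = see * T - se * se
    if det <= 1e-300:
        d = sy / T
        return 0.0, d, float(((y - d) ** 2).sum())
    A = (sey * T - se * sy) / det
    if A <= 0:
        d = sy / T
        return 0.0, d, float(((y - d) ** 2).sum())
    d = (sy - A * se) / T
    rss = float(((y - A * e - d) ** 2).sum())
    return A, d, rss


def _beta_grid(x: np.ndarray, n: int = 25) -> np.ndarray:
    span = max(float(x.max() - x.min()), 1e-9)
    mags = np.geomspace(0.05 / span, 60.0 / span, n)
    return np.concatenate([-mags[::-1], [0.0], mags])


def _varpro_rss(beta: float, x: np.ndarray, y: np.ndarray) -> float:
    z = np.clip(beta * x, -500.0, 500.0)
    return _linear_pair(np.exp(z), y)[2]


def fit_deceleration(time, speed, base: float = math.e) -> DecelFit:
    """Fit f(x) = base**(b*x - c) + d to a mean speed trace.

    Deterministic: a coarse log-spaced grid over the exponential rate is
    refined parabolically and polished with a bounded scalar minimization;
    the amplitude and offset are profiled out analytically at every step.
    A constant trace is returned as the degenerate family member (b = 0,
    c = 0, d = trace - 1) with zero residual.  A fit that fails to produce
    finite parameters is flagged (``success=False``), never silent.
    """
    x = np.asarray(time, float)
    y = np.asarray(speed, float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 4:
        raise ValueError("need matching 1-D time/speed arrays of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("trace contains non-finite values")
    if base <= 0 or base == 1.0:
        raise ValueError("base must be positive and != 1")
    if float(np.ptp(y)) < 1e-12:
        return DecelFit(base, 0.0, 0.0, float(y.mean()) - 1.0, 0.0, True)

    x0 = float(x.mean())
    xc = x - x0
    grid = _beta_grid(xc)
    rss = np.array([_varpro_rss(b, xc, y) for b in grid])
    i = int(np.argmin(rss))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    if hi <= lo:
        lo, hi = lo - 1e-6, hi + 1e-6
    res = optimize.minimize_scalar(
        _varpro_rss, args=(xc, y), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    beta = float(res.x) if res.fun <= rss[i] else float(grid[i])
    A, d, final_rss = _linear_pair(np.exp(np.clip(beta * xc, -500, 500)), y)
    if A <= 0:  # degenerate: no positive exponential component found
        return DecelFit(
            base, 0.0, 0.0, float(y.mean()) - 1.0,
            math.sqrt(float(((y - y.mean()) ** 2).sum())), True
        )
    gamma = -math.log(A) + beta * x0  # undo centering
    ln_base = math.log(base)
    b = beta / ln_base
    c = gamma / ln_base
    ok = all(map(math.isfinite, (b, c, d))) and math.isfinite(final_rss)
    return DecelFit(base, b, c, d, math.sqrt(final_rss), ok)


def _fit_exp_batch(x: np.ndarray, Y: np.ndarray, grid: np.ndarray | None = None):
    """Vectorized variable-projection fit of many traces sharing one time axis.

    Returns (beta, gamma, d, rss) arrays, one entry per row of ``Y``.  Grid
    argmin plus one parabolic refinement step; identical procedure for every
    trace, which is what permutation-test validity requires.
    """
    x = np.asarray(x, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    x0 = float(x.mean())
    xc = x - x0
    if grid is None:
        grid = _beta_grid(xc)
    T = len(x)
    E = np.exp(np.clip(np.outer(grid, xc), -500, 500))  # (nb, T)
    se = E.sum(axis=1)
    see = (E * E).sum(axis=1)
    sy = Y.sum(axis=1)
    syy = (Y * Y).sum(axis=1)
    sey = E @ Y.T  # (nb, m)
    det = see * T - se * se
    det = np.where(det <= 1e-300, np.inf, det)
    A = (sey * T - se[:, None] * sy[None, :]) / det[:, None]
    A = np.maximum(A, 0.0)
    d = (sy[None, :] - A * se[:, None]) / T
    rss = (
        syy[None, :]
        - 2 * A * sey
        - 2 * d * sy[None, :]
        + A * A * see[:, None]
        + 2 * A * d * se[:, None]
        + d * d * T
    )
    best = np.argmin(rss, axis=0)
    m = Y.shape[0]
    cols = np.arange(m)

    # parabolic refinement on the grid neighborhood
    i0 = np.clip(best - 1, 0, len(grid) - 1)
    i2 = np.clip(best + 1, 0, len(grid) - 1)
    b0, b1, b2 = grid[i0], grid[best], grid[i2]
    f0, f1, f2 = rss[i0, cols], rss[best, cols], rss[i2, cols]
    denom = (b1 - b0) * (f1 - f2) - (b1 - b2) * (f1 - f0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = b1 - 0.5 * (
            (b1 - b0) ** 2 * (f1 - f2) - (b1 - b2) ** 2 * (f1 - f0)
        ) / denom
    beta = np.where(np.isfinite(beta) & (beta > b0) & (beta < b2), beta, b1)

    # exact linear solve at the refined beta
    Eb = np.exp(np.clip(beta[:, None] * xc[None, :], -500, 500))
    se_b = Eb.sum(axis=1)
    see_b = (Eb * Eb).sum(axis=1)
    sey_b = (Eb * Y).sum(axis=1)
    det_b = see_b * T - se_b * se_b
    det_b = np.where(det_b <= 1e-300, np.inf, det_b)
    A_b = np.maximum((sey_b * T - se_b * sy) / det_b, 1e-300)
    d_b = (sy - A_b * se_b) / T
    rss_b = (
        syy - 2 * A_b * sey_b - 2 * d_b * sy + A_b * A_b * see_b
        + 2 * A_b * d_b * se_b + d_b * d_b * T
    )
    worse = rss_b > f1
    beta = np.where(worse, b1, beta)
    # recompute at fallback points
    if np.any(worse):
        Ef = np.exp(np.clip(beta[worse, None] * xc[None, :], -500, 500))
        se_f = Ef.sum(axis=1)
        see_f = (Ef * Ef).sum(axis=1)
        sey_f = (Ef * Y[worse]).sum(axis=1)
        det_f = np.where(see_f * T - se_f * se_f <= 1e-300, np.inf,
                         see_f * T - se_f * se_f)
        A_f = np.maximum((sey_f * T - se_f * sy[worse]) / det_f, 1e-300)
        d_f = (sy[worse] - A_f * se_f) / T
        A_b[worse], d_b[worse] = A_f, d_f
        rss_b[worse] = (
            syy[worse] - 2 * A_f * sey_f - 2 * d_f * sy[worse]
            + A_f * A_f * see_f + 2 * A_f * d_f * se_f + d_f * d_f * T
        )
    gamma = -np.log(A_b) + beta * x0
    return beta, gamma, d_b, np.maximum(rss_b, 0.0)


@dataclass(frozen=True)
class RandomizationResult:
    p_value: float
    observed: float
    c_a: float
    c_b: float
    n_shuffles: int
    null_quantiles: tuple[float, float, float]  # 50/95/99th of the null


def randomization_test_c(
    trials_a,
    trials_b,
    time,
    n_shuffles: int = 5000,
    seed: int | None = None,
    base: float = math.e,
    max_failure_frac: float = 0.05,
) -> RandomizationResult:
    """Randomization test on the deceleration parameter ``c``.

    ``trials_a``/``trials_b`` are (n_trials, n_time) speed-trace arrays on a
    shared ``time`` axis.  The observed statistic is ``|c_A - c_B|`` from
    fits to each group's mean trace; the null is built by shuffling the
    trial group labels and refitting both means per shuffle.  The result is
    invariant to which group is passed first (the groups are ordered
    canonically before pooling) and reproducible under a fixed seed.
    """
    a = np.atleast_2d(np.asarray(trials_a, float))
    b = np.atleast_2d(np.asarray(trials_b, float))
    x = np.asarray(time, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both trial groups must be non-empty")
    if a.shape[1] != len(x) or b.shape[1] != len(x):
        raise ValueError("trial traces must match the time axis")
    # canonical group order -> label-order invariance
    key_a = (a.shape[0], a.tobytes())
    key_b = (b.shape[0], b.tobytes())
    if key_b < key_a:
        a, b = b, a
    na = a.shape[0]
    pool = np.vstack([a, b])
    ln_base = math.log(base)

    _, g_obs, _, _ = _fit_exp_batch(x, np.vstack([a.mean(0), b.mean(0)]))
    c_a, c_b = g_obs / ln_base
    observed = abs(c_a - c_b)

    rng = np.random.default_rng(seed)
    n_tot = pool.shape[0]
    perms = np.argsort(rng.random((n_shuffles, n_tot)), axis=1)
    means_a = pool[perms[:, :na]].mean(axis=1)
    means_b = pool[perms[:, na:]].mean(axis=1)
    _, ga, _, ra = _fit_exp_batch(x, means_a)
    _, gb, _, rb = _fit_exp_batch(x, means_b)
    finite = np.isfinite(ga) & np.isfinite(gb) & np.isfinite(ra) & np.isfinite(rb)
    if (~finite).mean() > max_failure_frac:
        raise RuntimeError(
            f"deceleration fit failed in {(~finite).mean():.1%} of shuffles"
        )
    null = np.abs(ga[finite] - gb[finite]) / ln_base
    p = (1 + int(np.sum(null >= observed - 1e-12))) / (1 + len(null))
    q = tuple(float(v) for v in np.percentile(null, [50, 95, 99])) if len(null) else (
        math.nan,
    ) * 3
    return RandomizationResult(p, float(observed), float(c_a), float(c_b),
                               int(len(null)), q)


# ---------------------------------------------------------------------------
# Walking-speed deltas, response fractions, normalized histograms
# ---------------------------------------------------------------------------


def walking_speed_delta(
    ethogram: Ethogram,
    binned: BinnedActivity,
    baseline_window: tuple[float, float],
    stim_window: tuple[float, float],
) -> float | None:
    """Stimulation-minus-baseline change in walking speed.

    Mean speed over walking-labeled bins in the stimulation window minus the
    same in the baseline window.  Returns None (fly excluded) when either
    window contains no walking bins.
    """

    def _mean_walk(t0: float, t1: float) -> float | None:
        sel = (
            (ethogram.bin_start_s >= t0 - 1e-9)
            & (ethogram.bin_start_s < t1 - 1e-9)
            & (ethogram.labels == "walk")
        )
        return float(binned.speed_mm_s[sel].mean()) if sel.any() else None

    base = _mean_walk(*baseline_window)
    stim = _mean_walk(*stim_window)
    if base is None or stim is None:
        return None
    return stim - base


def response_fractions_timecourse(
    trials: list[TrialResponse] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-looming-index fractions of each response over the cohort.

    Rows are looming indices, columns the response labels; each row sums
    to 1 (every trial carries exactly one label).
    """
    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame(
            {
                "looming_idx": [t.looming_index for t in trials],
                "response": [t.response for t in trials],
            }
        )
    counts = (
        trials.groupby("looming_idx")["response"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(RESPONSES), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def pdf_hist(values, bin_edges) -> np.ndarray:
    """Histogram normalized to a probability density.

    Returns counts / (N * bin_width) so the integral over the binned range
    is exactly 1.  Raises when no value falls inside the range.
    """
    values = np.asarray(values, float)
    edges = np.asarray(bin_edges, float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if not np.isfinite(edges).all():
        raise ValueError("bin edges must be finite")
    counts, _ = np.histogram(values, bins=edges)
    if counts.sum() == 0:
        raise ValueError("all values fall outside the histogram range")
    widths = np.diff(edges)
    return counts / (counts.sum() * widths)


# ---------------------------------------------------------------------------
# Delegated standard tests (thin conveniences over scipy)
# ---------------------------------------------------------------------------


def rank_sum_test(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    return sps.mannwhitneyu(x, y, alternative="two-sided")


def chi2_proportions(successes, totals):
    """Chi-square test on success counts across groups."""
    successes = np.asarray(successes)
    totals = np.asarray(totals)
    table = np.column_stack([successes, totals - successes])
    return sps.chi2_contingency(table)


def kruskal_wallis(*groups):
    return sps.kruskal(*groups)
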