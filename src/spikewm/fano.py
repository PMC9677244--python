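"""Mean-matched Fano factors and cluster-based permutation comparisons.

The Fano factor (FF) — the across-trial variance-to-mean ratio of spike
counts — confounds rate with variability: higher rates mechanically shift
the (mean, variance) cloud.  The mean-matched procedure removes the
confound by (1) collecting, per unit x condition x 500-ms sliding window,
the across-trial mean and variance of spike counts; (2) extracting the
greatest common distribution of mean counts across windows (histogram bin
0.5); (3) per window, randomly discarding points until its mean-count
histogram matches the common one; (4) regressing variance on mean with a
zero intercept, each point weighted by 1/(0.01 + SE of the variance).  The
slope is the FF; the random matching is repeated (50 times by default) and
the mean with a 95% CI reported.

FF time courses are compared with a cluster-based nonparametric
permutation test on the repeat distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from spikewm.core import Session
from spikewm.irregularity import lvr_gated, window_right_edges

MEAN_BIN = 0.5


def _spike_counts(
    session: Session, window_s: float, step_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_units, n_trials, n_windows) count array and the window right edges."""
    edges = window_right_edges(window_s, step_s)
    counts = np.zeros((len(session.units), len(session.trials), edges.size), dtype=float)
    for i, uid in enumerate(session.unit_ids):
        for j, trial in enumerate(session.trials):
            t = session.spike_times(uid, trial.trial_id)
            if t.size:
                counts[i, j] = (
                    (t[None, :] >= (edges - window_s)[:, None]) & (t[None, :] < edges[:, None])
                ).sum(axis=1)
    return counts, edges


def window_counts(
    session: Session,
    window_s: float = 0.5,
    step_s: float = 0.05,
    conditions: Mapping[str, Sequence[int]] | None = None,
    rng: np.random.Generator | None = None,
    balance_trials: bool = False,
) -> pd.DataFrame:
    """Across-trial mean/variance of windowed spike counts per unit x condition.

    ``conditions`` maps a condition name to the trial ids it contains
    (default: the three set sizes).  With ``balance_trials`` the larger
    condition is undersampled to the smaller one, independently per
    unit x window.  Conditions with fewer than 2 trials are omitted.

    Returns a tidy frame with columns unit_id, condition, time, mean, var,
    n, se_var.
    """
    if conditions is None:
        conditions = {
            str(ss): [t.trial_id for t in session.trials if t.set_size == ss]
            for ss in (4, 6, 8)
        }
    counts, edges = _spike_counts(session, window_s, step_s)
    trial_pos = {t.trial_id: j for j, t in enumerate(session.trials)}
    n_min = min((len(v) for v in conditions.values() if len(v) >= 2), default=0)
    rng = np.random.default_rng() if rng is None else rng

    rows = []
    for cond, trial_ids in conditions.items():
        idx = np.array([trial_pos[t] for t in trial_ids], dtype=int)
        if idx.size < 2:
            continue
        for i, uid in enumerate(session.unit_ids):
            for w, time in enumerate(edges):
                use = idx
                if balance_trials and idx.size > n_min:
                    use = rng.choice(idx, size=n_min, replace=False)
                c = counts[i, use, w]
                n = c.size
                var = float(np.var(c, ddof=1))
                rows.append(
                    (
                        uid,
                        cond,
                        float(time),
                        float(c.mean()),
                        var,
                        n,
                        var * np.sqrt(2.0 / (n - 1)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["unit_id", "condition", "time", "mean", "var", "n", "se_var"]
    )


def greatest_common_distribution(
    points: pd.DataFrame, bin_width: float = MEAN_BIN, by: Sequence[str] = ("time",)
) -> np.ndarray:
    """Per-bin minimum, over windows, of the mean-spike-count histogram."""
    if points.empty:
        raise ValueError("no points")
    n_bins = int(np.floor(points["mean"].max() / bin_width)) + 1
    target = None
    for _, grp in points.groupby(list(by)):
        hist = np.bincount(
            np.floor(grp["mean"].to_numpy() / bin_width).astype(int), minlength=n_bins
        )[:n_bins]
        target = hist if target is None else np.minimum(target, hist)
    return target


def _weighted_zero_intercept_slope(means, variances, se_var) -> float:
    w = 1.0 / (0.01 + np.asarray(se_var, dtype=float))
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    denom = np.sum(w * m * m)
    if denom == 0:
        return float("nan")
    return float(np.sum(w * m * v) / denom)


@dataclass
class FFSeries:
    """Mean-matched FF per window: mean, 95% CI, and the per-repeat values."""

    times: np.ndarray
    ff: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    repeats: np.ndarray  # (n_repeats, n_windows)


def mean_matched_ff(
    points: pd.DataFrame,
    target_hist: np.ndarray | None = None,
    n_repeats: int = 50,
    rng: np.random.Generator | None = None,
    bin_width: float = MEAN_BIN,
) -> FFSeries:
    """Mean-matched FF time course.

    Per window and repeat, points are randomly discarded until the window's
    mean-count histogram equals the target (the greatest common
    distribution by default), then the FF is the weighted zero-intercept
    slope of variance on mean.
    """
    rng = np.random.default_rng() if rng is None else rng
    if target_hist is None:
        target_hist = greatest_common_distribution(points, bin_width)
    target_hist = np.asarray(target_hist, dtype=int)
    times = np.sort(points["time"].unique())
    reps = np.full((n_repeats, times.size), np.nan)
    by_time = dict(tuple(points.groupby("time")))
    for w, time in enumerate(times):
        grp = by_time[time]
        bins = np.floor(grp["mean"].to_numpy() / bin_width).astype(int)
        m = grp["mean"].to_numpy()
        v = grp["var"].to_numpy()
        se = grp["se_var"].to_numpy()
        members = [np.flatnonzero(bins == b) for b in range(target_hist.size)]
        for b, (mem, want) in enumerate(zip(members, target_hist)):
            if mem.size < want:
                raise ValueError(
                    f"window at t={time:g}s cannot match the target histogram "
                    f"(bin {b}: has {mem.size}, needs {want})"
                )
        for rep in range(n_repeats):
            take = [
                mem if mem.size == want else rng.choice(mem, size=want, replace=False)
                for mem, want in zip(members, target_hist)
            ]
            sel = np.concatenate([t for t in take if t.size]) if any(
                t.size for t in take
            ) else np.empty(0, dtype=int)
            if sel.size == 0:
                continue
            reps[rep, w] = _weighted_zero_intercept_slope(m[sel], v[sel], se[sel])
    any_finite = np.isfinite(reps).any(axis=0)
    ff = np.full(times.size, np.nan)
    ci_low = np.full(times.size, np.nan)
    ci_high = np.full(times.size, np.nan)
    if any_finite.any():
        ff[any_finite] = np.nanmean(reps[:, any_finite], axis=0)
        ci_low[any_finite] = np.nanpercentile(reps[:, any_finite], 2.5, axis=0)
        ci_high[any_finite] = np.nanpercentile(reps[:, any_finite], 97.5, axis=0)
    return FFSeries(times=times, ff=ff, ci_low=ci_low, ci_high=ci_high, repeats=reps)


def condition_balanced_ff(
    session: Session,
    condition_split: Mapping[str, Sequence[int]],
    window_s: float = 0.5,
    step_s: float = 0.05,
    n_repeats: int = 50,
    rng: np.random.Generator | None = None,
) -> dict[str, FFSeries]:
    """Mean-matched FF per condition with per-unit x window trial balancing.

    The two conditions (e.g. set size 4 vs 6-8) are equalized in trial
    count by undersampling the larger one, with a different undersampling
    per unit and window; a common target histogram over both conditions
    keeps the FFs comparable.
    """
    if len(condition_split) != 2:
        raise ValueError("exactly 2 conditions required")
    for name, ids in condition_split.items():
        if len(ids) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 trials")
    rng = np.random.default_rng() if rng is None else rng
    points = window_counts(
        session, window_s, step_s, conditions=dict(condition_split), rng=rng,
        balance_trials=True,
    )
    # common target: min over every condition x window histogram, so the
    # two FF series rest on the same mean-count distribution
    target = greatest_common_distribution(points, by=("condition", "time"))
    out = {}
    for name in condition_split:
        sub = points[points.condition == name]
        out[name] = mean_matched_ff(sub, target[: _n_bins(sub)], n_repeats=n_repeats, rng=rng)
    return out


def _n_bins(points: pd.DataFrame, bin_width: float = MEAN_BIN) -> int:
    return int(np.floor(points["mean"].max() / bin_width)) + 1


@dataclass
class ClusterTestResult:
    clusters: list[tuple[int, int]]   # [start, end) window index ranges
    masses: list[float]
    p_values: list[float]
    t_stats: np.ndarray


def cluster_permutation_test(
    repeats_a: np.ndarray,
    repeats_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Cluster-based nonparametric comparison of two windowed repeat sets.

    Window-wise two-sample t statistics are thresholded at ``alpha``
    (two-sided); maximal contiguous same-sign supra-threshold runs are
    scored by their summed t (cluster mass) and compared with the null
    distribution of maximal |mass| under random exchanges of the repeat
    rows between the two series.
    """
    a = np.asarray(repeats_a, dtype=float)
    b = np.asarray(repeats_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("series must cover the same windows")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng() if rng is None else rng

    def tstats(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return stats.ttest_ind(x, y, axis=0).statistic

    def clusters_of(t: np.ndarray, crit: float) -> list[tuple[int, int, float]]:
        out = []
        i = 0
        while i < t.size:
            if np.isfinite(t[i]) and abs(t[i]) > crit:
                sign = np.sign(t[i])
                j = i
                while (
                    j + 1 < t.size
                    and np.isfinite(t[j + 1])
                    and abs(t[j + 1]) > crit
                    and np.sign(t[j + 1]) == sign
                ):
                    j += 1
                out.append((i, j + 1, float(t[i : j + 1].sum())))
                i = j + 1
            else:
                i += 1
        return out

    df = a.shape[0] + b.shape[0] - 2
    crit = stats.t.ppf(1 - alpha / 2, df)
    t_obs = tstats(a, b)
    obs_clusters = clusters_of(t_obs, crit)

    pooled = np.vstack([a, b])
    n_a = a.shape[0]
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        t_null = tstats(pooled[idx[:n_a]], pooled[idx[n_a:]])
        cl = clusters_of(t_null, crit)
        null_max[k] = max((abs(m) for _, _, m in cl), default=0.0)

    clusters, masses, ps = [], [], []
    for start, end, mass in obs_clusters:
        clusters.append((start, end))
        masses.append(mass)
        ps.append(float((1 + np.sum(null_max >= abs(mass))) / (n_perm + 1)))
    return ClusterTestResult(clusters=clusters, masses=masses, p_values=ps, t_stats=t_obs)


def ff_by_lvr_quartile(
    session: Session,
    per_unit_mean_lvr: Mapping[str, float] | None = None,
    window_s: float = 0.5,
    step_s: float = 0.05,
    n_repeats: int = 50,
    rng: np.random.Generator | None = None,
) -> dict[int, dict]:
    """Mean-matched FF within unit quartiles of mean LvR, with period summaries.

    Units are split into 4 quartiles by their across-trial mean LvR
    (ascending; quartile 4 = burstiest); the FF pipeline runs within each
    quartile and per-period FF averages are attached.
    """
    if len(session.units) < 8:
        raise ValueError("need at least 8 units to form quartiles")
    rng = np.random.default_rng() if rng is None else rng
    if per_unit_mean_lvr is None:
        per_unit_mean_lvr = {}
        for uid in session.unit_ids:
            vals = [
                lvr_gated(session.spike_times(uid, t.trial_id))
                for t in session.trials
            ]
            vals = [v for v in vals if np.isfinite(v)]
            per_unit_mean_lvr[uid] = float(np.mean(vals)) if vals else float("nan")

    order = sorted(session.unit_ids, key=lambda u: (per_unit_mean_lvr.get(u, np.inf), u))
    quartiles = np.array_split(order, 4)
    periods = {"fixation": (0.0, 1.0), "encoding": (1.0, 3.0), "maintenance": (3.0, 6.0), "probe": (6.0, 8.0)}
    out: dict[int, dict] = {}
    for q, uids in enumerate(quartiles, start=1):
        sub = session.subset_units(list(uids))
        points = window_counts(sub, window_s, step_s, rng=rng)
        series = mean_matched_ff(points, n_repeats=n_repeats, rng=rng)
        summary = {}
        for name, (lo, hi) in periods.items():
            mask = (series.times > lo) & (series.times <= hi)
            summary[name] = float(np.nanmean(series.ff[mask])) if mask.any() else float("nan")
        out[q] = {
            "unit_ids": list(uids),
            "series": series,
            "period_mean_ff": summary,
            "mean_lvr": float(
                np.nanmean([per_unit_mean_lvr.get(u, np.nan) for u in uids])
            ),
        }
    return out
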