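"""Spiking irregularity: LvR, change points, and relations to trial variables.

The central statistic is the refractoriness-corrected local variation of
consecutive inter-spike intervals (ISIs),

    LvR = 3/(n-1) * sum_i (1 - 4 I_i I_{i+1} / (I_i + I_{i+1})^2)
                        * (1 + 4 R / (I_i + I_{i+1})),

where ``I_i`` are the n ISIs and ``R`` is a refractoriness constant
(5 ms for single units, 0 for combined trains).  LvR is ~1 for Poisson
firing, below 1 for regular firing and above 1 for bursty firing; being a
ratio of neighbouring intervals it is insensitive to slow rate changes.

A second family of tools detects rate change points inside single trials
by comparing the empirical cumulative spike count with the uniform one,
with a per-unit significance threshold adapted until the fixation period
is free of change points.  Finally, time-resolved permutation tests relate
windowed LvR values to trial variables (response time, workload,
correctness) while preserving the trial structure: simultaneously recorded
units always receive the same permuted trial variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from spikewm.core import FIXATION, TRIAL_DURATION_S, Session, bh_adjust

DEFAULT_R_S = 0.005
DEFAULT_MIN_SPIKES = 5
LOGIT_SCHEDULE = tuple(np.round(np.arange(1.3, 5.9 + 1e-9, 0.2), 10))


def lvr(isi_sequence, R_s: float = 0.0) -> float:
    """Refractoriness-corrected local variation of an ISI sequence.

    Returns 0 for perfectly regular trains; requires at least 2 intervals.
    """
    I = np.asarray(isi_sequence, dtype=float)
    if I.size < 2:
        raise ValueError("need at least 2 inter-spike intervals")
    if np.any(I <= 0):
        raise ValueError("all inter-spike intervals must be positive")
    a, b = I[:-1], I[1:]
    s = a + b
    terms = (1.0 - 4.0 * a * b / s**2) * (1.0 + 4.0 * R_s / s)
    return float(3.0 / (I.size - 1) * terms.sum())


def lvr_gated(
    spike_times,
    R_s: float = DEFAULT_R_S,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> float:
    """LvR of a spike train, or NaN when it has fewer than ``min_spikes`` spikes."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < min_spikes:
        return float("nan")
    isis = np.diff(t)
    if np.any(isis == 0):  # duplicates upstream; collapse defensively
        t = np.unique(t)
        if t.size < min_spikes:
            return float("nan")
        isis = np.diff(t)
    return lvr(isis, R_s)


def combine_trains(trains: Sequence[np.ndarray]) -> np.ndarray:
    """Sorted union of simultaneously recorded trains; duplicates collapsed."""
    parts = [np.asarray(t, dtype=float) for t in trains if np.asarray(t).size]
    if not parts:
        return np.empty(0)
    return np.unique(np.concatenate(parts))


@dataclass
class WindowedSeries:
    """Per-window statistic time series; the time index is the window's right edge."""

    times: np.ndarray
    values: np.ndarray
    window_s: float
    step_s: float
    kind: str = "LvR"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def window_right_edges(
    window_s: float, step_s: float, t_start: float = 0.0, t_end: float = TRIAL_DURATION_S
) -> np.ndarray:
    """Right edges of right-aligned sliding windows inside [t_start, t_end]."""
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    n = int(np.floor((t_end - t_start - window_s) / step_s + 1e-9)) + 1
    return t_start + window_s + step_s * np.arange(max(n, 0))


def sliding_lvr(
    spike_times,
    window_s: float = 2.0,
    step_s: float = 0.05,
    R_s: float = DEFAULT_R_S,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    t_start: float = 0.0,
    t_end: float = TRIAL_DURATION_S,
) -> WindowedSeries:
    """LvR in right-aligned sliding windows; gate failures are NaN."""
    t = np.asarray(spike_times, dtype=float)
    edges = window_right_edges(window_s, step_s, t_start, t_end)
    values = np.full(edges.size, np.nan)
    for i, right in enumerate(edges):
        sel = t[(t >= right - window_s) & (t < right)]
        values[i] = lvr_gated(sel, R_s, min_spikes)
    return WindowedSeries(edges, values, window_s, step_s, kind="LvR")


# ---------------------------------------------------------------------------
# Change points
# ---------------------------------------------------------------------------


@dataclass
class CPResult:
    """Change points detected in one window, with the logit threshold used."""

    times: list[float]
    logit: float


def _logit_to_p(logit: float) -> float:
    # logit = log10((1-P)/P): 1.3 -> P ~ 0.05, 5.9 -> P ~ 1e-6
    return 1.0 / (1.0 + 10.0**logit)


def _detect_cps(t: np.ndarray, t0: float, t1: float, p_threshold: float) -> list[float]:
    """Sequential cumulative-record change-point search on spikes in [t0, t1).

    Spikes are processed in order.  At each new spike the empirical
    cumulative count over the current segment is compared with the uniform
    expectation (the straight line from the segment origin to the current
    spike); the earliest spike of maximal absolute deviation is the
    candidate, accepted when a two-sided binomial test on the before/after
    counts (success probability = fraction of the segment before the
    candidate) falls below ``p_threshold``.  On acceptance the origin
    moves to the change point and the scan continues on the remaining
    spikes.
    """
    sel = t[(t >= t0) & (t < t1)]
    n = sel.size
    if n < 2 or t1 <= t0:
        return []
    cps: list[float] = []
    start = t0
    i0 = 0  # index of the first spike after the current origin
    r = 1
    while r < n:
        seg = sel[i0 : r + 1]
        span = seg[-1] - start
        if span <= 0:
            r += 1
            continue
        m = seg.size
        frac = (seg[:-1] - start) / span
        counts = np.arange(1, m)
        # deviation just before and just after each count jump
        dev = np.maximum(np.abs(counts - m * frac), np.abs(counts - 1 - m * frac))
        k = int(np.argmax(dev))  # earliest maximum
        candidate = float(seg[k])
        p_before = (candidate - start) / span
        if (
            0.0 < p_before < 1.0
            and stats.binomtest(k + 1, m, p_before).pvalue < p_threshold
        ):
            cps.append(candidate)
            start = candidate
            i0 = i0 + k + 1
            r = i0 + 1
        else:
            r += 1
    return cps


def change_points(
    spike_times,
    window: tuple[float, float] = (0.0, TRIAL_DURATION_S),
    logit: float = LOGIT_SCHEDULE[0],
) -> CPResult:
    """Change-point detection at a fixed logit threshold.

    The empirical cumulative spike count is compared with the uniform
    expectation of a perfectly regular train; the earliest maximally
    deviating spike is accepted as a change point when a two-sided
    binomial test on the before/after counts is significant at the P
    implied by the logit (P = 1/(1 + 10**logit)), after which the search
    restarts from the change point.
    """
    t = np.asarray(spike_times, dtype=float)
    times = _detect_cps(t, window[0], window[1], _logit_to_p(logit))
    return CPResult(times=times, logit=logit)


def adapt_logit(
    fixation_trains: Iterable[np.ndarray],
    schedule: Sequence[float] = LOGIT_SCHEDULE,
    fixation_window: tuple[float, float] = FIXATION,
) -> float:
    """Raise the logit along the schedule until no fixation change points remain.

    The adaptation pools all of a unit's fixation windows: the first logit at
    which every fixation train is free of change points is returned (the
    schedule's last value if none succeeds).
    """
    trains = [np.asarray(t, dtype=float) for t in fixation_trains]
    for logit in schedule:
        p = _logit_to_p(logit)
        if all(not _detect_cps(t, *fixation_window, p) for t in trains):
            return float(logit)
    return float(schedule[-1])


def unit_change_points(
    session: Session,
    unit_id: str,
    window: tuple[float, float] = (0.0, TRIAL_DURATION_S),
    schedule: Sequence[float] = LOGIT_SCHEDULE,
) -> dict[int, CPResult]:
    """Per-trial change points for one unit at its fixation-adapted logit."""
    fixation_trains = [
        session.spike_times(unit_id, tr.trial_id) for tr in session.trials
    ]
    logit = adapt_logit(fixation_trains, schedule)
    return {
        tr.trial_id: change_points(
            session.spike_times(unit_id, tr.trial_id), window, logit
        )
        for tr in session.trials
    }


def cp_lvr_correlation(
    sessions: Sequence[Session],
    R_s: float = DEFAULT_R_S,
    schedule: Sequence[float] = LOGIT_SCHEDULE,
) -> dict[str, dict[str, float]]:
    """Per-region Pearson correlation between per-unit mean CP count and mean LvR."""
    per_region: dict[str, list[tuple[float, float]]] = {}
    for session in sessions:
        for unit in session.units:
            cps = unit_change_points(session, unit.unit_id, schedule=schedule)
            mean_cp = float(np.mean([len(r.times) for r in cps.values()]))
            lvrs = [
                lvr_gated(session.spike_times(unit.unit_id, tr.trial_id), R_s)
                for tr in session.trials
            ]
            lvrs = [v for v in lvrs if np.isfinite(v)]
            if lvrs:
                per_region.setdefault(unit.region, []).append(
                    (mean_cp, float(np.mean(lvrs)))
                )
    out: dict[str, dict[str, float]] = {}
    for region, pairs in per_region.items():
        if len(pairs) < 3:
            out[region] = {"r": float("nan"), "p": float("nan"), "n": len(pairs)}
            continue
        x, y = np.array(pairs).T
        r, p = stats.pearsonr(x, y)
        out[region] = {"r": float(r), "p": float(p), "n": len(pairs)}
    return out


# ---------------------------------------------------------------------------
# Rank dissimilarity and permutation inference
# ---------------------------------------------------------------------------


def rank_dissimilarity(values, class_labels, class_a) -> float:
    """Signed area between class-wise rank-CDFs.

    Pooled values are rank-transformed ascending (ties receive average
    ranks); each class's empirical CDF is evaluated at every integer rank
    1..N and the statistic is the sum over ranks of ``F_A - F_B`` with A
    the designated class (high workload, or wrong responses).  Positive
    values mean class A concentrates at low ranks (low values).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(class_labels)
    mask_a = lab == class_a
    if mask_a.all() or not mask_a.any():
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(v, method="average")
    grid = np.arange(1, v.size + 1)
    f_a = (ranks[mask_a][:, None] <= grid).mean(axis=0)
    f_b = (ranks[~mask_a][:, None] <= grid).mean(axis=0)
    return float(np.sum(f_a - f_b))


def permutation_null(
    statistic_fn: Callable[[list[np.ndarray]], float],
    trial_vars_by_session: Sequence[np.ndarray],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Trial-structure-preserving permutation test.

    ``statistic_fn`` maps a list of per-session trial-variable vectors to a
    scalar.  Each permutation shuffles the variable vector *within* each
    session, so simultaneously recorded units keep receiving identical
    trial variables.  Returns (observed, two-sided p, null distribution)
    with the +1 smoothing convention.
    """
    rng = np.random.default_rng() if rng is None else rng
    vars_ = [np.asarray(v) for v in trial_vars_by_session]
    observed = float(statistic_fn(vars_))
    null = np.empty(n_perm)
    for k in range(n_perm):
        permuted = [v[rng.permutation(v.size)] for v in vars_]
        null[k] = statistic_fn(permuted)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return observed, float(p), null


def subsampled_combination_test(
    point_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    single_counts: Sequence[int],
    statistic_fn: Callable[[np.ndarray, list[np.ndarray]], float],
    trial_vars_by_session: Sequence[np.ndarray],
    n_subsamples: int = 100,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Median permutation p over random subsamples of combined-unit points.

    ``point_sets[s]`` holds, for session ``s``, the combined-LvR values and
    the trial index of each point; each subsample draws (without
    replacement, within session) as many points as the single-unit
    calculation used, evaluates ``statistic_fn(subsampled values by
    session, trial variables by session)`` and its permutation p-value.
    Returns (median p, all p-values).
    """
    rng = np.random.default_rng() if rng is None else rng
    if not any(v.size for v, _ in point_sets):
        raise ValueError("no combined points available")
    p_values = np.empty(n_subsamples)
    for rep in range(n_subsamples):
        chosen: list[tuple[np.ndarray, np.ndarray]] = []
        for (values, trial_idx), n_single in zip(point_sets, single_counts):
            n_take = min(int(n_single), values.size)
            sel = rng.choice(values.size, size=n_take, replace=False)
            chosen.append((values[sel], trial_idx[sel]))

        def stat(perm_vars: list[np.ndarray]) -> float:
            pooled_v, pooled_x = [], []
            for (values, trial_idx), var in zip(chosen, perm_vars):
                pooled_v.append(values)
                pooled_x.append(var[trial_idx])
            return statistic_fn(
                np.concatenate(pooled_v), np.concatenate(pooled_x)
            )

        _, p, _ = permutation_null(
            lambda pv: stat(pv), trial_vars_by_session, n_perm=n_perm, rng=rng
        )
        p_values[rep] = p
    return float(np.median(p_values)), p_values


def pearson_statistic(values: np.ndarray, trial_vars: np.ndarray) -> float:
    """Pearson r over pairwise-complete points; NaN when degenerate."""
    mask = np.isfinite(values) & np.isfinite(trial_vars)
    if mask.sum() < 3:
        return float("nan")
    v, x = values[mask], trial_vars[mask]
    if np.std(v) == 0 or np.std(x) == 0:
        return float("nan")
    return float(stats.pearsonr(v, x)[0])


def _session_unit_groups(session: Session, combo_order: int) -> list[tuple[str, ...]]:
    from itertools import combinations

    return list(combinations(session.unit_ids, combo_order))


def _windowed_points(
    session: Session,
    groups: Sequence[tuple[str, ...]],
    window_s: float,
    step_s: float,
    R_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_windows x n_points) LvR matrix with trial indices, per unit group."""
    edges = window_right_edges(window_s, step_s)
    values, trial_idx = [], []
    for gi, group in enumerate(groups):
        for ti, trial in enumerate(session.trials):
            train = combine_trains(
                [session.spike_times(uid, trial.trial_id) for uid in group]
            )
            series = sliding_lvr(train, window_s, step_s, R_s)
            values.append(series.values)
            trial_idx.append(ti)
    if not values:
        return edges, np.empty((edges.size, 0)), np.empty(0, dtype=int)
    return edges, np.array(values).T, np.asarray(trial_idx)


def timeresolved_rt_correlation(
    sessions: Sequence[Session],
    window_s: float = 2.0,
    step_s: float = 0.25,
    combo_order: int = 1,
    n_perm: int = 1000,
    n_subsamples: int = 100,
    drop_slow_responses: bool = True,
    rng: np.random.Generator | None = None,
    by_region: bool = True,
):
    """Sliding-window Pearson correlation between LvR and response time.

    Points are pooled over units and trials (window-wise); significance
    comes from trial-structure-preserving permutations, with BH adjustment
    across regions per window.  Combined orders (2, 3) use R = 0 and the
    subsampled-combination contract (median p over ``n_subsamples`` draws
    matched to the single-unit point count).

    Returns a dict region -> dict with keys times, r, p, p_adj.
    """
    rng = np.random.default_rng() if rng is None else rng
    R_s = DEFAULT_R_S if combo_order == 1 else 0.0
    regions = sorted({u.region for s in sessions for u in s.units})
    if not by_region:
        regions = ["all"]

    # trial variables (RTs) per session, optionally masking slow responses
    rts: list[np.ndarray] = []
    for session in sessions:
        rt = np.array([t.response_time for t in session.trials], dtype=float)
        if drop_slow_responses:
            rt = np.where(rt > 2.0, np.nan, rt)
        rts.append(rt)

    edges = window_right_edges(window_s, step_s)
    results: dict[str, dict] = {}
    for region in regions:
        mats, trial_idxs, singles = [], [], []
        for s_i, session in enumerate(sessions):
            uids = [
                u.unit_id
                for u in session.units
                if by_region is False or u.region == region
            ]
            sub = session.subset_units(uids)
            groups = _session_unit_groups(sub, combo_order)
            _, mat, tidx = _windowed_points(sub, groups, window_s, step_s, R_s)
            mats.append(mat)
            trial_idxs.append(tidx)
            singles.append(len(uids) * len(session.trials))

        r_obs = np.full(edges.size, np.nan)
        p_raw = np.full(edges.size, np.nan)
        for w in range(edges.size):
            point_sets = [
                (mats[s][w], trial_idxs[s]) for s in range(len(sessions))
            ]
            if combo_order == 1:

                def stat(perm_vars: list[np.ndarray]) -> float:
                    pooled_v = np.concatenate([ps[0] for ps in point_sets])
                    pooled_x = np.concatenate(
                        [var[ps[1]] for ps, var in zip(point_sets, perm_vars)]
                    )
                    return pearson_statistic(pooled_v, pooled_x)

                obs, p, _ = permutation_null(stat, rts, n_perm=n_perm, rng=rng)
                r_obs[w], p_raw[w] = obs, p
            else:
                try:
                    p, _ = subsampled_combination_test(
                        point_sets,
                        singles,
                        pearson_statistic,
                        rts,
                        n_subsamples=n_subsamples,
                        n_perm=n_perm,
                        rng=rng,
                    )
                except ValueError:
                    p = float("nan")
                pooled_v = np.concatenate([ps[0] for ps in point_sets])
                pooled_x = np.concatenate(
                    [rt[ps[1]] for ps, rt in zip(point_sets, rts)]
                )
                r_obs[w] = pearson_statistic(pooled_v, pooled_x)
                p_raw[w] = p
            if not np.isfinite(r_obs[w]):
                p_raw[w] = np.nan
        results[region] = {"times": edges, "r": r_obs, "p": p_raw}

    # BH across regions, per window
    p_adj = {region: np.full(edges.size, np.nan) for region in regions}
    for w in range(edges.size):
        ps = np.array([results[r]["p"][w] for r in regions])
        ok = np.isfinite(ps)
        if ok.any():
            adj = bh_adjust(ps[ok])
            k = 0
            for i, region in enumerate(regions):
                if ok[i]:
                    p_adj[region][w] = adj[k]
                    k += 1
    for region in regions:
        results[region]["p_adj"] = p_adj[region]
    return results


def partial_correlation_lvr_rt(lvr_values, response_times, firing_rates) -> float:
    """First-order partial Pearson correlation of LvR and RT given firing rate."""
    x = np.asarray(lvr_values, dtype=float)
    y = np.asarray(response_times, dtype=float)
    z = np.asarray(firing_rates, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[mask], y[mask], z[mask]
    if x.size < 4:
        raise ValueError("need at least 4 complete (LvR, RT, rate) triples")
    if min(np.std(x), np.std(y), np.std(z)) == 0:
        return float("nan")
    r_xy = stats.pearsonr(x, y)[0]
    r_xz = stats.pearsonr(x, z)[0]
    r_yz = stats.pearsonr(y, z)[0]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / denom)
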