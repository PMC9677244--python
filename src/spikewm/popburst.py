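"""Population bursts: detection, composition, sparsity, and density.

A population burst is a period of at least 100 ms during which the
unit-averaged smoothed firing rate exceeds a data-derived threshold
(mean + 3 sd of the per-trial unit-averaged whole-window rates).  Each
event carries a unit-composition vector ``w`` (per-unit mean smoothed
rate inside the burst), a sparsity index

    sparsity(w) = 1 - (sqrt(n) - sum_i |w_hat_i|) / (sqrt(n) - 1),

with ``w_hat`` the composition scaled to unit Euclidean length (0 when a
single unit dominates, 1 when all units contribute equally), a
composition-weighted LvR, and a trial-period assignment (the period
containing at least 80% of the event, the probe period's right edge being
the response time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from spikewm.core import TRIAL_DURATION_S, Session, Trial
from spikewm.irregularity import lvr_gated

RATE_STEP_S = 0.010
RATE_BANDWIDTH_S = 0.025


@dataclass
class PopulationRateSeries:
    """Smoothed per-unit rates (Hz) on a 10-ms grid, plus their unit average."""

    times: np.ndarray          # grid sample points, [0, 8] inclusive
    unit_rates: np.ndarray     # (n_units, n_bins)
    unit_ids: list[str]

    @property
    def population(self) -> np.ndarray:
        return self.unit_rates.mean(axis=0)


@dataclass
class BurstEvent:
    start: float
    end: float
    peak_rate: float
    trial_id: int | None = None
    composition: np.ndarray | None = None
    sparsity: float | None = None
    weighted_lvr: float | None = None
    period: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


def instantaneous_rates(
    session: Session,
    trial_id: int,
    bandwidth_s: float = RATE_BANDWIDTH_S,
    step_s: float = RATE_STEP_S,
    t_end: float = TRIAL_DURATION_S,
) -> PopulationRateSeries:
    """Gaussian-kernel rate estimates for every unit in one trial.

    The kernel is truncated at the trial edges without renormalization
    (naive convolution), which depresses the estimate within ~2 bandwidths
    of 0 and 8 s.
    """
    if not session.units:
        raise ValueError("session has no units")
    grid = np.arange(0.0, t_end + step_s / 2, step_s)
    rates = np.zeros((len(session.units), grid.size))
    norm = 1.0 / (bandwidth_s * np.sqrt(2 * np.pi))
    for i, unit in enumerate(session.units):
        t = session.spike_times(unit.unit_id, trial_id)
        if t.size:
            d = grid[None, :] - t[:, None]
            rates[i] = norm * np.exp(-0.5 * (d / bandwidth_s) ** 2).sum(axis=0)
    return PopulationRateSeries(times=grid, unit_rates=rates, unit_ids=list(session.unit_ids))


def burst_threshold(session: Session) -> float:
    """Population-rate threshold: mean + 3 sd of per-trial unit-averaged rates.

    Per trial, single-unit rates are averaged over the whole 8-s window and
    then across units; the sample mean and sd (n-1 denominator) across
    trials define the threshold.
    """
    if len(session.trials) < 2:
        raise ValueError("need at least 2 trials to estimate the burst threshold")
    per_trial = []
    for trial in session.trials:
        unit_rates = [
            session.spike_times(uid, trial.trial_id).size / TRIAL_DURATION_S
            for uid in session.unit_ids
        ]
        per_trial.append(float(np.mean(unit_rates)) if unit_rates else 0.0)
    per_trial = np.asarray(per_trial)
    return float(per_trial.mean() + 3.0 * per_trial.std(ddof=1))


def detect_bursts(
    rate_series: PopulationRateSeries,
    threshold: float,
    min_duration_s: float = 0.1,
    proximity_s: float = 0.15,
) -> list[BurstEvent]:
    """Maximal supra-threshold runs of the population rate, pruned for proximity.

    Runs shorter than ``min_duration_s`` are dropped; among consecutive
    events closer than ``proximity_s`` (tail to head) the one with the
    lower peak rate is discarded, re-checking left to right after each
    removal.
    """
    pop = rate_series.population
    t = rate_series.times
    step = t[1] - t[0] if t.size > 1 else RATE_STEP_S
    above = pop > threshold
    events: list[BurstEvent] = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            start, end = t[i], t[j] + step
            if end - start >= min_duration_s - 1e-12:
                events.append(
                    BurstEvent(
                        start=float(start),
                        end=float(end),
                        peak_rate=float(pop[i : j + 1].max()),
                    )
                )
            i = j + 1
        else:
            i += 1

    k = 0
    while k < len(events) - 1:
        gap = events[k + 1].start - events[k].end
        if gap < proximity_s:
            victim = k if events[k].peak_rate < events[k + 1].peak_rate else k + 1
            del events[victim]
            k = max(k - 1, 0)
        else:
            k += 1
    return events


def assign_period(event: BurstEvent, trial: Trial, min_fraction: float = 0.8) -> str | None:
    """Assign an event to the period holding >= 80% of its duration, else None."""
    if event.duration <= 0:
        return None
    for name, (lo, hi) in trial.periods().items():
        overlap = max(0.0, min(event.end, hi) - max(event.start, lo))
        if overlap / event.duration >= min_fraction - 1e-12:
            return name
    return None


def burst_composition(
    event: BurstEvent, rate_series: PopulationRateSeries
) -> np.ndarray:
    """Per-unit mean smoothed rate within [start, end)."""
    mask = (rate_series.times >= event.start) & (rate_series.times < event.end)
    if not mask.any():
        raise ValueError("event shorter than one grid step")
    return rate_series.unit_rates[:, mask].mean(axis=1)


def sparsity(w) -> float:
    """Composition sparsity in [0, 1]: 0 for one-hot, 1 for uniform weights."""
    w = np.asarray(w, dtype=float)
    n = w.size
    if n < 2:
        raise ValueError("need at least 2 units")
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("composition must not be all zero")
    w_hat = w / norm
    return float(1.0 - (np.sqrt(n) - np.abs(w_hat).sum()) / (np.sqrt(n) - 1.0))


def burst_weighted_lvr(per_unit_lvr, w) -> float:
    """Composition-weighted mean of single-unit LvR values.

    Units with missing (NaN) LvR are dropped and the weights renormalized;
    NaN when every weighted unit lacks an LvR.
    """
    lv = np.asarray(per_unit_lvr, dtype=float)
    w = np.asarray(w, dtype=float)
    ok = np.isfinite(lv) & (w > 0)
    if not ok.any() or w[ok].sum() == 0:
        return float("nan")
    return float(np.sum(w[ok] * lv[ok]) / w[ok].sum())


def annotate_events(
    session: Session,
    trial: Trial,
    events: Sequence[BurstEvent],
    rate_series: PopulationRateSeries,
    R_s: float = 0.005,
) -> list[BurstEvent]:
    """Fill composition, sparsity, weighted LvR and period for detected events."""
    per_unit_lvr = np.array(
        [lvr_gated(session.spike_times(uid, trial.trial_id), R_s) for uid in rate_series.unit_ids]
    )
    for ev in events:
        ev.trial_id = trial.trial_id
        w = burst_composition(ev, rate_series)
        ev.composition = w
        ev.sparsity = sparsity(w) if w.size >= 2 and np.linalg.norm(w) > 0 else None
        ev.weighted_lvr = burst_weighted_lvr(per_unit_lvr, w)
        ev.period = assign_period(ev, trial)
    return list(events)


def session_bursts(
    session: Session,
    threshold: float | None = None,
    min_duration_s: float = 0.1,
    proximity_s: float = 0.15,
    annotate: bool = True,
) -> dict[int, list[BurstEvent]]:
    """Detect (and optionally annotate) bursts for every trial of a session."""
    if threshold is None:
        threshold = burst_threshold(session)
    out: dict[int, list[BurstEvent]] = {}
    for trial in session.trials:
        series = instantaneous_rates(session, trial.trial_id)
        events = detect_bursts(series, threshold, min_duration_s, proximity_s)
        if annotate:
            events = annotate_events(session, trial, events, series)
        out[trial.trial_id] = events
    return out


@dataclass
class BurstDensity:
    """Fraction of trials with an ongoing burst, per 10-ms bin, with 95% CI."""

    times: np.ndarray
    density: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_trials: int


def burst_density(
    events_by_trial: Mapping[int, Sequence[BurstEvent]],
    trials: Sequence[Trial],
    align: str = "trial_start",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    step_s: float = RATE_STEP_S,
) -> BurstDensity:
    """Per-bin fraction of trials with an ongoing burst, with a trial bootstrap.

    ``align='response'`` re-references times to the response (probe onset +
    response time) and discards trials with response times above 2 s, whose
    pre-response recording is truncated.
    """
    if align not in ("trial_start", "response"):
        raise ValueError("align must be 'trial_start' or 'response'")
    rng = np.random.default_rng() if rng is None else rng

    if align == "trial_start":
        grid = np.arange(0.0, TRIAL_DURATION_S + step_s / 2, step_s)
        kept = list(trials)
        offsets = {t.trial_id: 0.0 for t in kept}
    else:
        grid = np.arange(-4.0, 1.0 + step_s / 2, step_s)
        kept = [t for t in trials if t.response_time <= 2.0]
        offsets = {t.trial_id: -(6.0 + t.response_time) for t in kept}

    n_trials = len(kept)
    occupancy = np.zeros((max(n_trials, 1), grid.size), dtype=bool)
    for i, trial in enumerate(kept):
        for ev in events_by_trial.get(trial.trial_id, ()):
            lo = ev.start + offsets[trial.trial_id]
            hi = ev.end + offsets[trial.trial_id]
            occupancy[i] |= (grid >= lo) & (grid < hi)
    if n_trials == 0:
        z = np.zeros(grid.size)
        return BurstDensity(grid, z, z.copy(), z.copy(), 0)

    density = occupancy[:n_trials].mean(axis=0)
    boots = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, n_trials, size=n_trials)
        boots[b] = occupancy[idx].mean(axis=0)
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    return BurstDensity(grid, density, ci_low, ci_high, n_trials)
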