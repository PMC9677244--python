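"""Synthetic cohorts of Sternberg-task sessions.

The generator produces sessions with the statistical structure the
analyses assume: units with heterogeneous rates and irregularity regimes
(gamma-renewal inter-spike intervals whose shape parameter spans regular,
Poisson-like and bursty firing), 8-s trials with the fixed
fixation/encoding/maintenance/probe geometry, and injectable effects —
a set-size rate gain in a coding subpopulation, probe-locked population
bursts in amygdala/entorhinal units, and a trial-level latent that couples
burstiness to response time.

For a gamma renewal process with shape ``k`` the expected local variation
of consecutive inter-spike intervals is ``3 / (2k + 1)``: shape 1 gives a
Poisson process (Lv ≈ 1), larger shapes regular firing (Lv < 1), smaller
shapes bursty firing (Lv > 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from spikewm.core import (
    PROBE_ONSET_S,
    REGIONS,
    TRIAL_DURATION_S,
    Session,
    Trial,
    Unit,
    write_session,
)


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Effect sizes default to "off" or to moderate values representative of
    single-unit medial-temporal-lobe recordings: base rates 2–15 Hz,
    gamma shapes 0.4–3.0 (LvR roughly 0.5–1.8), a 1.3× workload gain in a
    quarter of the units, and a 3× probe-locked gain for amygdala and
    entorhinal units in the 0.5 s after probe onset.
    """

    n_sessions: int = 3
    units_per_region: int = 8
    n_trials: int = 50
    base_rate_hz_range: tuple[float, float] = (2.0, 15.0)
    gamma_shape_range: tuple[float, float] = (0.4, 3.0)
    setsize_gain: float = 1.3
    setsize_gain_fraction: float = 0.25
    probe_burst_gain: float = 3.0
    probe_burst_window_s: float = 0.5
    rt_lvr_coupling: float = 0.0
    wrong_rate: float = 0.1
    rt_lognorm_mu: float = 0.0  # log-seconds; median RT ~ 1 s
    rt_lognorm_sigma: float = 0.35
    rt_bounds_s: tuple[float, float] = (0.3, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setsize_gain < 0 or self.probe_burst_gain < 0:
            raise ValueError("gains must be >= 0")
        if not (0 <= self.wrong_rate <= 1):
            raise ValueError("wrong_rate must lie in [0, 1]")
        if not (0 <= self.setsize_gain_fraction <= 1):
            raise ValueError("setsize_gain_fraction must lie in [0, 1]")
        if min(self.gamma_shape_range) <= 0:
            raise ValueError("gamma shapes must be positive")


def gamma_renewal_train(
    rate_hz: float, shape: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Equilibrium-stationary gamma-renewal spike train on [0, duration].

    Inter-spike intervals are i.i.d. Gamma(shape, scale=1/(shape*rate)) so
    the mean interval is 1/rate.  The first spike time is drawn from the
    forward-recurrence-time distribution (a uniform position inside a
    length-biased interval, i.e. Gamma(shape + 1)), which makes every
    window statistic stationary rather than start-synchronized.
    """
    if rate_hz <= 0 or shape <= 0:
        raise ValueError("rate_hz and shape must be positive")
    scale = 1.0 / (shape * rate_hz)
    first = rng.uniform() * rng.gamma(shape + 1.0, scale)
    if first >= duration_s:
        return np.empty(0)
    # draw ISIs in blocks until the train overshoots the duration
    times = [first]
    t = first
    while t < duration_s:
        isis = rng.gamma(shape, scale, size=max(16, int(rate_hz * duration_s)))
        for isi in isis:
            t += isi
            if t >= duration_s:
                break
            times.append(t)
    return np.asarray(times)


@dataclass(frozen=True)
class RateProfile:
    """Piecewise-constant firing-rate function over [0, 8] s."""

    edges: np.ndarray  # K+1 breakpoints, edges[0] = 0, edges[-1] = duration
    rates: np.ndarray  # K non-negative rates (Hz)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if edges.size != rates.size + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be increasing with len(rates)+1 entries")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "rates", rates)

    @classmethod
    def constant(cls, rate_hz: float, duration_s: float = TRIAL_DURATION_S):
        return cls(edges=np.array([0.0, duration_s]), rates=np.array([rate_hz]))

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """Integrated rate Λ(t) = ∫₀ᵗ r(s) ds."""
        cum = np.concatenate([[0.0], np.cumsum(self.rates * np.diff(self.edges))])
        return np.interp(t, self.edges, cum)

    def total_mass(self) -> float:
        return float(np.sum(self.rates * np.diff(self.edges)))

    def inverse_cumulative(self, u: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(self.rates * np.diff(self.edges))])
        return np.interp(u, cum, self.edges)

    def scaled(self, factor: float, window: tuple[float, float] | None = None):
        """Multiply the rate by ``factor``, optionally only inside ``window``."""
        if window is None:
            return RateProfile(self.edges, self.rates * factor)
        lo, hi = window
        edges = np.unique(np.concatenate([self.edges, [lo, hi]]))
        edges = edges[(edges >= self.edges[0]) & (edges <= self.edges[-1])]
        mids = 0.5 * (edges[:-1] + edges[1:])
        base = self.rates[np.searchsorted(self.edges, mids, side="right") - 1]
        gain = np.where((mids >= lo) & (mids < hi), factor, 1.0)
        return RateProfile(edges, base * gain)


def inhomogeneous_train(
    profile: RateProfile, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous gamma-renewal train via time rescaling.

    A unit-rate equilibrium gamma renewal process is generated on the
    rescaled axis [0, Λ(T)] and mapped back through Λ⁻¹, so the expected
    count in any window equals the rate integral over that window.
    """
    mass = profile.total_mass()
    if mass <= 0:
        return np.empty(0)
    rescaled = gamma_renewal_train(1.0, shape, mass, rng)
    return profile.inverse_cumulative(rescaled)


def _draw_trials(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[Trial], np.ndarray]:
    """Trial sequence with the set-size rule: forced to 4 after a wrong trial."""
    trials = []
    prev_wrong = False
    z = rng.standard_normal(config.n_trials)  # trial-level latent, shared by units
    lo, hi = config.rt_bounds_s
    for i in range(config.n_trials):
        set_size = 4 if prev_wrong else int(rng.choice([4, 6, 8]))
        correct = bool(rng.uniform() >= config.wrong_rate)
        rt = float(
            np.clip(
                rng.lognormal(config.rt_lognorm_mu, config.rt_lognorm_sigma), lo, hi
            )
        )
        rt = float(np.clip(rt * np.exp(config.rt_lvr_coupling * z[i]), lo, hi))
        trials.append(
            Trial(trial_id=i, set_size=set_size, correct=correct, response_time=rt)
        )
        prev_wrong = not correct
    return trials, z


def synth_session(
    config: GeneratorConfig, rng: np.random.Generator, session_index: int = 0
) -> tuple[Session, dict]:
    """Generate one session plus its ground-truth record.

    Ground truth holds per-unit base rate, gamma shape and coding-group
    membership, and the per-trial latent ``z``; these drive
    parameter-recovery tests downstream.
    """
    session_id = f"synth{session_index:02d}"
    subject_id = f"subj{session_index:02d}"
    trials, z = _draw_trials(config, rng)

    units, truth_units = [], {}
    for region in REGIONS:
        for j in range(config.units_per_region):
            uid = f"{region[:3]}{j:02d}"
            rate = float(rng.uniform(*config.base_rate_hz_range))
            shape = float(rng.uniform(*config.gamma_shape_range))
            coding = bool(rng.uniform() < config.setsize_gain_fraction)
            units.append(Unit(unit_id=uid, region=region, session_id=session_id))
            truth_units[uid] = {
                "region": region,
                "base_rate_hz": rate,
                "gamma_shape": shape,
                "coding": coding,
            }

    spikes: dict[tuple[str, int], np.ndarray] = {}
    for unit in units:
        info = truth_units[unit.unit_id]
        for trial, z_t in zip(trials, z):
            profile = RateProfile.constant(info["base_rate_hz"])
            if info["coding"] and trial.set_size in (6, 8):
                profile = profile.scaled(config.setsize_gain)
            if unit.region in ("amygdala", "entorhinal") and config.probe_burst_gain != 1:
                profile = profile.scaled(
                    config.probe_burst_gain,
                    (PROBE_ONSET_S, PROBE_ONSET_S + config.probe_burst_window_s),
                )
            # the latent scales burstiness: high z lowers the shape (burstier)
            shape_t = info["gamma_shape"] * float(
                np.exp(-config.rt_lvr_coupling * z_t)
            )
            train = inhomogeneous_train(profile, shape_t, rng)
            spikes[(unit.unit_id, trial.trial_id)] = train

    session = Session(
        session_id=session_id,
        subject_id=subject_id,
        units=units,
        trials=trials,
        spikes=spikes,
    )
    truth = {
        "session_id": session_id,
        "units": truth_units,
        "trial_latents": [float(v) for v in z],
    }
    return session, truth


def synth_cohort(
    config: GeneratorConfig, out_dir=None
) -> tuple[list[Session], dict]:
    """Generate ``config.n_sessions`` sessions and a ground-truth record.

    When ``out_dir`` is given, each session is written to
    ``out_dir/<session_id>/`` and the ground truth to ``out_dir/truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    sessions, truths = [], []
    for i in range(config.n_sessions):
        session, truth = synth_session(config, rng, session_index=i)
        sessions.append(session)
        truths.append(truth)
    record = {"config": dataclasses.asdict(config), "sessions": truths}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for session in sessions:
            write_session(session, out / session.session_id)
        with open(out / "truth.json", "w") as fh:
            json.dump(record, fh, indent=1)
    return sessions, record
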