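"""Session data model, file I/O, unit-quality filters and shared statistics.

A *session* is the universal input of every analysis: a set of units (each
tagged with an anatomical region of the medial temporal lobe) recorded over
a sequence of 8-s Sternberg-task trials.  Trial time is expressed in
seconds relative to trial start; all intervals are half-open ``[start,
end)``.  The trial geometry is fixed: 1 s fixation, 2 s encoding, 3 s
maintenance, then probe presentation until the response (the recording
truncates at 8 s, so responses slower than 2 s are partially missing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REGIONS = ("hippocampus", "amygdala", "entorhinal")

TRIAL_DURATION_S = 8.0
FIXATION = (0.0, 1.0)
ENCODING = (1.0, 3.0)
MAINTENANCE = (3.0, 6.0)
PROBE_ONSET_S = 6.0

PERIOD_NAMES = ("fixation", "encoding", "maintenance", "probe")


class FormatError(ValueError):
    """A session file is malformed (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """Session contents violate an invariant (bounds, labels, references)."""


@dataclass(frozen=True)
class Unit:
    unit_id: str
    region: str
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )


@dataclass(frozen=True)
class Trial:
    """One Sternberg trial: fixed 8-s recording with a variable response time.

    ``response_time`` is measured in seconds from probe onset (6 s into the
    trial).  The probe period is ``[6, min(6 + response_time, 8))``.
    """

    trial_id: int
    set_size: int
    correct: bool
    response_time: float
    duration: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.set_size not in (4, 6, 8):
            raise ValidationError(f"set_size must be 4, 6 or 8, got {self.set_size}")
        if not self.response_time > 0:
            raise ValidationError("response_time must be > 0")

    @property
    def probe_end(self) -> float:
        return min(PROBE_ONSET_S + self.response_time, self.duration)

    def periods(self) -> dict[str, tuple[float, float]]:
        """Half-open period intervals for this trial."""
        return {
            "fixation": FIXATION,
            "encoding": ENCODING,
            "maintenance": MAINTENANCE,
            "probe": (PROBE_ONSET_S, self.probe_end),
        }


@dataclass
class Session:
    """Units × trials spike-time container.

    ``spikes`` maps ``(unit_id, trial_id)`` to a sorted array of spike times
    in seconds relative to trial start.  Missing keys mean no spikes.
    """

    session_id: str
    subject_id: str
    units: list[Unit]
    trials: list[Trial]
    spikes: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unit_ids = [u.unit_id for u in self.units]
        if len(set(unit_ids)) != len(unit_ids):
            raise ValidationError("duplicate unit_id within session")
        trial_ids = {t.trial_id for t in self.trials}
        uid_set = set(unit_ids)
        clean: dict[tuple[str, int], np.ndarray] = {}
        for (uid, tid), times in self.spikes.items():
            if uid not in uid_set:
                raise ValidationError(f"spikes reference undeclared unit {uid!r}")
            if tid not in trial_ids:
                raise ValidationError(f"spikes reference undeclared trial {tid}")
            arr = np.asarray(times, dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > TRIAL_DURATION_S):
                raise ValidationError(
                    f"spike time outside [0, {TRIAL_DURATION_S}] for unit {uid!r}"
                )
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                raise ValidationError(f"spike times not sorted for unit {uid!r}")
            clean[(uid, tid)] = arr
        self.spikes = clean

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    @property
    def trial_ids(self) -> list[int]:
        return [t.trial_id for t in self.trials]

    def spike_times(self, unit_id: str, trial_id: int) -> np.ndarray:
        return self.spikes.get((unit_id, trial_id), np.empty(0))

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def mean_rate(self, unit_id: str) -> float:
        """Pooled firing rate: total spikes / total recorded time (Hz)."""
        total_time = TRIAL_DURATION_S * len(self.trials)
        if total_time == 0:
            return 0.0
        n = sum(self.spike_times(unit_id, t.trial_id).size for t in self.trials)
        return n / total_time

    def subset_units(self, keep: Iterable[str]) -> "Session":
        keep = set(keep)
        return Session(
            session_id=self.session_id,
            subject_id=self.subject_id,
            units=[u for u in self.units if u.unit_id in keep],
            trials=list(self.trials),
            spikes={k: v for k, v in self.spikes.items() if k[0] in keep},
        )

    def total_spikes(self) -> int:
        return int(sum(v.size for v in self.spikes.values()))


# ---------------------------------------------------------------------------
# I/O: spikes.csv + trials.csv + session.json
# ---------------------------------------------------------------------------

_SPIKE_COLS = ["unit_id", "region", "trial_id", "spike_time_s"]
_TRIAL_COLS = ["trial_id", "set_size", "correct", "response_time_s"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file is missing column(s): {', '.join(missing)}")


def read_session(spikes_path, trials_path, meta_path) -> Session:
    """Read a session from ``spikes.csv``, ``trials.csv`` and ``session.json``."""
    with open(meta_path) as fh:
        meta = json.load(fh)
    spikes_df = pd.read_csv(spikes_path, dtype={"unit_id": str})
    trials_df = pd.read_csv(trials_path)
    _require_columns(spikes_df, _SPIKE_COLS, "spikes")
    _require_columns(trials_df, _TRIAL_COLS, "trials")

    bad = spikes_df[
        (spikes_df.spike_time_s < 0) | (spikes_df.spike_time_s > TRIAL_DURATION_S)
    ]
    if len(bad):
        raise ValidationError(
            f"{len(bad)} spike row(s) with spike_time_s outside [0, {TRIAL_DURATION_S}]"
        )

    trials = [
        Trial(
            trial_id=int(r.trial_id),
            set_size=int(r.set_size),
            correct=bool(r.correct),
            response_time=float(r.response_time_s),
        )
        for r in trials_df.itertuples()
    ]

    units: list[Unit] = []
    seen: set[str] = set()
    for uid, region in zip(spikes_df.unit_id, spikes_df.region):
        if uid not in seen:
            seen.add(uid)
            units.append(Unit(unit_id=uid, region=region, session_id=meta["session_id"]))

    spikes: dict[tuple[str, int], np.ndarray] = {}
    for (uid, tid), grp in spikes_df.groupby(["unit_id", "trial_id"], sort=True):
        spikes[(str(uid), int(tid))] = np.sort(grp.spike_time_s.to_numpy(dtype=float))

    return Session(
        session_id=meta["session_id"],
        subject_id=meta["subject_id"],
        units=units,
        trials=trials,
        spikes=spikes,
    )


def write_session(session: Session, dir_path) -> dict[str, Path]:
    """Write a session to ``dir_path``; returns the paths written."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    region = {u.unit_id: u.region for u in session.units}
    for uid in session.unit_ids:
        for trial in session.trials:
            for t in session.spike_times(uid, trial.trial_id):
                rows.append((uid, region[uid], trial.trial_id, t))
    spikes_df = pd.DataFrame(rows, columns=_SPIKE_COLS)
    trials_df = pd.DataFrame(
        [
            (t.trial_id, t.set_size, t.correct, t.response_time)
            for t in session.trials
        ],
        columns=_TRIAL_COLS,
    )
    paths = {
        "spikes": out / "spikes.csv",
        "trials": out / "trials.csv",
        "meta": out / "session.json",
    }
    spikes_df.to_csv(paths["spikes"], index=False, float_format="%.6f")
    trials_df.to_csv(paths["trials"], index=False)
    with open(paths["meta"], "w") as fh:
        json.dump(
            {"session_id": session.session_id, "subject_id": session.subject_id}, fh
        )
    return paths


# ---------------------------------------------------------------------------
# Unit-quality filters
# ---------------------------------------------------------------------------


def filter_units_by_rate(session: Session, min_rate_hz: float = 1.0) -> Session:
    """Keep units with pooled firing rate strictly above ``min_rate_hz``.

    The rate pools spike counts over the total recorded time across trials
    (counts / (n_trials * 8 s)) rather than averaging per-trial rates; with
    fixed-length trials the two conventions coincide.
    """
    keep = [uid for uid in session.unit_ids if session.mean_rate(uid) > min_rate_hz]
    return session.subset_units(keep)


def binarize(spike_times, bin_width_s: float, t_start: float, t_end: float) -> np.ndarray:
    """Binary occupancy sequence: bin i covers [t_start + i*w, t_start + (i+1)*w)."""
    if t_end <= t_start:
        raise ValueError("t_end must be greater than t_start")
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    n_bins = int(np.ceil((t_end - t_start) / bin_width_s))
    out = np.zeros(n_bins, dtype=np.int8)
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= t_start) & (t < t_end)]
    if t.size:
        idx = np.floor((t - t_start) / bin_width_s).astype(int)
        out[idx[idx < n_bins]] = 1
    return out


def jaccard(binary_a, binary_b) -> float:
    """Intersection-over-union of two equal-length binary sequences.

    Defined as 0 when both sequences are all-zero.
    """
    a = np.asarray(binary_a, dtype=bool)
    b = np.asarray(binary_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def crosstalk_filter(
    session: Session, bin_width_s: float = 0.001, threshold: float = 0.3
) -> tuple[Session, list[str]]:
    """Remove electrode cross-talk duplicates via pairwise Jaccard screening.

    All session trials are concatenated, spike trains binarized at 1 ms, and
    pairwise Jaccard similarities computed.  While any pair exceeds the
    threshold, the unit participating in the most supra-threshold pairs is
    removed (ties: lower pooled firing rate, then unit_id order).
    """
    uids = list(session.unit_ids)
    if len(uids) < 2:
        return session, []

    n_bins_per_trial = int(round(TRIAL_DURATION_S / bin_width_s))
    trains = {}
    for uid in uids:
        parts = [
            binarize(
                session.spike_times(uid, t.trial_id), bin_width_s, 0.0, TRIAL_DURATION_S
            )[:n_bins_per_trial]
            for t in session.trials
        ]
        trains[uid] = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)

    rates = {uid: session.mean_rate(uid) for uid in uids}
    removed: list[str] = []
    active = list(uids)
    sim = {
        (a, b): jaccard(trains[a], trains[b])
        for i, a in enumerate(uids)
        for b in uids[i + 1 :]
    }
    while True:
        counts = {uid: 0 for uid in active}
        any_bad = False
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                if sim[(a, b)] > threshold:
                    counts[a] += 1
                    counts[b] += 1
                    any_bad = True
        if not any_bad:
            break
        worst = max(counts.values())
        candidates = [u for u in active if counts[u] == worst]
        candidates.sort(key=lambda u: (rates[u], u))
        victim = candidates[0]
        active.remove(victim)
        removed.append(victim)
    return session.subset_units(active), removed


def flag_period_elevated_units(
    session: Session, period: str, alpha: float = 0.05, min_trials: int = 5
) -> dict[str, bool | None]:
    """Flag units with elevated spike counts in a period relative to fixation.

    Per-trial counts are rate-normalized (divided by period length) and
    compared with a one-sided paired Wilcoxon signed-rank test at ``alpha``.
    Units from sessions with fewer than ``min_trials`` trials are marked
    indeterminate (``None``).
    """
    if period not in ("maintenance", "probe"):
        raise ValueError("period must be 'maintenance' or 'probe'")
    out: dict[str, bool | None] = {}
    if len(session.trials) < min_trials:
        return {uid: None for uid in session.unit_ids}
    for uid in session.unit_ids:
        period_rates, fix_rates = [], []
        for trial in session.trials:
            t = session.spike_times(uid, trial.trial_id)
            lo, hi = trial.periods()[period]
            if hi <= lo:
                continue
            period_rates.append(np.count_nonzero((t >= lo) & (t < hi)) / (hi - lo))
            f_lo, f_hi = FIXATION
            fix_rates.append(np.count_nonzero((t >= f_lo) & (t < f_hi)) / (f_hi - f_lo))
        diffs = np.asarray(period_rates) - np.asarray(fix_rates)
        if len(diffs) < min_trials or np.all(diffs == 0):
            out[uid] = False
            continue
        # zero differences dropped per the default Wilcoxon convention
        res = stats.wilcoxon(diffs, alternative="greater", zero_method="wilcox")
        out[uid] = bool(res.pvalue < alpha)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
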