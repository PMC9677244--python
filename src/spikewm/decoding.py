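"""Pseudo-population decoding of trial variables from maintenance activity.

Units recorded in separate sessions are combined into a pseudo-population
by sampling, per session, the same number of trials per class (n_T, the
minimum class count across sessions; sessions with a class minimum below
5 are discarded) and concatenating unit columns.  Features are per-unit
spike counts in twelve non-overlapping 250-ms bins of the 3-s maintenance
period, z-scored per unit; each bin is one sample, so a pseudo-population
holds 12 x 2 x n_T samples.  A balanced linear SVM with 10-fold
stratified cross-validation yields the accuracy; label shuffles within
each bootstrap cycle provide the null, and the median one-tailed p over
cycles is the summary.

Burstiness enters through n-tile splits of the units by their mean LvR in
the cycle's sampled trials, and through a d-prime sensitivity index for
the accuracy drop when an n-tile is removed:

    d' = (mu_Full - mu_Red) / sqrt(0.5 * (var_Full + var_Red)),

with means and variances taken across the 10 cross-validation folds of
the full and reduced populations decoded on the same trial sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from spikewm.core import MAINTENANCE, Session, bh_adjust
from spikewm.irregularity import lvr_gated

N_BINS = 12
BIN_S = 0.25
MIN_CLASS_TRIALS = 5


def class_trials(session: Session, class_def: str) -> dict[int, list[int]]:
    """Trial ids per binary class: 0/1 = low/high workload or correct/wrong."""
    if class_def == "setsize":
        return {
            0: [t.trial_id for t in session.trials if t.set_size == 4],
            1: [t.trial_id for t in session.trials if t.set_size in (6, 8)],
        }
    if class_def == "correctness":
        return {
            0: [t.trial_id for t in session.trials if t.correct],
            1: [t.trial_id for t in session.trials if not t.correct],
        }
    raise ValueError("class_def must be 'setsize' or 'correctness'")


def maintenance_features(session: Session) -> tuple[np.ndarray, list[str]]:
    """(n_trials, 12, n_units) maintenance spike counts, z-scored per unit.

    The z-score pools all bins x trials of a unit; zero-variance units map
    to all-zero features.
    """
    lo, _ = MAINTENANCE
    edges = lo + BIN_S * np.arange(N_BINS + 1)
    n_trials = len(session.trials)
    feats = np.zeros((n_trials, N_BINS, len(session.units)))
    for u, uid in enumerate(session.unit_ids):
        for j, trial in enumerate(session.trials):
            t = session.spike_times(uid, trial.trial_id)
            feats[j, :, u], _ = np.histogram(t, bins=edges)
        col = feats[:, :, u]
        sd = col.std()
        feats[:, :, u] = (col - col.mean()) / sd if sd > 0 else 0.0
    return feats, list(session.unit_ids)


@dataclass
class PseudoPopulation:
    """Z-scored sample matrix with per-sample labels and sampling bookkeeping."""

    X: np.ndarray                 # (12 * 2 * n_T, total units)
    y: np.ndarray                 # per-sample class label
    trial_slot: np.ndarray        # per-sample pseudo-trial index (for shuffles)
    unit_ids: list[str]
    unit_sessions: list[int]
    sampled_trials: list[dict[int, list[int]]]  # per session: class -> trial ids
    n_T: int


def build_pseudopopulation(
    sessions: Sequence[Session],
    class_def: str,
    rng: np.random.Generator | None = None,
    features: Sequence[tuple[np.ndarray, list[str]]] | None = None,
) -> PseudoPopulation:
    """Sample one trial alignment and assemble the pseudo-population matrix.

    Sessions whose smaller class has fewer than 5 trials are discarded;
    n_T is the minimum class count across the remaining sessions and
    trials are drawn uniformly without replacement within class and
    session.  Precomputed ``features`` (from :func:`maintenance_features`)
    can be passed to avoid recomputation across bootstrap cycles.
    """
    rng = np.random.default_rng() if rng is None else rng
    if features is None:
        features = [maintenance_features(s) for s in sessions]

    usable, minima = [], []
    for s_i, session in enumerate(sessions):
        ct = class_trials(session, class_def)
        m = min(len(ct[0]), len(ct[1]))
        if m >= MIN_CLASS_TRIALS:
            usable.append((s_i, ct))
            minima.append(m)
    if not usable:
        raise ValueError("no session retains >= 5 trials in both classes")
    n_T = min(minima)

    blocks, sampled = [], []
    unit_ids: list[str] = []
    unit_sessions: list[int] = []
    for s_i, ct in usable:
        feats, uids = features[s_i]
        trial_pos = {t.trial_id: j for j, t in enumerate(sessions[s_i].trials)}
        picks = {
            c: sorted(rng.choice(ct[c], size=n_T, replace=False).tolist())
            for c in (0, 1)
        }
        sampled.append(picks)
        rows = []
        for c in (0, 1):
            for tid in picks[c]:
                rows.append(feats[trial_pos[tid]])  # (12, n_units)
        blocks.append(np.concatenate(rows, axis=0))  # (2*n_T*12, n_units)
        unit_ids.extend(uids)
        unit_sessions.extend([s_i] * len(uids))

    X = np.concatenate(blocks, axis=1)
    y = np.repeat([0, 1], n_T * N_BINS)
    trial_slot = np.repeat(np.arange(2 * n_T), N_BINS)
    return PseudoPopulation(
        X=X,
        y=y,
        trial_slot=trial_slot,
        unit_ids=unit_ids,
        unit_sessions=unit_sessions,
        sampled_trials=sampled,
        n_T=n_T,
    )


def decode_cv(
    X: np.ndarray, y: np.ndarray, n_folds: int = 10, C: float = 1.0
) -> tuple[float, np.ndarray]:
    """Balanced linear SVM accuracy under stratified 10-fold cross-validation.

    Returns the mean test accuracy and the per-fold accuracies (the folds
    feed the d-prime index).
    """
    if X.shape[0] < 2 * n_folds:
        raise ValueError("too few samples for the requested folds")
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean()), scores


def shuffle_labels(
    y: np.ndarray,
    trial_slot: np.ndarray,
    rng: np.random.Generator,
    by_trial: bool = False,
) -> np.ndarray:
    """Permute class labels across samples.

    The default permutes per sample (each 250-ms bin independently), which
    keeps the shuffle null exactly chance-centered.  ``by_trial`` moves all
    12 bins of a pseudo-trial together instead, preserving the within-trial
    correlation in the null at the cost of a slight optimistic shift when
    trials straddle cross-validation folds.
    """
    if not by_trial:
        return y[rng.permutation(y.size)]
    slots = np.unique(trial_slot)
    slot_label = np.array([y[trial_slot == s][0] for s in slots])
    permuted = slot_label[rng.permutation(slots.size)]
    out = np.empty_like(y)
    for s, lab in zip(slots, permuted):
        out[trial_slot == s] = lab
    return out


@dataclass
class DecodingResult:
    accuracies: np.ndarray        # one per bootstrap cycle
    null_accuracies: np.ndarray   # (n_cycles, n_shuffles)
    p_per_cycle: np.ndarray
    summary_p: float
    n_T: int


def bootstrap_decode(
    sessions: Sequence[Session],
    class_def: str,
    n_cycles: int = 50,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    shuffle_by_trial: bool = False,
) -> DecodingResult:
    """Bootstrap decoding: fresh trial alignments, label-shuffle nulls.

    Per cycle: a new pseudo-population is sampled and decoded; the class
    labels are shuffled ``n_shuffles`` times to build the null; the
    one-tailed p uses the +1 smoothing convention.  The summary p is the
    median over cycles.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    features = [maintenance_features(s) for s in sessions]
    accs = np.empty(n_cycles)
    nulls = np.empty((n_cycles, n_shuffles))
    ps = np.empty(n_cycles)
    n_T = 0
    for c in range(n_cycles):
        pop = build_pseudopopulation(sessions, class_def, rng, features=features)
        n_T = pop.n_T
        accs[c], _ = decode_cv(pop.X, pop.y)
        for k in range(n_shuffles):
            y_null = shuffle_labels(pop.y, pop.trial_slot, rng, by_trial=shuffle_by_trial)
            nulls[c, k], _ = decode_cv(pop.X, y_null)
        ps[c] = (1 + np.sum(nulls[c] >= accs[c])) / (n_shuffles + 1)
    return DecodingResult(
        accuracies=accs,
        null_accuracies=nulls,
        p_per_cycle=ps,
        summary_p=float(np.median(ps)),
        n_T=n_T,
    )


def cycle_mean_lvr(
    sessions: Sequence[Session], pop: PseudoPopulation, R_s: float = 0.005
) -> dict[str, float]:
    """Per-unit mean whole-trial LvR over the trials sampled in one cycle."""
    out: dict[str, float] = {}
    usable_sessions = sorted(set(pop.unit_sessions))
    for s_i, picks in zip(usable_sessions, pop.sampled_trials):
        session = sessions[s_i]
        tids = picks[0] + picks[1]
        for uid in session.unit_ids:
            vals = [
                lvr_gated(session.spike_times(uid, tid), R_s) for tid in tids
            ]
            vals = [v for v in vals if np.isfinite(v)]
            out[uid] = float(np.mean(vals)) if vals else float("nan")
    return out


def ntile_split(
    unit_ids: Sequence[str], mean_lvr: Mapping[str, float], n_tiles: int
) -> list[list[str]]:
    """Partition units into n equal-size (+-1) tiles by ascending mean LvR.

    Units with missing LvR rank lowest; ties break by unit_id.
    """
    if n_tiles > len(unit_ids):
        raise ValueError("n_tiles exceeds the number of units")

    def key(u: str):
        v = mean_lvr.get(u, float("nan"))
        return (not np.isnan(v), v if np.isfinite(v) else 0.0, u)

    order = sorted(unit_ids, key=key)
    return [list(part) for part in np.array_split(order, n_tiles)]


@dataclass
class DPrimeResult:
    n_tiles: int
    dprime: np.ndarray            # (n_cycles, n_tiles)
    mean: np.ndarray
    sem: np.ndarray
    t_p: np.ndarray               # one-sample t vs 0 per tile
    t_p_adj: np.ndarray           # BH across tiles
    tile_mean_lvr: np.ndarray     # mean LvR of each tile's units, across cycles


def dprime(full_scores: np.ndarray, red_scores: np.ndarray) -> float:
    """Sensitivity index for the accuracy change between two fold-score sets."""
    var_f = float(np.var(full_scores, ddof=1))
    var_r = float(np.var(red_scores, ddof=1))
    pooled = 0.5 * (var_f + var_r)
    diff = float(np.mean(full_scores) - np.mean(red_scores))
    if diff == 0.0:
        return 0.0
    if pooled == 0:
        return float("nan")
    return diff / float(np.sqrt(pooled))


def dprime_ablation(
    sessions: Sequence[Session],
    class_def: str,
    n_tiles: int = 20,
    n_cycles: int = 50,
    rng: np.random.Generator | None = None,
) -> DPrimeResult:
    """Per-LvR-n-tile d-prime of the accuracy drop under tile removal.

    Per cycle the full population and each tile-ablated population are
    decoded on the identical trial sample; d' follows from the fold
    accuracies.  Tiles are re-formed each cycle from that cycle's mean
    LvR, so a unit can change tiles between cycles.
    """
    rng = np.random.default_rng() if rng is None else rng
    features = [maintenance_features(s) for s in sessions]
    d = np.full((n_cycles, n_tiles), np.nan)
    tile_lvr = np.full((n_cycles, n_tiles), np.nan)
    for c in range(n_cycles):
        pop = build_pseudopopulation(sessions, class_def, rng, features=features)
        mean_lvr = cycle_mean_lvr(sessions, pop)
        tiles = ntile_split(pop.unit_ids, mean_lvr, n_tiles)
        _, full_scores = decode_cv(pop.X, pop.y)
        col = {u: i for i, u in enumerate(pop.unit_ids)}
        for q, tile in enumerate(tiles):
            keep = [i for u, i in col.items() if u not in set(tile)]
            if not tile:
                d[c, q] = 0.0
                continue
            _, red_scores = decode_cv(pop.X[:, keep], pop.y)
            d[c, q] = dprime(full_scores, red_scores)
            tile_lvr[c, q] = np.nanmean([mean_lvr.get(u, np.nan) for u in tile])
    mean = np.nanmean(d, axis=0)
    n_eff = np.sum(np.isfinite(d), axis=0)
    sem = np.nanstd(d, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    t_p = np.array(
        [
            stats.ttest_1samp(d[np.isfinite(d[:, q]), q], 0.0).pvalue
            if n_eff[q] > 1
            else np.nan
            for q in range(n_tiles)
        ]
    )
    ok = np.isfinite(t_p)
    t_p_adj = np.full(n_tiles, np.nan)
    if ok.any():
        t_p_adj[ok] = bh_adjust(t_p[ok])
    return DPrimeResult(
        n_tiles=n_tiles,
        dprime=d,
        mean=mean,
        sem=sem,
        t_p=t_p,
        t_p_adj=t_p_adj,
        tile_mean_lvr=np.nanmean(tile_lvr, axis=0),
    )


def single_unit_setsize_tests(
    sessions: Sequence[Session],
    class_def: str = "setsize",
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-unit two-sample t tests on maintenance firing rates between classes.

    Uses one balanced trial sample per session (the decoding alignment
    rule); reports the fractions of significantly positive / negative t
    statistics and a binomial test of the sign split against 0.5.
    Zero-variance units are excluded.
    """
    rng = np.random.default_rng() if rng is None else rng
    pop = build_pseudopopulation(sessions, class_def, rng)
    lo, hi = MAINTENANCE
    n_pos = n_neg = n_tested = 0
    per_unit = {}
    usable_sessions = sorted(set(pop.unit_sessions))
    for s_i, picks in zip(usable_sessions, pop.sampled_trials):
        session = sessions[s_i]
        for uid in session.unit_ids:
            rates = {
                c: np.array(
                    [
                        np.count_nonzero(
                            (session.spike_times(uid, tid) >= lo)
                            & (session.spike_times(uid, tid) < hi)
                        )
                        / (hi - lo)
                        for tid in picks[c]
                    ]
                )
                for c in (0, 1)
            }
            if rates[0].std() == 0 and rates[1].std() == 0:
                per_unit[uid] = None
                continue
            t, p = stats.ttest_ind(rates[1], rates[0])
            per_unit[uid] = (float(t), float(p))
            n_tested += 1
            if p < alpha:
                if t > 0:
                    n_pos += 1
                else:
                    n_neg += 1
    n_sig = n_pos + n_neg
    binom_p = (
        stats.binomtest(n_pos, n_sig, 0.5).pvalue if n_sig > 0 else float("nan")
    )
    return {
        "per_unit": per_unit,
        "n_tested": n_tested,
        "frac_significant_positive": n_pos / n_tested if n_tested else float("nan"),
        "frac_significant_negative": n_neg / n_tested if n_tested else float("nan"),
        "binomial_p": float(binom_p),
    }
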