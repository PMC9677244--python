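"""Configuration-driven orchestration of the full analysis on a cohort.

Stages run in order — unit-quality filters, windowed LvR, time-resolved
LvR/response-time correlation, population bursts and densities,
mean-matched Fano factors, and pseudo-population decoding — each writing
CSV/JSON artifacts into the output directory.  A named seed-substream
registry (stage name -> independent RNG) keeps every stage's draws
independent of the others, so toggling one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spikewm import core, decoding, fano, irregularity, popburst, synthgen

STAGES = ("filters", "lvr", "rtcorr", "bursts", "fano", "decoding")

_DEFAULTS = {
    "seed": 0,
    "out_dir": "spikewm_out",
    "cohort_dir": None,          # read an existing cohort, else generate
    "generator": {},             # GeneratorConfig overrides
    "stages": list(STAGES),
    "lvr": {"window_s": 2.0, "step_s": 0.25, "R_s": 0.005},
    "rtcorr": {"window_s": 2.0, "step_s": 0.25, "n_perm": 200, "combo_orders": [1]},
    "bursts": {"n_boot": 1000, "min_duration_s": 0.1, "proximity_s": 0.15},
    "fano": {"window_s": 0.5, "step_s": 0.05, "n_repeats": 50},
    "decoding": {"class_def": "setsize", "n_cycles": 50, "n_shuffles": 500},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "spikewm_out"
    cohort_dir: str | None = None
    generator: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    lvr: dict = field(default_factory=dict)
    rtcorr: dict = field(default_factory=dict)
    bursts: dict = field(default_factory=dict)
    fano: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=dict)


def validate_config(path) -> PipelineConfig:
    """Load and normalize a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    merged = {}
    for key, default in _DEFAULTS.items():
        value = raw.get(key, default)
        if isinstance(default, dict) and value is not None:
            if not isinstance(value, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            sub_unknown = (
                set(value) - {f.name for f in dataclasses.fields(synthgen.GeneratorConfig)}
                if key == "generator"
                else set(value) - set(default)
            )
            if sub_unknown and key != "generator":
                raise ValueError(
                    f"unknown key(s) under {key!r}: {', '.join(sorted(sub_unknown))}"
                )
            value = {**default, **value}
        merged[key] = value
    bad = set(merged["stages"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {', '.join(sorted(bad))}")
    return PipelineConfig(**merged)


def _load_cohort(cohort_dir: Path) -> list[core.Session]:
    sessions = []
    for sub in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        if (sub / "spikes.csv").exists():
            sessions.append(
                core.read_session(
                    sub / "spikes.csv", sub / "trials.csv", sub / "session.json"
                )
            )
    if not sessions:
        raise ValueError(f"no session directories under {cohort_dir}")
    return sessions


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run report (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(len(STAGES) + 1)
    rngs = {name: np.random.default_rng(s) for name, s in zip(STAGES, seeds)}
    report: dict = {"stages": {}, "config": dataclasses.asdict(config)}
    manifest: dict[str, str] = {}

    t0 = time.perf_counter()
    if config.cohort_dir:
        sessions = _load_cohort(Path(config.cohort_dir))
    else:
        gen_cfg = synthgen.GeneratorConfig(
            **{"seed": config.seed, **config.generator}
        )
        sessions, truth = synthgen.synth_cohort(gen_cfg)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
        manifest["truth"] = str(out / "truth.json")
    report["stages"]["input"] = {"seconds": time.perf_counter() - t0,
                                 "n_sessions": len(sessions)}

    def _run_stage(name, fn):
        if name not in config.stages:
            return
        t = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # keep partial outputs, mark the failure
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {"seconds": time.perf_counter() - t}

    def stage_filters():
        nonlocal sessions
        filtered = []
        rows = []
        for s in sessions:
            s1 = core.filter_units_by_rate(s)
            s2, removed = core.crosstalk_filter(s1)
            filtered.append(s2)
            rows.append((s.session_id, len(s.units), len(s1.units), len(s2.units),
                         ";".join(removed)))
        sessions = filtered
        df = pd.DataFrame(rows, columns=["session_id", "n_units", "after_rate",
                                         "after_crosstalk", "removed_crosstalk"])
        df.to_csv(out / "filters.csv", index=False)
        manifest["filters"] = str(out / "filters.csv")

    def stage_lvr():
        p = config.lvr
        rows = []
        for s in sessions:
            for u in s.units:
                for tr in s.trials:
                    series = irregularity.sliding_lvr(
                        s.spike_times(u.unit_id, tr.trial_id),
                        p["window_s"], p["step_s"], p["R_s"],
                    )
                    for t, v in zip(series.times, series.values):
                        rows.append((s.session_id, u.unit_id, u.region,
                                     tr.trial_id, t, v))
        pd.DataFrame(rows, columns=["session_id", "unit_id", "region", "trial_id",
                                    "time_s", "lvr"]).to_csv(out / "lvr.csv",
                                                             index=False)
        manifest["lvr"] = str(out / "lvr.csv")

    def stage_rtcorr():
        p = config.rtcorr
        rows = []
        for order in p["combo_orders"]:
            res = irregularity.timeresolved_rt_correlation(
                sessions, p["window_s"], p["step_s"], combo_order=order,
                n_perm=p["n_perm"], rng=rngs["rtcorr"],
            )
            for region, d in res.items():
                for t, r, pv, pa in zip(d["times"], d["r"], d["p"], d["p_adj"]):
                    rows.append((order, region, t, r, pv, pa))
        pd.DataFrame(rows, columns=["combo_order", "region", "time_s", "r", "p",
                                    "p_bh"]).to_csv(out / "rtcorr.csv", index=False)
        manifest["rtcorr"] = str(out / "rtcorr.csv")

    def stage_bursts():
        p = config.bursts
        ev_rows, dens = [], []
        for s in sessions:
            events = popburst.session_bursts(
                s, min_duration_s=p["min_duration_s"], proximity_s=p["proximity_s"]
            )
            for tid, evs in events.items():
                for ev in evs:
                    ev_rows.append((s.session_id, tid, ev.start, ev.end,
                                    ev.peak_rate, ev.sparsity, ev.weighted_lvr,
                                    ev.period))
            for align in ("trial_start", "response"):
                den = popburst.burst_density(events, s.trials, align=align,
                                             n_boot=p["n_boot"],
                                             rng=rngs["bursts"])
                for t, d, lo_, hi_ in zip(den.times, den.density, den.ci_low,
                                          den.ci_high):
                    dens.append((s.session_id, align, t, d, lo_, hi_))
        pd.DataFrame(ev_rows, columns=["session_id", "trial_id", "start_s", "end_s",
                                       "peak_hz", "sparsity", "weighted_lvr",
                                       "period"]).to_csv(out / "bursts.csv",
                                                         index=False)
        pd.DataFrame(dens, columns=["session_id", "align", "time_s", "density",
                                    "ci_low", "ci_high"]).to_csv(
            out / "density.csv", index=False)
        manifest["bursts"] = str(out / "bursts.csv")
        manifest["density"] = str(out / "density.csv")

    def stage_fano():
        p = config.fano
        rows = []
        for s in sessions:
            points = fano.window_counts(s, p["window_s"], p["step_s"],
                                        rng=rngs["fano"])
            if points.empty:
                continue
            series = fano.mean_matched_ff(points, n_repeats=p["n_repeats"],
                                          rng=rngs["fano"])
            for t, f, lo_, hi_ in zip(series.times, series.ff, series.ci_low,
                                      series.ci_high):
                rows.append((s.session_id, t, f, lo_, hi_))
        pd.DataFrame(rows, columns=["session_id", "time_s", "ff", "ci_low",
                                    "ci_high"]).to_csv(out / "ff.csv", index=False)
        manifest["ff"] = str(out / "ff.csv")

    def stage_decoding():
        p = config.decoding
        res = decoding.bootstrap_decode(
            sessions, p["class_def"], n_cycles=p["n_cycles"],
            n_shuffles=p["n_shuffles"], rng=rngs["decoding"],
        )
        payload = {
            "class_def": p["class_def"],
            "n_T": res.n_T,
            "accuracy_mean": float(res.accuracies.mean()),
            "accuracies": res.accuracies.tolist(),
            "p_per_cycle": res.p_per_cycle.tolist(),
            "summary_p": res.summary_p,
        }
        with open(out / "decode.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        manifest["decode"] = str(out / "decode.json")

    _run_stage("filters", stage_filters)
    _run_stage("lvr", stage_lvr)
    _run_stage("rtcorr", stage_rtcorr)
    _run_stage("bursts", stage_bursts)
    _run_stage("fano", stage_fano)
    _run_stage("decoding", stage_decoding)

    report["manifest"] = manifest
    report["total_seconds"] = time.perf_counter() - t0
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
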