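# spikewm

Spike-train analysis of trial-structured working-memory recordings:
irregularity (LvR), change points, population bursts, mean-matched Fano
factors, and burstiness-stratified pseudo-population decoding — with a
synthetic-session generator so the whole pipeline is testable without
access to clinical data.

The package targets single-unit recordings from a Sternberg task (8-s
trials: 1 s fixation, 2 s encoding of 4/6/8 letters, 3 s maintenance,
probe until the response) with units labelled by medial-temporal-lobe
region (hippocampus, amygdala, entorhinal cortex).  It is written for
electrophysiologists who want the full chain — unit-quality filtering,
statistics, permutation inference, decoding — as tested, reusable library
code with a thin CLI.

## The core statistic

Spiking irregularity is measured by the refractoriness-corrected local
variation of consecutive inter-spike intervals I_1..I_n:

    LvR = 3/(n−1) Σ_{i=1}^{n−1} (1 − 4 I_i I_{i+1}/(I_i+I_{i+1})²)(1 + 4R/(I_i+I_{i+1}))

with R = 5 ms for single units.  LvR ≈ 1 for Poisson firing, < 1 for
regular, > 1 for bursty trains, and is insensitive to slow rate changes.
For gamma-renewal ISIs of shape k, E[Lv] = 3/(2k+1) — the closed form the
calibration suite checks against.  Around it the package builds:
sequential change-point detection with a fixation-adapted binomial
threshold; population-burst detection (25-ms kernel rates, mean + 3 sd
threshold, 100-ms minimum) with composition, sparsity and weighted-LvR
descriptors; mean-matched Fano factors (greatest-common mean-count
matching, weighted zero-intercept regression); and linear-SVM decoding of
workload/correctness from maintenance activity, with LvR-n-tile ablation
d′ indices.  See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from spikewm.synthgen import GeneratorConfig, synth_cohort
from spikewm.irregularity import lvr_gated
from spikewm.decoding import bootstrap_decode

cfg = GeneratorConfig(n_sessions=2, units_per_region=4, n_trials=40,
                      setsize_gain=1.3, seed=17)
sessions, truth = synth_cohort(cfg)

# mean LvR of one unit across trials
s = sessions[0]
vals = [lvr_gated(s.spike_times(s.unit_ids[0], t.trial_id)) for t in s.trials]
print(f"unit {s.unit_ids[0]}: mean LvR = {np.nanmean(vals):.3f}")

res = bootstrap_decode(sessions, "setsize", n_cycles=5, n_shuffles=99,
                       rng=np.random.default_rng(17))
print(f"decoding accuracy = {res.accuracies.mean():.3f}, "
      f"summary p = {res.summary_p:.4f}")
```

prints

```
unit hip00: mean LvR = 0.526
decoding accuracy = 0.727, summary p = 0.0100
```

The first line is the across-trial mean irregularity of a synthetic unit
whose generative gamma shape was drawn at 2.87 (regular regime, LvR < 1;
the renewal expectation 3/(2·2.87+1) ≈ 0.44 plus the refractoriness
correction gives ≈ 0.5).  The second line shows that a 1.3× rate gain for
high workloads in a quarter of the units is decodable from maintenance
activity: mean 10-fold CV accuracy 0.73 against a label-shuffle null
centered at 0.5, with a
median one-tailed p of 0.01 over bootstrap cycles (the minimum attainable
at 99 shuffles with +1 smoothing).

The same analyses are scriptable from the shell:

```
spikewm simulate --out cohort --seed 1
spikewm lvr --session cohort/synth00 --out lvr.csv
spikewm decode --cohort cohort --classes setsize --cycles 5 --shuffles 99 \
    --seed 1 --out decode.json
spikewm run --config cfg.yaml      # full pipeline from a YAML config
```

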