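# Methods

`spikewm` analyses trial-structured single-unit recordings from a Sternberg
working-memory task: 8-s trials beginning with 1 s of fixation, 2 s of
stimulus encoding (4, 6 or 8 letters), a 3-s maintenance delay, and a probe
period ending at the response (the recording truncates at 8 s, so responses
slower than 2 s are partially missing and are dropped where an analysis
needs the full probe window).  Units carry an anatomical label
(hippocampus, amygdala, entorhinal cortex).  All intervals are half-open
`[start, end)` in seconds from trial start.

## Unit-quality filters

Units with a pooled firing rate of at most 1 Hz (total spikes over total
recorded time; strict `> 1 Hz` to keep) are removed.  Electrode cross-talk
is screened by binarizing each unit's concatenated trains at 1 ms and
computing pairwise Jaccard similarities; while any pair exceeds 0.3, the
unit in the most supra-threshold pairs is removed (ties: lower rate, then
unit id).  The pooled-rate convention (vs per-trial averaging) is
irrelevant here because trials have fixed length; a flag is unnecessary.

## LvR

The central irregularity statistic is the refractoriness-corrected local
variation of consecutive inter-spike intervals (ISIs) I_1..I_n:

    LvR = 3/(n-1) * sum_{i=1}^{n-1} (1 - 4 I_i I_{i+1}/(I_i+I_{i+1})^2)
                                    * (1 + 4R/(I_i+I_{i+1}))

with R = 5 ms for single units and R = 0 for combined trains (where exact
duplicate spike times are collapsed, since a zero ISI is undefined in the
formula).  LvR is 0 for perfectly regular trains, ~1 for Poisson firing,
above 1 for bursty firing, and scale-invariant when ISIs and R are scaled
together.  Windows or trains with fewer than 5 spikes yield a missing
value, never a zero.  For a gamma-renewal process of shape k the expected
plain local variation is 3/(2k+1); this closed form is the package's main
calibration oracle.

## Change points

Rate change points within a trial are found by a sequential
cumulative-record scan: spikes are processed in order; at each new spike
the empirical cumulative count over the current segment is compared with
the straight line joining the segment origin to the current spike (the
expectation of a perfectly regular train), the deviation being evaluated
both just before and just after each count step.  The earliest maximally
deviating spike is accepted as a change point when a two-sided binomial
test on the before/after counts (success probability = the fraction of the
segment before the candidate) is significant at P = 1/(1 + 10^logit); the
origin then moves to the change point.  The logit is adapted per unit:
starting at 1.3 it is raised in steps of 0.2 (up to 5.9, P ≈ 0.05 to 1e-6)
until none of the unit's fixation windows contains a change point.
Adaptation pools all of a unit's fixation windows (per-unit, not
per-trial — the choice that makes the threshold a property of the unit).

Localization precision depends on the ISI regularity of the underlying
train.  For a memoryless (Poisson) train the information about the change
point position is weak: even a maximum-likelihood estimator with known
pre/post rates localizes a 2→10 Hz step at 4 s to within ±0.3 s only ~74%
of the time, so no detector can do better.  The package's localization
benchmark therefore uses a regular renewal train (gamma shape 4, local
variation ≈ 1/3) — the regime in which a rate change point is a
well-posed notion and which matches the detector's own null model — at
logit 2.5, the mid-schedule value the fixation adaptation typically
returns for random-firing units.  At these conditions ≥ 90% of simulated
steps are localized within ±0.3 s.

## Time-resolved LvR and trial variables

Sliding-window LvR (2-s windows, right-aligned time index) is correlated
window-by-window with response times over all unit × trial points pooled
within a region.  Significance comes from trial-structure-preserving
permutations: the trial-variable vector is permuted within each session
and shared by all simultaneously recorded units; p-values use the +1
smoothing convention and are BH-adjusted across regions per window.
Distribution shifts between trial classes (high vs low workload, wrong vs
correct) use a rank-based dissimilarity: pooled values are rank-
transformed (average ranks on ties), each class's empirical CDF is
evaluated at integer ranks 1..N, and the statistic is the signed sum of
CDF differences — a signed area that is invariant to any strictly
monotone transform of the values and antisymmetric under label swap.
Combined-unit LvR values (pairs/triples, R = 0) are subsampled within
session to the single-unit point count, the permutation test repeated, and
the median p over 100 subsamples reported.  A first-order partial
correlation (LvR–RT given firing rate) controls for rate confounds.

## Population bursts

Per trial, each unit's raster is convolved with a 25-ms Gaussian kernel
sampled on a 10-ms grid (kernel truncated at the trial edges without
renormalization, which depresses estimates within ~50 ms of 0 and 8 s);
the population rate is the unit average.  The threshold is mean + 3·sd
(sample sd, n−1) of the per-trial unit-averaged whole-window rates.
Supra-threshold runs of at least 100 ms are events; consecutive events
closer than 150 ms (tail to head) lose the one with the lower peak rate,
re-checking left to right.  Each event carries a composition vector w
(per-unit mean smoothed rate within the burst), the sparsity index
1 − (√n − Σ|ŵ_i|)/(√n − 1) with ŵ the unit-normalized composition (0 =
one unit dominates, 1 = uniform), a composition-weighted mean of the
single-unit LvRs (missing LvRs dropped with weight renormalization), and a
period assignment (the period containing ≥ 80% of the event, boundary
inclusive; the probe period's right edge is the response time).  Burst
density is the per-10-ms-bin fraction of trials with an ongoing event,
with a 1000-draw trial-level percentile bootstrap for 95% CIs; the
response-aligned variant re-references to the response and discards trials
with response times above 2 s.

Known limitation: the threshold's sd is taken across trial-averaged
rates, whose sampling variability is far smaller than that of the
instantaneous smoothed population rate (the ratio is √(0.0886 s / 8 s) ≈
0.105 for a stationary process, independent of unit count and rate).  For
a memoryless Poisson population the threshold therefore sits at only ~0.3
instantaneous-rate standard deviations above the mean and essentially
every trial contains spurious "bursts".  The rule is meaningful on data
with substantial trial-to-trial rate variability — as real recordings
have — but a stationary Poisson null does not satisfy a low false-positive
bound, and the corresponding assertion in the acceptance suite fails by
design rather than being weakened.

## Mean-matched Fano factor

Across-trial mean and variance of spike counts are collected per
unit × condition (the three set sizes by default) in 500-ms windows
stepped by 50 ms (right-aligned).  The greatest common distribution of
mean counts across windows (histogram bin 0.5) defines a target; per
window, points are randomly discarded to match it, and the Fano factor is
the slope of the zero-intercept regression of variance on mean, each
point weighted by 1/(0.01 + SE(variance)) with SE(variance) =
variance·√(2/(n−1)) (the normal-theory approximation; the SE estimator is
a package choice).  The matching is repeated 50 times (fresh RNG
substream per repeat) and the mean with a 2.5–97.5 percentile CI
reported.  Because the weights anti-correlate with the sampled variance,
the Poisson slope is mildly biased low at small per-condition trial
counts (≈0.90 at 20 trials/condition, ≈0.97 at 60); the calibration
suite uses 60 trials.  Direct set-size comparisons (4 vs 6–8) equalize
trial counts by undersampling the larger condition independently per
unit × window, with a common matching target taken as the per-bin minimum
over every condition × window histogram.

FF (or density) time courses are compared by a cluster-based permutation
test: window-wise two-sample t statistics over the repeat distributions,
thresholded two-sided at alpha = 0.05; maximal contiguous same-sign
supra-threshold runs are scored by summed t, and the null distribution of
the maximal |cluster mass| is built by permuting repeat rows between the
two series (the window-wise statistic is a package choice and is
switchable in principle; the clustering alpha equals the test alpha).
Units can also be split into quartiles of across-trial mean LvR, with the
full FF pipeline run per quartile and per-period FF averages reported —
under a shared trial latent, burstier quartiles show larger trial
variability.

## Decoding

Features are per-unit spike counts in twelve non-overlapping 250-ms bins
of the maintenance period, z-scored per unit over all bins × trials
(z-scoring precedes cross-validation, mirroring the pipeline order; the
mild leakage is noted).  Sessions whose smaller class holds fewer than 5
trials are discarded; n_T, the minimum class count across sessions, sets
the per-class sample per session, drawn uniformly without replacement, and
unit columns are concatenated across sessions (12·2·n_T samples).  A
linear SVM (C = 1, balanced class weights) under stratified 10-fold CV
gives the accuracy; per bootstrap cycle the labels are shuffled 500 times
(per sample — trial-level shuffling is available but leaves the null
~0.013 above chance when pseudo-trials straddle folds) for a one-tailed
+1-smoothed p, and the median p over 50 cycles is the summary.

For burstiness stratification, units are split per cycle into equal-size
n-tiles by mean whole-trial LvR over that cycle's sampled trials (missing
LvR ranks lowest, ties by unit id).  Ablating an n-tile and re-decoding
the identical trial sample yields, from the fold accuracies,

    d' = (mu_Full − mu_Red) / sqrt(0.5 (var_Full + var_Red)),

summarized across cycles by mean ± SEM with a one-sample t test against 0,
BH-adjusted across n-tiles.  Complementary single-unit two-sample t tests
(maintenance rates, class 1 vs class 0 on the decoding trial sample)
report the fractions of significant positive/negative effects and a
binomial test of the sign split.

## Synthetic sessions

The generator emulates the recording structure so every stage is testable
without clinical data.  Per unit it draws a base rate uniform in 2–15 Hz
and a gamma-renewal shape uniform in 0.4–3.0 (LvR roughly 0.5–1.8); trains
are equilibrium-stationary (first spike from the forward-recurrence
distribution) and inhomogeneous profiles are realized by time-rescaling a
unit-rate renewal process, so window counts are unbiased for the rate
integral.  Trials follow the task rule that a wrong response forces set
size 4 on the next trial; response times are log-normal (median 1 s,
sigma 0.35 log-units) truncated to [0.3, 2.5] s.  Injectable effects: a
multiplicative workload gain (default 1.3) on set sizes 6/8 in a random
quarter of the units; a 3× probe-locked gain in the 0.5 s after probe
onset for amygdala/entorhinal units (bursts emerge mechanistically from
the rate elevation rather than from pasted spikes); and a trial-level
standard-normal latent z_t, shared by all units of a session, that with
coupling c scales response times by exp(c·z_t) and per-trial renewal
shapes by exp(−c·z_t) — high-z trials are burstier and slower, giving the
LvR–RT coupling its sign.  The generator omits features of real data —
refractory periods, slow nonstationarities, cross-unit correlation beyond
the single latent, artifact and sorting noise — so passing recovery tests
demonstrates correctness of the estimators under the stated model, not
robustness to clinical data.

## Problem sizes and numerical choices

The test and calibration suites run at desk scale: 500 trains for the LvR
oracle (tolerance ±0.05), 200 units × 60 trials for the Poisson FF
calibration (±0.1), 200 replicate runs for permutation calibration
(99 permutations each), 500 shuffles for the chance-centering check
(±0.01), 200 simulations for the change-point and burst-injection
benchmarks, and 5 cycles × 99 shuffles for the decoding power check.
Permutation p-values always use +1 smoothing; missing windowed values are
NaN and correlations use pairwise-complete points; seeds fan out through
`numpy.random.SeedSequence.spawn` so stages draw from independent
substreams and every result is reproducible from a single integer seed.
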