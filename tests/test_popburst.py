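import numpy as np
import pytest

from spikewm.core import Session, Trial, Unit
from spikewm.popburst import (
    BurstEvent,
    assign_period,
    burst_composition,
    burst_density,
    burst_threshold,
    burst_weighted_lvr,
    detect_bursts,
    instantaneous_rates,
    session_bursts,
    sparsity,
    PopulationRateSeries,
)
from spikewm.synthgen import GeneratorConfig, RateProfile, inhomogeneous_train, synth_session
from tests.conftest import poisson_session


def _series(pop, step=0.01):
    """Wrap a population-rate vector as a single-unit series."""
    t = np.arange(0, pop.size) * step
    return PopulationRateSeries(times=t, unit_rates=pop[None, :], unit_ids=["u"])


class TestInstantaneousRates:
    def test_empty_trains_zero(self):
        s = Session(
            "s", "p",
            [Unit(unit_id="u", region="hippocampus")],
            [Trial(trial_id=0, set_size=4, correct=True, response_time=1.0)],
            {},
        )
        series = instantaneous_rates(s, 0)
        assert np.all(series.unit_rates == 0)

    def test_single_spike_kernel_mass(self):
        s = Session(
            "s", "p",
            [Unit(unit_id="u", region="hippocampus")],
            [Trial(trial_id=0, set_size=4, correct=True, response_time=1.0)],
            {("u", 0): np.array([4.0])},
        )
        series = instantaneous_rates(s, 0)
        mass = np.trapezoid(series.unit_rates[0], series.times)
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_population_mean_matches_rate(self):
        s = poisson_session(n_units=20, n_trials=1, rate_hz=10.0, seed=0)
        series = instantaneous_rates(s, 0)
        # interior of the window: edge truncation depresses the first/last ~50 ms
        interior = (series.times > 0.2) & (series.times < 7.8)
        assert series.population[interior].mean() == pytest.approx(10.0, rel=0.05)


class TestBurstThreshold:
    def test_identical_trials_sd_zero(self):
        t = np.arange(0.5, 8, 0.5)
        units = [Unit(unit_id="u", region="hippocampus")]
        trials = [
            Trial(trial_id=j, set_size=4, correct=True, response_time=1.0)
            for j in range(3)
        ]
        s = Session("s", "p", units, trials, {("u", j): t for j in range(3)})
        assert burst_threshold(s) == pytest.approx(t.size / 8.0)

    def test_hand_arithmetic_two_trials(self):
        # per-trial unit-averaged rates 4 and 6 Hz -> 5 + 3*sd(ddof=1)
        units = [Unit(unit_id="u", region="hippocampus")]
        trials = [
            Trial(trial_id=j, set_size=4, correct=True, response_time=1.0)
            for j in range(2)
        ]
        spikes = {
            ("u", 0): np.linspace(0.1, 7.9, 32),
            ("u", 1): np.linspace(0.1, 7.9, 48),
        }
        s = Session("s", "p", units, trials, spikes)
        sd = np.std([4.0, 6.0], ddof=1)
        assert burst_threshold(s) == pytest.approx(5.0 + 3 * sd)

    def test_single_trial_insufficient(self):
        s = poisson_session(n_units=2, n_trials=1, seed=1)
        with pytest.raises(ValueError):
            burst_threshold(s)


class TestDetectBursts:
    def test_below_threshold_no_events(self):
        assert detect_bursts(_series(np.full(800, 2.0)), threshold=5.0) == []

    def test_short_excursion_dropped(self):
        pop = np.zeros(800)
        pop[100:105] = 10.0  # 50 ms < 100 ms minimum
        assert detect_bursts(_series(pop), threshold=5.0) == []

    def test_close_pair_lower_peak_discarded(self):
        pop = np.zeros(800)
        pop[100:120] = 8.0    # 200 ms, peak 8
        pop[130:150] = 12.0   # starts 100 ms after first ends, peak 12
        events = detect_bursts(_series(pop), threshold=5.0)
        assert len(events) == 1
        assert events[0].peak_rate == pytest.approx(12.0)

    def test_events_respect_spacing_and_duration(self, rng):
        pop = rng.uniform(0, 12, size=800)
        events = detect_bursts(_series(pop), threshold=6.0)
        for ev in events:
            assert ev.duration >= 0.1 - 1e-12
        for a, b in zip(events, events[1:]):
            assert b.start - a.end >= 0.15

    def test_injected_elevation_recovered(self, rng):
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            units = [
                Unit(unit_id=f"u{i}", region="hippocampus") for i in range(15)
            ]
            trials = [Trial(trial_id=0, set_size=4, correct=True, response_time=1.0)]
            prof = RateProfile(
                np.array([0.0, 3.5, 3.7, 8.0]), np.array([5.0, 25.0, 5.0])
            )
            spikes = {
                (u.unit_id, 0): inhomogeneous_train(prof, 1.0, rng) for u in units
            }
            s = Session("s", "p", units, trials, spikes)
            series = instantaneous_rates(s, 0)
            events = detect_bursts(series, threshold=5.0 + 3 * 5.0 / np.sqrt(15 * 8))
            if any(ev.start < 3.7 and ev.end > 3.5 for ev in events):
                hits += 1
        assert hits / n_sim >= 0.9


class TestAssignPeriod:
    trial = Trial(trial_id=0, set_size=4, correct=True, response_time=1.5)

    def test_fully_inside_maintenance(self):
        assert assign_period(BurstEvent(3.1, 3.4, 1.0), self.trial) == "maintenance"

    def test_boundary_80_percent_inclusive(self):
        assert assign_period(BurstEvent(2.9, 3.4, 1.0), self.trial) == "maintenance"

    def test_straddling_unassigned(self):
        assert assign_period(BurstEvent(2.75, 3.25, 1.0), self.trial) is None

    def test_probe_right_edge_is_response(self):
        trial = Trial(trial_id=0, set_size=4, correct=True, response_time=0.5)
        # event extends past probe end (6.5): only 50% inside the probe period
        assert assign_period(BurstEvent(6.2, 7.2, 1.0), trial) is None
        assert assign_period(BurstEvent(6.1, 6.4, 1.0), trial) == "probe"


class TestSparsity:
    def test_one_hot_zero(self):
        w = np.zeros(10)
        w[3] = 5.0
        assert sparsity(w) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_uniform_one(self, n):
        assert sparsity(np.full(n, 3.3)) == pytest.approx(1.0)

    def test_hand_value(self):
        assert sparsity([3.0, 1.0]) == pytest.approx(0.6396, abs=1e-4)

    def test_scale_invariance_and_bounds(self, rng):
        w = rng.uniform(0.1, 5, size=12)
        assert sparsity(w) == pytest.approx(sparsity(10 * w))
        assert 0.0 <= sparsity(w) <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sparsity([1.0])
        with pytest.raises(ValueError):
            sparsity([0.0, 0.0])


class TestWeightedLvr:
    def test_constant_lvr_identity(self):
        assert burst_weighted_lvr([0.7, 0.7, 0.7], [1, 5, 2]) == pytest.approx(0.7)

    def test_zero_weight_excluded(self):
        assert burst_weighted_lvr([0.4, 1.6], [1.0, 0.0]) == pytest.approx(0.4)

    def test_hand_weighted_mean(self):
        assert burst_weighted_lvr([1.0, 2.0], [1.0, 3.0]) == pytest.approx(1.75)

    def test_missing_lvr_renormalized(self):
        assert burst_weighted_lvr([np.nan, 2.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_all_missing_is_nan(self):
        assert np.isnan(burst_weighted_lvr([np.nan], [1.0]))


class TestBurstComposition:
    def test_single_active_unit(self):
        t = np.arange(0, 801) * 0.01
        rates = np.zeros((3, 801))
        rates[1, 300:350] = 4.0
        series = PopulationRateSeries(times=t, unit_rates=rates, unit_ids=list("abc"))
        w = burst_composition(BurstEvent(3.0, 3.5, 4.0), series)
        assert w[1] > 0 and w[0] == 0 and w[2] == 0


class TestBurstDensity:
    def test_no_bursts_all_zero(self):
        trials = [
            Trial(trial_id=j, set_size=4, correct=True, response_time=1.0)
            for j in range(5)
        ]
        den = burst_density({}, trials, n_boot=50, rng=np.random.default_rng(0))
        assert np.all(den.density == 0)
        assert np.all(den.ci_high == 0)

    def test_single_trial_ci_width_zero(self):
        trials = [Trial(trial_id=0, set_size=4, correct=True, response_time=1.0)]
        events = {0: [BurstEvent(2.0, 2.3, 5.0)]}
        den = burst_density(events, trials, n_boot=50, rng=np.random.default_rng(0))
        assert np.all(den.ci_high - den.ci_low == 0)
        assert den.density.max() == 1.0

    def test_point_estimate_within_ci(self, rng):
        trials = [
            Trial(trial_id=j, set_size=4, correct=True, response_time=1.0)
            for j in range(20)
        ]
        events = {
            j: [BurstEvent(float(rng.uniform(1, 6)), 0.0, 5.0)] for j in range(20)
        }
        for j in events:
            events[j][0].end = events[j][0].start + 0.2
        den = burst_density(events, trials, n_boot=200, rng=rng)
        assert np.all(den.ci_low - 1e-12 <= den.density)
        assert np.all(den.density <= den.ci_high + 1e-12)

    def test_response_alignment_drops_slow_trials(self):
        trials = [
            Trial(trial_id=0, set_size=4, correct=True, response_time=2.5),
            Trial(trial_id=1, set_size=4, correct=True, response_time=1.0),
        ]
        den = burst_density({}, trials, align="response", n_boot=10,
                            rng=np.random.default_rng(0))
        assert den.n_trials == 1

    def test_probe_burst_gain_density_peak_after_probe(self):
        cfg = GeneratorConfig(
            n_trials=25, units_per_region=5, probe_burst_gain=4.0, seed=51
        )
        s, _ = synth_session(cfg, np.random.default_rng(51))
        amy = s.subset_units(
            [u.unit_id for u in s.units if u.region in ("amygdala", "entorhinal")]
        )
        events = session_bursts(amy, annotate=False)
        den = burst_density(events, amy.trials, n_boot=50,
                            rng=np.random.default_rng(0))
        after = den.density[(den.times >= 6.0) & (den.times <= 7.0)]
        before = den.density[(den.times >= 4.0) & (den.times <= 5.5)]
        assert after.max() > before.max()
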