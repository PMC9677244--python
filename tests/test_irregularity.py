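import numpy as np
import pytest

from spikewm.irregularity import (
    LOGIT_SCHEDULE,
    adapt_logit,
    change_points,
    combine_trains,
    cp_lvr_correlation,
    lvr,
    lvr_gated,
    partial_correlation_lvr_rt,
    permutation_null,
    pearson_statistic,
    rank_dissimilarity,
    sliding_lvr,
    subsampled_combination_test,
    timeresolved_rt_correlation,
    window_right_edges,
)
from spikewm.synthgen import (
    GeneratorConfig,
    RateProfile,
    gamma_renewal_train,
    inhomogeneous_train,
    synth_session,
)


class TestLvR:
    def test_regular_train_is_zero(self):
        assert lvr([0.2] * 10, R_s=0.005) == pytest.approx(0.0)

    def test_hand_value_no_refractoriness(self):
        assert lvr([0.1, 0.2], R_s=0.0) == pytest.approx(1 / 3)

    def test_hand_value_with_refractoriness(self):
        assert lvr([0.1, 0.2], R_s=0.005) == pytest.approx(0.35556, abs=1e-5)

    def test_scale_invariance(self, rng):
        """Scaling all ISIs and R by a constant leaves LvR unchanged."""
        isis = rng.exponential(0.2, size=50)
        for c in (0.1, 3.0, 40.0):
            assert lvr(isis * c, R_s=0.005 * c) == pytest.approx(
                lvr(isis, R_s=0.005)
            )

    def test_errors(self):
        with pytest.raises(ValueError):
            lvr([0.1])
        with pytest.raises(ValueError):
            lvr([0.1, 0.0, 0.2])

    def test_gate(self):
        assert np.isnan(lvr_gated([0.1, 0.2, 0.3, 0.4]))
        assert lvr_gated(np.linspace(1, 3, 5)) == pytest.approx(0.0)

    def test_poisson_lvr_near_one(self, rng):
        vals = [
            lvr_gated(gamma_renewal_train(5.0, 1.0, 8.0, rng), R_s=0.0)
            for _ in range(500)
        ]
        assert np.nanmean(vals) == pytest.approx(1.0, abs=0.05)


class TestCombineTrains:
    def test_interleaved_regular_trains(self):
        a = np.arange(0.1, 8, 0.2)
        b = a + 0.1
        merged = combine_trains([a, b])
        assert lvr_gated(merged, R_s=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_merge_with_empty(self):
        a = np.array([1.0, 2.0])
        np.testing.assert_array_equal(combine_trains([a, np.empty(0)]), a)

    def test_duplicates_collapsed(self):
        merged = combine_trains([np.array([1.0, 2.0]), np.array([2.0, 3.0])])
        np.testing.assert_array_equal(merged, [1.0, 2.0, 3.0])

    def test_poisson_superposition_stays_poisson(self, rng):
        vals = []
        for _ in range(300):
            merged = combine_trains(
                [gamma_renewal_train(4.0, 1.0, 8.0, rng) for _ in range(3)]
            )
            vals.append(lvr_gated(merged, R_s=0.0))
        assert np.nanmean(vals) == pytest.approx(1.0, abs=0.05)


class TestSlidingLvR:
    def test_window_grid_arithmetic(self):
        edges = window_right_edges(2.0, 0.25, 0.0, 8.0)
        assert edges.size == 25
        assert edges[0] == pytest.approx(2.0) and edges[-1] == pytest.approx(8.0)

    def test_regular_train_all_zero(self):
        series = sliding_lvr(np.arange(0.05, 8, 0.1), 2.0, 0.5, R_s=0.0)
        assert np.allclose(series.values, 0.0)

    def test_silent_start_gated(self):
        t = np.arange(3.5, 8, 0.1)
        series = sliding_lvr(t, 2.0, 0.5)
        assert np.all(np.isnan(series.values[series.times <= 3.0]))


class TestChangePoints:
    def test_regular_train_no_cps(self):
        res = change_points(np.arange(0.05, 8, 0.1), (0.0, 8.0), logit=1.3)
        assert res.times == []

    def test_step_detected_and_localized(self, rng):
        hits = 0
        for _ in range(40):
            t = inhomogeneous_train(
                RateProfile(np.array([0.0, 4.0, 8.0]), np.array([2.0, 10.0])),
                4.0,
                rng,
            )
            res = change_points(t, (0.0, 8.0), logit=2.5)
            if any(abs(c - 4.0) <= 0.3 for c in res.times):
                hits += 1
        assert hits >= 32  # >= 80% at modest n; the full benchmark is stricter

    def test_cp_times_increasing_within_window(self, rng):
        t = gamma_renewal_train(10.0, 0.5, 8.0, rng)
        res = change_points(t, (0.0, 8.0), logit=1.3)
        assert all(0 <= c < 8 for c in res.times)
        assert all(a < b for a, b in zip(res.times, res.times[1:]))

    def test_empty_window(self):
        assert change_points(np.empty(0), (0.0, 8.0), 1.3).times == []

    def test_adaptation_clears_fixation(self, rng):
        trains = [gamma_renewal_train(8.0, 0.6, 1.0, rng) for _ in range(40)]
        logit = adapt_logit(trains)
        assert logit in LOGIT_SCHEDULE
        for t in trains:
            assert change_points(t, (0.0, 1.0), logit).times == []


class TestCpLvrCorrelation:
    def test_shape_diverse_cohort_positive_r(self):
        cfg = GeneratorConfig(
            n_trials=25,
            units_per_region=4,
            gamma_shape_range=(0.4, 3.0),
            probe_burst_gain=1.0,
            seed=31,
        )
        s, _ = synth_session(cfg, np.random.default_rng(31))
        res = cp_lvr_correlation([s])
        # burstier (high-LvR) units produce more detected change points
        rs = [d["r"] for d in res.values() if np.isfinite(d["r"])]
        assert len(rs) > 0 and np.mean(rs) > 0

    def test_two_units_insufficient(self):
        cfg = GeneratorConfig(n_trials=8, units_per_region=1, seed=1)
        s, _ = synth_session(cfg, np.random.default_rng(1))
        sub = s.subset_units(s.unit_ids[:2])
        res = cp_lvr_correlation([sub])
        assert all(np.isnan(d["r"]) for d in res.values())


class TestRankDissimilarity:
    def test_identical_multisets_zero(self):
        v = [1.0, 2.0, 1.0, 2.0]
        assert rank_dissimilarity(v, ["A", "A", "B", "B"], "A") == pytest.approx(0.0)

    def test_hand_case(self):
        stat = rank_dissimilarity(
            [0.5, 0.9, 1.2, 1.4], ["B", "B", "A", "A"], "A"
        )
        assert stat == pytest.approx(-2.0)

    def test_label_swap_antisymmetry(self, rng):
        v = rng.normal(size=30)
        lab = np.array(["A"] * 12 + ["B"] * 18)
        s1 = rank_dissimilarity(v, lab, "A")
        s2 = rank_dissimilarity(v, lab, "B")
        assert s1 == pytest.approx(-s2)

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=40)
        lab = np.where(rng.uniform(size=40) < 0.4, "A", "B")
        s1 = rank_dissimilarity(v, lab, "A")
        s2 = rank_dissimilarity(np.exp(3 * v), lab, "A")
        assert s1 == pytest.approx(s2)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            rank_dissimilarity([1.0, 2.0], ["A", "A"], "A")


class TestPermutationNull:
    def test_constant_statistic_p_one(self, rng):
        _, p, _ = permutation_null(
            lambda vars_: 1.0, [np.arange(10)], n_perm=99, rng=rng
        )
        assert p == pytest.approx(1.0)

    def test_null_p_super_uniform(self, rng):
        """p-values under a label-independent null are approximately uniform."""
        ps = []
        for _ in range(100):
            y = rng.normal(size=24)
            x = rng.normal(size=24)

            def stat(vars_):
                return float(np.corrcoef(y, vars_[0])[0, 1])

            _, p, _ = permutation_null(stat, [x], n_perm=49, rng=rng)
            ps.append(p)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.12

    def test_strong_effect_small_p(self, rng):
        y = np.arange(40.0)

        def stat(vars_):
            return float(np.corrcoef(y, vars_[0])[0, 1])

        _, p, _ = permutation_null(stat, [y + rng.normal(size=40)], n_perm=999, rng=rng)
        assert p <= 0.005


class TestSubsampledCombination:
    def test_null_cohort_median_p_not_small(self, rng):
        values = rng.normal(size=60)
        trial_idx = rng.integers(0, 20, size=60)
        rts = [rng.normal(size=20)]
        med, ps = subsampled_combination_test(
            [(values, trial_idx)],
            [30],
            pearson_statistic,
            rts,
            n_subsamples=20,
            n_perm=49,
            rng=rng,
        )
        assert med >= 0.05
        assert ps.size == 20

    def test_no_points_raises(self, rng):
        with pytest.raises(ValueError):
            subsampled_combination_test(
                [(np.empty(0), np.empty(0, dtype=int))],
                [5],
                pearson_statistic,
                [np.arange(5)],
                n_subsamples=2,
                n_perm=9,
                rng=rng,
            )


class TestTimeResolvedCorrelation:
    def test_coupling_yields_positive_maintenance_r(self):
        cfg = GeneratorConfig(
            n_trials=40,
            units_per_region=2,
            rt_lvr_coupling=0.5,
            probe_burst_gain=1.0,
            seed=41,
        )
        s, _ = synth_session(cfg, np.random.default_rng(41))
        res = timeresolved_rt_correlation(
            [s], step_s=0.5, n_perm=99, rng=np.random.default_rng(0)
        )
        sig_pos = 0
        for region, d in res.items():
            mask = (d["times"] >= 5.0) & (d["times"] <= 6.0)  # windows within maintenance
            sig_pos += np.sum((d["r"][mask] > 0) & (d["p"][mask] < 0.05))
        assert sig_pos > 0

    def test_constant_rt_reported_missing(self):
        cfg = GeneratorConfig(n_trials=10, units_per_region=2, seed=5)
        s, _ = synth_session(cfg, np.random.default_rng(5))
        s.trials = [
            type(t)(t.trial_id, t.set_size, t.correct, 1.0) for t in s.trials
        ]
        res = timeresolved_rt_correlation(
            [s], step_s=1.0, n_perm=19, rng=np.random.default_rng(0)
        )
        for d in res.values():
            assert np.all(np.isnan(d["r"]))


class TestPartialCorrelation:
    def test_rate_independent_partial_equals_raw(self, rng):
        x = rng.normal(size=300)
        y = 0.6 * x + rng.normal(size=300)
        z = rng.normal(size=300)
        raw = np.corrcoef(x, y)[0, 1]
        assert partial_correlation_lvr_rt(x, y, z) == pytest.approx(raw, abs=0.05)

    def test_rate_driven_rt_partials_out(self, rng):
        z = rng.normal(size=400)
        y = z + 0.05 * rng.normal(size=400)  # RT a near-pure function of rate
        x = rng.normal(size=400)             # LvR independent
        assert abs(partial_correlation_lvr_rt(x, y, z)) < 0.15

    def test_too_few_triples(self):
        with pytest.raises(ValueError):
            partial_correlation_lvr_rt([1, 2, 3], [1, 2, 3], [1, 2, 3])
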