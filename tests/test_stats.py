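"""Magnitude, correlation, suppression and behavioral statistics."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from popmag.pseudopop import Pseudopopulation, align_sessions
from popmag.stats import (
    bin_behavior_for_plot,
    exclude_top_rate_units,
    grand_mean_rate,
    l2_magnitude,
    magnitude_memorability_correlation,
    point_biserial,
    repetition_suppression,
    window_sweep,
)
from popmag.synthetic import GeneratorConfig, generate_behavior, generate_sessions


def _simple_pop(response, memorability):
    response = np.asarray(response, dtype=float)
    n_slots, n_units = response.shape
    return Pseudopopulation(
        response=response,
        memorability=np.asarray(memorability, dtype=float),
        n_back=np.ones(n_slots, dtype=int),
        window_ms=(180.0, 260.0),
        unit_ids=[f"u{i}" for i in range(n_units)],
        unit_sessions=["s0"] * n_units,
    )


class TestL2Magnitude:
    def test_all_zero_vector_has_zero_magnitude(self):
        assert l2_magnitude(np.zeros(10)) == 0.0

    def test_pythagorean_pair(self):
        assert l2_magnitude([3.0, 4.0]) == pytest.approx(5.0)

    def test_matches_bruteforce_square_sum_sqrt_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(3.0, size=707).astype(float)
        oracle = np.sqrt(sum(v * v for v in x))
        assert l2_magnitude(x) == pytest.approx(oracle, rel=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            l2_magnitude(np.array([]))

    @given(
        x=hnp.arrays(float, 12, elements=st.floats(0, 100)),
        y=hnp.arrays(float, 12, elements=st.floats(0, 100)),
        c=st.floats(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_homogeneity_and_triangle_inequality(self, x, y, c):
        assert l2_magnitude(c * x + 1e-12) <= c * l2_magnitude(x + 1e-12) + 1e-6
        assert l2_magnitude(x + y + 1e-12) <= (
            l2_magnitude(x + 1e-12) + l2_magnitude(y + 1e-12) + 1e-6
        )


class TestMagnitudeCorrelation:
    def test_affine_increasing_magnitudes_give_perfect_correlation(self):
        m = np.linspace(0.1, 0.9, 20)
        response = np.outer(2.0 + 3.0 * m, np.ones(5))  # magnitude affine in m
        res = magnitude_memorability_correlation(_simple_pop(response, m))
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-20

    def test_correlation_invariant_to_unit_and_slot_permutation(self, tiny_sessions):
        pop = align_sessions([(s, np.arange(s.n_units)) for s in tiny_sessions])
        base = magnitude_memorability_correlation(pop)
        rng = np.random.default_rng(1)
        uperm = rng.permutation(pop.n_units)
        sperm = rng.permutation(pop.n_slots)
        shuffled = _simple_pop(pop.response[sperm][:, uperm], pop.memorability[sperm])
        res = magnitude_memorability_correlation(shuffled)
        assert res.r == pytest.approx(base.r, rel=1e-12)

    def test_zero_variance_magnitudes_rejected(self):
        pop = _simple_pop(np.ones((5, 3)), np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            magnitude_memorability_correlation(pop)

    def test_novel_and_familiar_splits_both_positive_under_coupling(self):
        cfg = GeneratorConfig(n_sessions=1, units_per_session=(250,),
                              images_per_session=70, magnitude_coupling=2.0,
                              completion_prob=1.0, seed=41)
        sess = generate_sessions(cfg)[0]
        pop = align_sessions([(sess, np.arange(250))])
        r_novel = sps.pearsonr(pop.memorability, l2_magnitude(pop.novel)).statistic
        r_familiar = sps.pearsonr(pop.memorability, l2_magnitude(pop.familiar)).statistic
        assert r_novel > 0.3 and r_familiar > 0.3


class TestGrandMeanRate:
    def test_uniform_counts_convert_to_rate_by_window_duration(self):
        pop = _simple_pop(np.full((4, 6), 2.0), [0.1, 0.2, 0.3, 0.9])
        with pytest.raises(ValueError):
            grand_mean_rate(pop)  # zero variance in rates
        pop = _simple_pop(np.outer([1, 2, 3, 4], np.ones(6)), [0.1, 0.2, 0.3, 0.9])
        res = grand_mean_rate(pop)  # 80 ms window
        np.testing.assert_allclose(res.rates, np.array([1, 2, 3, 4]) / 0.08)

    def test_doubling_counts_doubles_the_rate(self):
        m = np.linspace(0, 1, 6)
        resp = np.outer(1 + m, np.ones(3))
        r1 = grand_mean_rate(_simple_pop(resp, m))
        r2 = grand_mean_rate(_simple_pop(2 * resp, m))
        np.testing.assert_allclose(r2.rates, 2 * r1.rates)

    def test_rate_and_magnitude_rank_correlate_but_differ(self, tiny_sessions):
        pop = align_sessions([(s, np.arange(s.n_units)) for s in tiny_sessions])
        mag = magnitude_memorability_correlation(pop).magnitudes
        rate = grand_mean_rate(pop).rates
        rho = sps.spearmanr(mag, rate).statistic
        assert rho > 0.9
        assert not np.allclose(np.argsort(mag), np.argsort(rate))


class TestUnitExclusion:
    def test_zero_fraction_is_identity(self, tiny_sessions):
        pop = align_sessions([(s, np.arange(s.n_units)) for s in tiny_sessions])
        assert exclude_top_rate_units(pop, 0.0) is pop

    def test_ceiling_arithmetic_drops_the_right_count(self):
        pop = _simple_pop(np.arange(50, dtype=float).reshape(5, 10), np.linspace(0, 1, 5))
        assert exclude_top_rate_units(pop, 0.25).n_units == 7

    def test_dropped_units_are_the_highest_rate_ones(self):
        response = np.tile(np.arange(1.0, 7.0), (4, 1))
        response += np.linspace(0, 1, 4)[:, None]  # keep slot variance
        pop = _simple_pop(response, np.linspace(0.1, 0.9, 4))
        reduced = exclude_top_rate_units(pop, 0.34)  # ceil(0.34*6) = 3
        assert reduced.unit_ids == ["u0", "u1", "u2"]

    def test_coupled_correlation_survives_high_rate_exclusion(self):
        cfg = GeneratorConfig(n_sessions=1, units_per_session=(200,),
                              images_per_session=60, magnitude_coupling=2.0,
                              completion_prob=1.0, seed=43)
        sess = generate_sessions(cfg)[0]
        pop = align_sessions([(sess, np.arange(200))])
        res = magnitude_memorability_correlation(exclude_top_rate_units(pop, 0.1))
        assert res.r > 0.4

    def test_fraction_of_one_rejected(self, tiny_sessions):
        pop = align_sessions([(s, np.arange(s.n_units)) for s in tiny_sessions])
        with pytest.raises(ValueError):
            exclude_top_rate_units(pop, 1.0)


class TestRepetitionSuppression:
    def test_identical_matrices_give_zero_suppression(self):
        x = np.random.default_rng(0).poisson(3.0, size=(20, 10)).astype(float)
        assert repetition_suppression(x, x) == 0.0

    def test_ten_percent_elementwise_reduction_recovered_exactly(self):
        x = np.random.default_rng(0).poisson(5.0, size=(20, 10)).astype(float) + 1
        assert repetition_suppression(x, 0.9 * x) == pytest.approx(0.10)
        assert repetition_suppression(x, 0.9 * x, per_unit=True) == pytest.approx(0.10)

    def test_zero_novel_grand_mean_rejected(self):
        with pytest.raises(ValueError):
            repetition_suppression(np.zeros((3, 3)), np.ones((3, 3)))

    def test_generator_suppression_recovered_within_sampling_error(self):
        cfg = GeneratorConfig(n_sessions=1, units_per_session=(300,),
                              images_per_session=80, completion_prob=1.0, seed=47)
        sess = generate_sessions(cfg)[0]
        pop = align_sessions([(sess, np.arange(300))])
        est = repetition_suppression(pop.novel, pop.familiar)
        assert est == pytest.approx(0.06, abs=0.02)


class TestPointBiserial:
    def test_hand_computed_four_point_example(self):
        r, p = point_biserial([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert r == pytest.approx(0.4472, abs=1e-4)

    def test_equals_pearson_on_zero_one_encoding_to_machine_precision(self):
        rng = np.random.default_rng(5)
        x = rng.random(400)
        y = (rng.random(400) < 0.5 + 0.3 * (x - 0.5)).astype(int)
        r, p = point_biserial(x, y)
        r_ref, p_ref = sps.pearsonr(x, y.astype(float))
        assert r == pytest.approx(r_ref, abs=1e-13)
        assert p == pytest.approx(p_ref, rel=1e-9)
        r_pb, p_pb = sps.pointbiserialr(y, x)
        assert r == pytest.approx(r_pb, abs=1e-13)

    def test_median_split_outcomes_give_strong_correlation(self):
        rng = np.random.default_rng(9)
        x = rng.random(1000)
        y = (x > np.median(x)).astype(int)
        r, p = point_biserial(x, y)
        assert r > 0.8 and p < 1e-100

    def test_independent_outcomes_give_null_correlation(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(50):
            x = rng.random(200)
            y = rng.integers(0, 2, size=200)
            rs.append(point_biserial(x, y)[0])
        ci = sps.t.interval(0.95, 49, loc=np.mean(rs), scale=sps.sem(rs))
        assert ci[0] <= 0 <= ci[1]

    def test_single_class_outcomes_rejected(self):
        with pytest.raises(ValueError):
            point_biserial([0.1, 0.5, 0.9], [1, 1, 1])


@pytest.fixture(scope="module")
def coupled_pop():
    cfg = GeneratorConfig(n_sessions=4, units_per_session=(25,) * 4,
                          images_per_session=63, magnitude_coupling=2.0,
                          image_gain_sd=0.1, completion_prob=1.0, seed=51)
    sessions = generate_sessions(cfg)
    return align_sessions(
        [(s, np.arange(s.n_units)) for s in sessions], keep_bins=True
    )


@pytest.fixture(scope="module")
def session_behavior():
    cfg = GeneratorConfig(n_sessions=8, units_per_session=(2,) * 8,
                          images_per_session=70, completion_prob=1.0,
                          behavioral_ceiling=1.0, seed=53)
    return generate_behavior(generate_sessions(cfg))


class TestWindowSweep:
    def test_coupling_emerges_only_after_the_evoked_latency(self, coupled_pop):
        sweep = window_sweep(coupled_pop, window_length_ms=80.0, step_ms=20.0)
        pre = sweep[sweep.window_end_ms <= 0]
        evoked = sweep[sweep.window_start_ms >= 100]
        assert pre["r"].abs().max() < 0.35
        assert evoked["r"].min() > 0.45

    def test_nonoverlapping_windows_tile_the_trial_period(self, coupled_pop):
        sweep = window_sweep(coupled_pop, window_length_ms=100.0, step_ms=100.0)
        assert len(sweep) == 6  # floor(600 / 100)
        assert sweep["window_start_ms"].iloc[0] == -200.0

    def test_unbinnable_window_rejected(self, coupled_pop):
        with pytest.raises(ValueError):
            window_sweep(coupled_pop, window_length_ms=50.0)

    def test_zero_variance_window_reports_missing_not_error(self):
        a = _simple_pop(np.ones((4, 2)), [0.1, 0.3, 0.6, 0.9])
        a.novel_binned = np.zeros((4, 2, 3))
        a.familiar_binned = np.zeros((4, 2, 3))
        a.bin_edges_ms = np.array([0.0, 20.0, 40.0, 60.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            sweep = window_sweep(a, window_length_ms=20.0)
        assert sweep["r"].isna().all()


class TestBehaviorBinning:
    def test_single_bin_equals_the_grand_mean(self, session_behavior):
        behavior = session_behavior
        binned = bin_behavior_for_plot(behavior, 1)
        assert len(binned) == 1
        assert binned["performance"].iloc[0] == binned["grand_mean"].iloc[0]
        assert binned["performance"].iloc[0] == pytest.approx(
            behavior["correct"].mean()
        )

    def test_monotone_link_gives_increasing_bin_means(self, session_behavior):
        binned = bin_behavior_for_plot(session_behavior, 5)
        assert binned["memorability"].is_monotonic_increasing
        assert (np.diff(binned["performance"]) > -0.05).all()
        assert binned["performance"].iloc[-1] > binned["performance"].iloc[0] + 0.2

    def test_flat_link_keeps_bins_near_the_grand_mean(self):
        cfg = GeneratorConfig(n_sessions=10, units_per_session=(2,) * 10,
                              images_per_session=70, completion_prob=1.0,
                              behavioral_ceiling=0.5, seed=55)
        behavior = generate_behavior(generate_sessions(cfg))
        binned = bin_behavior_for_plot(behavior, 5)
        assert (binned["performance"] - binned["grand_mean"]).abs().max() < 0.1

    def test_more_bins_than_images_rejected(self, session_behavior):
        with pytest.raises(ValueError):
            bin_behavior_for_plot(session_behavior, 10_000)
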