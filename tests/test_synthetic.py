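"""Generator invariants: determinism, pairing, coupling, behavior."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from popmag.pseudopop import align_sessions
from popmag.stats import magnitude_memorability_correlation
from popmag.synthetic import (
    GeneratorConfig,
    generate_behavior,
    generate_layer_activations,
    generate_sessions,
    generate_test_images,
)


def _pooled_r(beta: float, seed: int, units: int = 150, images: int = 60) -> float:
    cfg = GeneratorConfig(
        n_sessions=1,
        units_per_session=(units,),
        images_per_session=images,
        magnitude_coupling=beta,
        completion_prob=1.0,
        seed=seed,
    )
    sess = generate_sessions(cfg)[0]
    pop = align_sessions([(sess, np.arange(units))])
    return magnitude_memorability_correlation(pop).r


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sessions": 0},
            {"units_per_session_mean": -1},
            {"images_per_session": 0},
            {"magnitude_coupling": -0.5},
            {"suppression_fraction": 1.0},
            {"behavioral_ceiling": 0.4},
            {"noise_model": "gaussian"},
            {"bin_width_ms": 7.0},  # does not tile the 600 ms trial window
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_bin_edges_tile_trial_window_half_open(self):
        cfg = GeneratorConfig()
        edges = cfg.bin_edges_ms
        assert edges[0] == cfg.trial_window_ms[0]
        assert edges[-1] == cfg.trial_window_ms[1]
        assert np.allclose(np.diff(edges), cfg.bin_width_ms)


class TestSessionStructure:
    def test_same_seed_gives_bit_identical_sessions(self):
        cfg = GeneratorConfig(n_sessions=2, units_per_session=(6, 7),
                              images_per_session=21, seed=5)
        a = generate_sessions(cfg)
        b = generate_sessions(cfg)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.counts, sb.counts)
            pd.testing.assert_frame_equal(sa.trials, sb.trials)
            pd.testing.assert_frame_equal(sa.images, sb.images)

    def test_every_familiar_trial_has_one_earlier_novel_partner(self, tiny_sessions):
        for sess in tiny_sessions:
            t = sess.trials
            novel_pos = t[t.exposure == "novel"].set_index("image_id")["trial_index"]
            fam = t[t.exposure == "familiar"]
            assert fam["image_id"].is_unique
            assert (t.groupby("image_id").size() == 2).all()
            # exact separation: n_back intervening trial positions
            sep = fam["trial_index"].to_numpy() - novel_pos.loc[fam["image_id"]].to_numpy()
            assert np.array_equal(sep, fam["n_back"].to_numpy() + 1)

    def test_nback_counts_cover_all_configured_levels(self, tiny_sessions):
        cfg = tiny_sessions[0].config
        for sess in tiny_sessions:
            fam = sess.trials[sess.trials.exposure == "familiar"]
            counts = fam["n_back"].value_counts()
            assert set(counts.index) == set(cfg.n_back_levels)
            # 28 completed pairs over 7 levels: exactly 4 per level
            assert (counts == 4).all()

    def test_counts_are_nonnegative_integers(self, tiny_sessions):
        for sess in tiny_sessions:
            assert np.issubdtype(sess.counts.dtype, np.integer)
            assert (sess.counts >= 0).all()

    def test_suppression_reduces_familiar_evoked_counts(self):
        cfg = GeneratorConfig(n_sessions=1, units_per_session=(120,),
                              images_per_session=80, completion_prob=1.0,
                              suppression_fraction=0.2, seed=3)
        sess = generate_sessions(cfg)[0]
        win = sess.window_counts((80.0, 400.0))
        fam = (sess.trials.exposure == "familiar").to_numpy()
        reduction = 1 - win[fam].mean() / win[~fam].mean()
        assert reduction == pytest.approx(0.2, abs=0.03)


class TestCoupling:
    def test_no_coupling_gives_null_correlation(self):
        rs = [_pooled_r(0.0, seed) for seed in range(12)]
        # 95% CI of the mean across replicate generations covers 0
        ci = sps.t.interval(0.95, len(rs) - 1, loc=np.mean(rs),
                            scale=sps.sem(rs))
        assert ci[0] <= 0 <= ci[1]

    def test_strong_coupling_recovers_positive_correlation(self):
        rs = [_pooled_r(2.0, seed, units=300, images=80) for seed in range(3)]
        assert min(rs) > 0.5

    def test_recovered_r_monotone_in_coupling_strength(self):
        betas = [0.0, 0.5, 1.0, 2.0]
        means = [np.mean([_pooled_r(b, s) for s in range(6)]) for b in betas]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestBehavior:
    def test_zero_memorability_gives_chance_performance(self):
        cfg = GeneratorConfig(n_sessions=4, units_per_session=(2,) * 4,
                              images_per_session=105, completion_prob=1.0,
                              memorability_scores=(0.0,) * 105, seed=9)
        beh = generate_behavior(generate_sessions(cfg))
        assert beh["correct"].mean() == pytest.approx(0.5, abs=0.05)

    def test_max_memorability_at_ceiling_is_always_correct(self):
        cfg = GeneratorConfig(n_sessions=2, units_per_session=(2, 2),
                              images_per_session=35, completion_prob=1.0,
                              memorability_scores=(1.0,) * 35, seed=9)
        beh = generate_behavior(generate_sessions(cfg), behavioral_ceiling=1.0)
        assert (beh["correct"] == 1).all()

    def test_hit_rate_tracks_chance_corrected_line(self):
        scores = tuple(np.linspace(0, 1, 120))
        cfg = GeneratorConfig(n_sessions=30, units_per_session=(1,) * 30,
                              images_per_session=120, completion_prob=1.0,
                              memorability_scores=scores, seed=2)
        beh = generate_behavior(generate_sessions(cfg), behavioral_ceiling=0.9)
        lo = beh[beh.memorability < 0.2]["correct"].mean()
        hi = beh[beh.memorability > 0.8]["correct"].mean()
        assert lo == pytest.approx(0.5 + 0.1 * 0.4, abs=0.05)
        assert hi == pytest.approx(0.5 + 0.9 * 0.4, abs=0.05)

    def test_ceiling_outside_range_rejected(self, tiny_sessions):
        with pytest.raises(ValueError):
            generate_behavior(tiny_sessions, behavioral_ceiling=1.2)

    def test_behavior_stream_does_not_perturb_counts(self, tiny_sessions):
        before = tiny_sessions[0].counts.copy()
        generate_behavior(tiny_sessions)
        assert np.array_equal(tiny_sessions[0].counts, before)


class TestLayerActivations:
    def test_identical_seeds_and_betas_give_identical_profiles(self):
        a, _ = generate_layer_activations(50, 3, [0.5, 1.0, 1.5], seed=4)
        b, _ = generate_layer_activations(50, 3, [0.5, 1.0, 1.5], seed=4)
        assert np.array_equal(a.magnitudes, b.magnitudes)

    def test_uncoupled_condition_has_null_correlation_everywhere(self):
        _, unc = generate_layer_activations(4000, 3, [0.5, 1.0, 1.5], seed=4)
        for l in range(3):
            r, _ = sps.pearsonr(unc.memorability, unc.magnitudes[:, l])
            assert abs(r) < 0.05

    def test_correlation_nondecreasing_when_coupling_grows_by_layer(self):
        coupled, _ = generate_layer_activations(6000, 4, [0.2, 0.6, 1.2, 2.0], seed=8)
        rs = [
            sps.pearsonr(coupled.memorability, coupled.magnitudes[:, l])[0]
            for l in range(4)
        ]
        assert all(b > a - 0.02 for a, b in zip(rs, rs[1:]))
        assert rs[-1] > rs[0] + 0.2

    def test_mismatched_coupling_length_rejected(self):
        with pytest.raises(ValueError):
            generate_layer_activations(10, 3, [0.5], seed=0)


class TestImages:
    def test_zero_requested_images_gives_empty_set(self):
        assert generate_test_images(0) == []

    def test_undersized_images_rejected(self):
        with pytest.raises(ValueError):
            generate_test_images(1, side=128)

    def test_images_are_uint8_rgb_and_deterministic(self):
        a = generate_test_images(4, seed=3)
        b = generate_test_images(4, seed=3)
        for ia, ib in zip(a, b):
            assert ia.shape == (256, 256, 3) and ia.dtype == np.uint8
            assert np.array_equal(ia, ib)

    def test_second_image_is_mirror_symmetric(self):
        img = generate_test_images(2, seed=3)[1]
        assert np.array_equal(img, img[:, ::-1])
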