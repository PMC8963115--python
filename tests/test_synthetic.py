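"""The synthetic study generator: panel, ratings, frames, signals."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats as spstats

from cyresick.biosignals import detect_qrs, hrv_features, relative_band_power
from cyresick.scenes import Scene
from cyresick.synthetic import (
    EffectConfig,
    gen_ecg,
    gen_eeg,
    gen_gsr,
    gen_panel,
    gen_scores,
    gen_ssq,
    render_scene_motion,
    scene_severity,
)


def _scene(components, **kwargs):
    base = dict(
        scene_id="T01", background="urban", movement_class="complex",
        components=frozenset(components), translation_speed="moderate_4mps",
        category="CUU",
    )
    base.update(kwargs)
    return Scene(**base)


class TestPanel:
    def test_study_scale_mix(self, full_panel):
        counts = Counter((p.group, p.sex) for p in full_panel)
        assert counts == {
            ("young", "man"): 43, ("young", "woman"): 63,
            ("middle_aged", "man"): 28, ("middle_aged", "woman"): 20,
        }

    def test_deterministic_under_seed(self):
        assert gen_panel(10, seed=3) == gen_panel(10, seed=3)
        assert gen_panel(10, seed=3) != gen_panel(10, seed=4)

    def test_single_participant(self):
        (p,) = gen_panel(1, seed=0)
        assert p.participant_id == "P001"
        assert p.group in ("young", "middle_aged")

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            gen_panel(0)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            gen_panel(10, group_mix={("young", "man"): 0.7})


class TestScores:
    def test_entries_in_range_and_deterministic(self, study_scores):
        scores, _ = study_scores
        assert scores.to_numpy().min() >= 1
        assert scores.to_numpy().max() <= 5
        assert scores.shape == (154, 52)

    def test_same_seed_reproduces(self, small_panel, scene_table):
        a, _ = gen_scores(small_panel, scene_table, seed=9)
        b, _ = gen_scores(small_panel, scene_table, seed=9)
        assert a.equals(b)

    def test_zero_weights_near_zero_noise_hit_baseline_category(
        self, small_panel, scene_table
    ):
        config = EffectConfig(
            component_weights={c: 0.0 for c in "ry rr rp tf tb tl tu td".split()},
            speed_fast_weight=0.0, acceleration_weight=0.0,
            duration_long_weight=0.0, fov_small_relief=0.0,
            frame_reference_relief=0.0, controllability_relief=0.0,
            susceptibility_weight=0.0, age_controllability_weight=0.0,
            noise_sd=1e-9,
        )
        scores, _ = gen_scores(small_panel, scene_table, config, seed=0)
        # baseline latent 1.0 sits below the first cut point at 1.5
        assert (scores.to_numpy() == 1).all()

    def test_roll_scenes_outscore_yaw_scenes(self, study_scores):
        scores, _ = study_scores
        roll = scores[["S102", "S202"]].to_numpy().mean()
        yaw = scores[["S101", "S201"]].to_numpy().mean()
        assert roll > yaw

    def test_latent_and_score_strongly_rank_correlated(
        self, small_panel, scene_table
    ):
        config = EffectConfig(noise_sd=0.3)
        scores, latent = gen_scores(small_panel, scene_table, config, seed=21)
        rho = spstats.spearmanr(
            latent.to_numpy().ravel(), scores.to_numpy().ravel()
        ).statistic
        assert rho > 0.8

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            EffectConfig(thresholds=(1.5, 1.5, 3.5, 4.5))

    def test_positive_weight_shifts_distribution_up(self, small_panel, scene_table):
        base = EffectConfig()
        heavy = base.with_(speed_fast_weight=1.2)
        fast_scenes = [s for s in scene_table if s.translation_speed == "fast_9.2mps"]
        lo, _ = gen_scores(small_panel, fast_scenes, base, seed=3)
        hi, _ = gen_scores(small_panel, fast_scenes, heavy, seed=3)
        # stochastic dominance of the emitted distribution
        for cut in range(1, 5):
            assert (hi.to_numpy() > cut).mean() >= (lo.to_numpy() > cut).mean()


class TestSSQGeneration:
    def test_tidy_shape_and_levels(self, small_panel, scene_table):
        df = gen_ssq(small_panel, scene_table, seed=2)
        assert set(df["timepoint"]) == {"rest", "post_CCU", "post_CUA", "post_CUU"}
        assert len(df) == len(small_panel) * 4
        items = df[[f"item_{i}" for i in range(1, 17)]].to_numpy()
        assert items.min() >= 0 and items.max() <= 3

    def test_post_exposure_exceeds_rest(self, full_panel, scene_table):
        df = gen_ssq(full_panel, scene_table, seed=2)
        items = [f"item_{i}" for i in range(1, 17)]
        means = df.groupby("timepoint")[items].mean().sum(axis=1)
        assert means["post_CUU"] > means["rest"]


class TestSceneMotion:
    def test_static_scene_has_zero_flow_and_frozen_frames(self):
        scene = _scene((), movement_class="complex", translation_speed="none")
        stack, fields = render_scene_motion(scene, frames=5, seed=0)
        assert all(np.allclose(f, 0) for f in fields)
        assert np.allclose(stack[0], stack[-1])

    def test_speed_scales_flow_magnitude_by_2_3(self):
        moderate = _scene({"tf"}, movement_class="simple")
        fast = _scene({"tf"}, movement_class="simple",
                      translation_speed="fast_9.2mps")
        _, f_mod = render_scene_motion(moderate, frames=8, seed=1)
        _, f_fast = render_scene_motion(fast, frames=8, seed=1)
        ratio = (np.linalg.norm(f_fast[0], axis=-1).mean()
                 / np.linalg.norm(f_mod[0], axis=-1).mean())
        assert ratio == pytest.approx(9.2 / 4, rel=1e-9)

    def test_acceleration_ramps_last_over_first_to_terminal_rate(self):
        scene = _scene({"tf"}, movement_class="simple", acceleration_rate=1.60)
        _, fields = render_scene_motion(scene, frames=30, seed=1)
        first = np.linalg.norm(fields[0], axis=-1).mean()
        last = np.linalg.norm(fields[-1], axis=-1).mean()
        assert last / first == pytest.approx(1.60, rel=1e-6)

    def test_deterministic_and_minimum_frames(self):
        scene = _scene({"rr"}, translation_speed="none")
        a, _ = render_scene_motion(scene, frames=4, seed=5)
        b, _ = render_scene_motion(scene, frames=4, seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            render_scene_motion(scene, frames=1)

    def test_roll_flow_rotates_about_center(self):
        scene = _scene({"rr"}, translation_speed="none")
        _, fields = render_scene_motion(scene, frames=3, grid=(33, 33), seed=0)
        f = fields[0]
        assert np.allclose(f[16, 16], 0, atol=1e-12)  # center pixel at rest
        assert f[16, 32, 1] > 0  # right edge moves down: +y for +x
        assert f[0, 16, 0] > 0   # top edge moves right


class TestEEG:
    def test_zero_slopes_give_level_independent_power(self):
        # without configured slopes the level does not enter the generative
        # model at all, so matched seeds give identical band powers
        config = EffectConfig(eeg_slopes={})
        for seed in (0, 1):
            a = relative_band_power(gen_eeg(1, 6, config=config, seed=seed))
            b = relative_band_power(gen_eeg(5, 6, config=config, seed=seed))
            assert np.array_equal(a.power, b.power)

    def test_configured_delta_slope_recovered(self):
        config = EffectConfig(eeg_slopes={("Fp1", "delta"): 0.03})
        means = {}
        for lvl in (1, 3, 5):
            vals = [
                relative_band_power(
                    gen_eeg(lvl, duration_s=6, config=config, seed=100 * lvl + i)
                ).get("Fp1", "delta")
                for i in range(40)
            ]
            means[lvl] = np.mean(vals)
        slope = (means[5] - means[1]) / 4
        assert slope == pytest.approx(0.03, rel=0.25)

    def test_deterministic_and_validation(self):
        a = gen_eeg(3, duration_s=5, seed=8)
        b = gen_eeg(3, duration_s=5, seed=8)
        assert np.array_equal(a.samples, b.samples)
        with pytest.raises(ValueError):
            gen_eeg(0, duration_s=5)
        with pytest.raises(ValueError):
            gen_eeg(3, duration_s=2)

    def test_blink_bursts_are_frontal_and_high_kurtosis(self):
        config = EffectConfig(blink_rate_hz=0.4)
        ep = gen_eeg(3, duration_s=13, config=config, seed=3)
        kurt = spstats.kurtosis(ep.samples, axis=1)
        assert kurt[:2].min() > 3 * max(kurt[2:].max(), 0.1)


class TestECGAndGSR:
    def test_jitter_free_train_yields_exact_hrv_zeros(self):
        ep = gen_ecg(60, rr_jitter_s=0.0, duration_s=30, seed=0)
        hrv = hrv_features(detect_qrs(ep))
        assert hrv.bpm == pytest.approx(60.0, abs=1e-9)
        assert hrv.sdnn_s == 0.0
        assert hrv.rmssd_s == 0.0

    def test_jitter_round_trip(self):
        ep = gen_ecg(72, rr_jitter_s=0.02, duration_s=60, seed=1)
        hrv = hrv_features(detect_qrs(ep))
        assert hrv.bpm == pytest.approx(72, abs=1)
        assert hrv.sdnn_s == pytest.approx(0.02, abs=0.005)

    def test_determinism_and_validation(self):
        assert np.array_equal(
            gen_ecg(80, 0.01, 10, seed=4).samples, gen_ecg(80, 0.01, 10, seed=4).samples
        )
        with pytest.raises(ValueError):
            gen_ecg(80, rr_jitter_s=-0.01)
        with pytest.raises(ValueError):
            gen_ecg(250)

    def test_gsr_mean_grows_with_level(self):
        from cyresick.biosignals import gsr_mean

        means = [
            gsr_mean(gen_gsr(level, duration_s=13, seed=6)).mean_amplitude
            for level in (1, 3, 5)
        ]
        assert means[0] < means[1] < means[2]


def test_scene_severity_ordering_follows_factor_directions(scene_table):
    config = EffectConfig()
    by_id = {s.scene_id: s for s in scene_table}
    sev = {k: scene_severity(v, config) for k, v in by_id.items()}
    assert sev["S102"] > sev["S103"] > sev["S101"]   # roll > pitch > yaw
    assert sev["S105"] > sev["S104"]                 # backward > forward
    assert sev["S112"] > sev["S110"]                 # fast > moderate
    assert sev["S116"] > sev["S110"]                 # accelerating > constant
    assert sev["S115"] < sev["S110"]                 # small FOV protective
    assert sev["S118"] < sev["S117"]                 # frame reference protective
    assert sev["S224"] > sev["S210"]                 # longer exposure worse
    assert sev["S001"] < sev["S210"]                 # controllability protective
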