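"""Cohort generator: design invariants, trajectory targets, rating structure."""

import numpy as np
import pytest

from mentakin import GeneratorParams, generate_cohort, generate_design
from mentakin import kinematics as kin
from mentakin import scoring, tables
from mentakin.errors import InvalidDesignError, ParameterError
from mentakin.synthetic import (
    EMOTION_SPEED,
    generate_ratings,
    generate_trajectory,
    ratings_from_accuracy,
)


class TestDesign:
    def test_two_subjects_are_counterbalanced(self):
        d = generate_design(2, seed=0)
        orders = {s.drug_order for s in d.subjects}
        assert orders == {("HAL", "PLA"), ("PLA", "HAL")}

    @pytest.mark.parametrize("n", [2, 5, 12, 33])
    def test_order_split_within_one(self, n):
        d = generate_design(n, seed=3)
        hal_first = sum(s.drug_order[0] == "HAL" for s in d.subjects)
        assert abs(hal_first - (n - hal_first)) <= 1
        if n % 2 == 0:
            assert hal_first == n // 2

    def test_deterministic(self):
        assert generate_design(9, seed=5) == generate_design(9, seed=5)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_design(1, seed=0)

    def test_arousal_integer_range(self):
        d = generate_design(20, seed=7)
        for s in d.subjects:
            assert all(1 <= a <= 10 for a in s.arousal_by_session)


class TestTrajectory:
    def test_default_frame_count_and_agents(self):
        tr = generate_trajectory("following", (80.0, 8000.0), seed=1)
        assert tr.n_frames == 4655  # 35 s at 133 frames/s
        assert tr.xy.shape[0] == 2

    @pytest.mark.parametrize("speed", [40.0, 120.0, 250.0])
    def test_realised_speed_within_ten_percent(self, speed):
        tr = generate_trajectory(
            "fighting", (speed, speed * 100.0), duration_s=4.0, rate_hz=60.0, seed=2
        )
        assert kin.compute_mean_speed(tr) == pytest.approx(speed, rel=0.10)

    def test_positions_confined_to_canvas(self):
        tr = generate_trajectory(
            "fighting", (400.0, 400.0 * 4.0), duration_s=4.0, rate_hz=60.0, seed=3
        )
        assert tr.xy[..., 0].min() >= 0 and tr.xy[..., 0].max() <= 1280
        assert tr.xy[..., 1].min() >= 0 and tr.xy[..., 1].max() <= 1024

    def test_nonpositive_targets_rejected(self):
        with pytest.raises(ParameterError):
            generate_trajectory("following", (0.0, 100.0))


class TestRatings:
    def test_null_configuration_gives_equal_ratings(self):
        truth = GeneratorParams(
            grand_mean_accuracy=0.0,
            drug_effect=0.0,
            mental_state_effect=0.0,
            jerk_diff_slope_nonmental=0.0,
            jerk_diff_slope_mental_contrast=0.0,
            er_coupling_slope=0.0,
            residual_sd=1e-12,
        )
        ctx = {"treatment": "PLA", "mental_state": "mental", "target_word": "seducing"}
        r = generate_ratings(ctx, truth, {}, seed=0)
        vals = np.array(list(r.values()))
        assert np.allclose(vals, 5.5, atol=1e-6)
        assert scoring.accuracy_score(r, "seducing") == pytest.approx(0.0, abs=1e-9)

    def test_ratings_preserve_latent_accuracy_exactly(self, rng):
        for a in rng.uniform(-12, 12, 50):
            r = ratings_from_accuracy(a, "fighting", rng)
            assert scoring.accuracy_score(r, "fighting") == pytest.approx(
                float(np.clip(a, -9, 9)), abs=1e-9
            )
            assert all(1 <= v <= 10 for v in r.values())

    def test_strong_negative_drug_effect_lowers_haloperidol_mean(self):
        params = GeneratorParams(drug_effect=-5.0, residual_sd=0.3)
        c = generate_cohort(20, params=params, seed=1, duration_s=2.0, rate_hz=50.0)
        scored = scoring.score_trials(c.animation_trials)
        means = scored.groupby("treatment")["accuracy"].mean()
        assert means["HAL"] < means["PLA"] - 3.0


class TestMixtureControl:
    @staticmethod
    def _two_means_separation(acc):
        """Distance between a 2-means split in units of pooled within-cluster SD."""
        acc = np.sort(np.asarray(acc))
        best = 0.0
        for cut in np.quantile(acc, np.linspace(0.2, 0.8, 25)):
            lo, hi = acc[acc <= cut], acc[acc > cut]
            if len(lo) < 10 or len(hi) < 10:
                continue
            within = np.sqrt(0.5 * (lo.var() + hi.var()))
            best = max(best, (hi.mean() - lo.mean()) / max(within, 1e-9))
        return best

    def test_zero_weight_is_unimodal_and_half_weight_bimodal(self):
        # All regression effects zeroed so the check isolates the mixture
        # structure itself: a pure Gaussian admits a best two-means split of
        # about 2.6 within-SD units, a 50/50 mixture at separation 6 about 6.
        null = dict(
            drug_effect=0.0,
            mental_state_effect=0.0,
            jerk_diff_slope_nonmental=0.0,
            jerk_diff_slope_mental_contrast=0.0,
            er_coupling_slope=0.0,
            subject_sd=1e-6,
            subject_drug_slope_sd=1e-6,
            animation_sd=1e-6,
            residual_sd=1.0,
        )
        uni = GeneratorParams(mixture_weight=0.0, **null)
        bi = GeneratorParams(mixture_weight=0.5, mixture_separation=6.0, **null)
        c_uni = generate_cohort(16, params=uni, seed=8, duration_s=2.0, rate_hz=50.0)
        c_bi = generate_cohort(16, params=bi, seed=8, duration_s=2.0, rate_hz=50.0)
        a_uni = scoring.score_trials(c_uni.animation_trials)["accuracy"].to_numpy()[:1000]
        a_bi = scoring.score_trials(c_bi.animation_trials)["accuracy"].to_numpy()[:1000]
        assert self._two_means_separation(a_bi) > 4.5
        assert self._two_means_separation(a_uni) < 3.5


class TestAuxiliaryStreams:
    def test_emotion_speed_ordering(self, cohort):
        means = cohort.emotion_trials.groupby("emotion")["stimulus_speed"].mean()
        assert means["sad"] < means["happy"] < means["angry"]
        assert EMOTION_SPEED["sad"] < EMOTION_SPEED["happy"] < EMOTION_SPEED["angry"]

    def test_null_walking_effects_equalise_speeds(self):
        params = GeneratorParams(walk_drug_effect=0.0, walk_wm_interaction=0.0)
        c = generate_cohort(24, params=params, seed=11, duration_s=2.0, rate_hz=50.0)
        wt = tables.walk_table(c.walk, c.subjects)
        diff = (
            wt.pivot_table(index="subject_id", columns="treatment", values="speed")
            .eval("HAL - PLA")
            .mean()
        )
        assert abs(diff) < 0.02  # pass-time noise only

    def test_zero_coupling_decorrelates_er_and_accuracy_change(self):
        params = GeneratorParams(er_coupling_slope=0.0)
        c = generate_cohort(24, params=params, seed=13, duration_s=2.0, rate_hz=50.0)
        tt = tables.trial_table(c.animation_trials, c.subjects)
        ch = tables.change_table(tt, c.emotion_trials, c.wm_trials)
        mental = ch[ch["mental_state"] == "mental"]
        r = np.corrcoef(mental["er_change"], mental["accuracy_change"])[0, 1]
        assert abs(r) < 0.35

    def test_wm_trials_span_set_sizes(self, cohort):
        assert sorted(cohort.wm_trials["set_size"].unique()) == [5, 6, 7, 8, 9]


class TestCohortInvariants:
    def test_session_trial_counts(self, cohort):
        per_session = cohort.animation_trials.groupby(["subject_id", "day_index"])
        assert set(per_session.size()) == {32}
        per_word = cohort.animation_trials.groupby(
            ["subject_id", "day_index", "target_word"]
        )
        assert set(per_word.size()) == {8}
        assert set(
            cohort.emotion_trials.groupby(["subject_id", "day_index"]).size()
        ) == {48}

    def test_byte_identical_reproduction(self, cohort):
        again = generate_cohort(12, seed=42, duration_s=2.0, rate_hz=50.0)
        assert cohort.animation_trials.equals(again.animation_trials)
        assert cohort.walk.equals(again.walk)
        some_id = next(iter(cohort.trajectories))
        assert np.array_equal(
            cohort.trajectories[some_id].xy, again.trajectories[some_id].xy
        )

    def test_each_subject_has_two_distinct_treatments(self, cohort):
        per = cohort.sessions.groupby("subject_id")["treatment"].agg(set)
        assert all(s == {"HAL", "PLA"} for s in per)
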