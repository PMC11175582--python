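"""Finite-difference kinematics against analytic and quadrature oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mentakin import kinematics as kin
from mentakin.errors import (
    InsufficientDataError,
    LinkageError,
    MentakinError,
    SamplingError,
)


def _traj(fx, fy, duration=35.0, rate=133.0):
    """Two-agent trajectory where both agents follow (fx(t), fy(t))."""
    n = int(duration * rate)
    t = np.arange(n) / rate
    xy = np.stack([np.stack([fx(t), fy(t)], axis=-1)] * 2)
    return kin.Trajectory("test", "following", t, xy, rate)


class TestMeanSpeed:
    def test_straight_line(self):
        tr = _traj(lambda t: 3 * t, lambda t: 4 * t, duration=2.0, rate=50.0)
        assert kin.compute_mean_speed(tr) == pytest.approx(5.0, abs=1e-9)

    def test_static_is_zero(self):
        tr = _traj(lambda t: 0 * t + 7.0, lambda t: 0 * t + 3.0, duration=1.0, rate=50.0)
        assert kin.compute_mean_speed(tr) == 0.0

    def test_sinusoid_matches_analytic_oracle(self):
        # oracle: the analytic derivative |2*pi*cos(2*pi*t)| averaged over the
        # interior frames the estimator sees, isolating differentiation error
        tr = _traj(lambda t: np.sin(2 * np.pi * t), lambda t: 0 * t)
        oracle = np.mean(np.abs(2 * np.pi * np.cos(2 * np.pi * tr.t[2:-2])))
        assert kin.compute_mean_speed(tr) == pytest.approx(oracle, abs=1e-3)
        # whole-period quadrature average (= 4 = 2*(2*pi)/pi) up to windowing
        tt = np.linspace(0.0, 35.0, 2_000_001)
        quad = np.trapezoid(np.abs(2 * np.pi * np.cos(2 * np.pi * tt)), tt) / 35.0
        assert kin.compute_mean_speed(tr) == pytest.approx(quad, abs=5e-3)

    def test_too_few_frames(self):
        tr = kin.Trajectory("x", "fighting", np.array([0.0]), np.zeros((2, 1, 2)), 1.0)
        with pytest.raises(InsufficientDataError):
            kin.compute_mean_speed(tr)


class TestMeanJerk:
    def test_quadratic_has_zero_jerk(self):
        tr = _traj(lambda t: t**2, lambda t: 0 * t, duration=2.0, rate=50.0)
        assert kin.compute_mean_jerk(tr) == pytest.approx(0.0, abs=1e-9)

    def test_cubic_jerk_exact(self):
        tr = _traj(lambda t: t**3, lambda t: 0 * t, duration=2.0, rate=50.0)
        assert kin.compute_mean_jerk(tr) == pytest.approx(6.0, abs=1e-6)

    def test_sinusoid_matches_quadrature_oracle(self):
        tt = np.linspace(0.0, 35.0, 2_000_001)
        oracle = np.trapezoid(
            np.abs((2 * np.pi) ** 3 * np.cos(2 * np.pi * tt)), tt
        ) / 35.0
        tr = _traj(lambda t: np.sin(2 * np.pi * t), lambda t: 0 * t)
        assert kin.compute_mean_jerk(tr) == pytest.approx(oracle, rel=5e-3)

    @pytest.mark.parametrize("coeffs", [(0.3, -1.2, 0.5, 2.0), (1.0, 0.0, -3.0, 0.7)])
    def test_cubic_polynomial_matches_analytic_third_derivative(self, coeffs):
        a, b, c, d = coeffs
        tr = _traj(
            lambda t: a * t**3 + b * t**2 + c * t + d,
            lambda t: -2 * a * t**3 + t,
            duration=2.0,
            rate=50.0,
        )
        oracle = np.sqrt((6 * a) ** 2 + (6 * -2 * a) ** 2)
        assert kin.compute_mean_jerk(tr) == pytest.approx(oracle, rel=1e-6)

    def test_too_few_frames(self):
        t = np.arange(3) / 10.0
        tr = kin.Trajectory("x", "fighting", t, np.zeros((2, 3, 2)), 10.0)
        with pytest.raises(InsufficientDataError):
            kin.compute_mean_jerk(tr)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.25, 0.3, 0.4, 0.5])
        tr = kin.Trajectory("x", "fighting", t, np.random.default_rng(0).normal(size=(2, 6, 2)), 10.0)
        with pytest.raises(SamplingError):
            kin.compute_mean_jerk(tr)


class TestScaleAndSymmetryProperties:
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        n = 60
        t = np.arange(n) / 30.0
        xy = rng.normal(size=(2, n, 2)).cumsum(axis=1)  # smooth-ish random walk
        tr = kin.Trajectory("a", "following", t, xy, 30.0)
        tr_scaled = kin.Trajectory("b", "following", t, xy * scale, 30.0)
        assert kin.compute_mean_speed(tr_scaled) == pytest.approx(
            scale * kin.compute_mean_speed(tr), rel=1e-9
        )
        assert kin.compute_mean_jerk(tr_scaled) == pytest.approx(
            scale * kin.compute_mean_jerk(tr), rel=1e-9
        )

    def test_optional_smoothing_reduces_noise_jerk_but_not_cubic(self, rng):
        n = 400
        t = np.arange(n) / 100.0
        clean = np.stack([np.stack([0.5 * t**3, t], axis=-1)] * 2)
        noisy = clean + rng.normal(0, 0.01, clean.shape)
        tr_noisy = kin.Trajectory("n", "following", t, noisy, 100.0)
        assert kin.compute_mean_jerk(tr_noisy, smooth=True) < kin.compute_mean_jerk(
            tr_noisy, smooth=False
        )
        tr_clean = kin.Trajectory("c", "following", t, clean, 100.0)
        assert kin.compute_mean_jerk(tr_clean, smooth=True) == pytest.approx(
            kin.compute_mean_jerk(tr_clean, smooth=False), rel=1e-6
        )

    def test_time_reversal_invariance(self, rng):
        n = 100
        t = np.arange(n) / 25.0
        xy = rng.normal(size=(2, n, 2)).cumsum(axis=1)
        fwd = kin.Trajectory("f", "fighting", t, xy, 25.0)
        rev = kin.Trajectory("r", "fighting", t, xy[:, ::-1, :], 25.0)
        assert kin.compute_mean_jerk(rev) == pytest.approx(
            kin.compute_mean_jerk(fwd), rel=1e-9
        )


class TestJerkDifference:
    @pytest.mark.parametrize(
        "a,b,expected", [(12.0, 9.5, 2.5), (7.0, 7.0, 0.0), (9.5, 12.0, 2.5)]
    )
    def test_examples(self, a, b, expected):
        assert kin.jerk_difference(a, b) == pytest.approx(expected)

    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_nonnegative(self, a, b):
        d = kin.jerk_difference(a, b)
        assert d == kin.jerk_difference(b, a)
        assert d >= 0
        assert (d == 0) == (a == b)

    def test_negative_input_rejected(self):
        with pytest.raises(MentakinError):
            kin.jerk_difference(-1.0, 2.0)


class TestAttachJerkDifferences:
    @pytest.fixture
    def trials(self):
        return pd.DataFrame(
            {
                "trial_id": ["t1", "t2"],
                "subject_id": ["S01", "S01"],
                "treatment": ["PLA", "HAL"],
                "target_word": ["fighting", "fighting"],
                "stimulus_mean_jerk": [9.0, 9.0],
            }
        )

    def test_placebo_trial_indices_coincide(self, trials):
        self_jerk = {("S01", "fighting", "PLA"): 14.0, ("S01", "fighting", "HAL"): 10.0}
        recs = kin.attach_jerk_differences(trials, self_jerk)
        assert recs[0].same_session_jerk_diff == recs[0].placebo_jerk_diff == 5.0

    def test_haloperidol_trial_uses_both_sessions(self, trials):
        self_jerk = {("S01", "fighting", "PLA"): 14.0, ("S01", "fighting", "HAL"): 10.0}
        recs = kin.attach_jerk_differences(trials, self_jerk)
        assert recs[1].same_session_jerk_diff == pytest.approx(1.0)
        assert recs[1].placebo_jerk_diff == pytest.approx(5.0)

    def test_missing_word_raises_linkage_error(self, trials):
        with pytest.raises(LinkageError, match="fighting"):
            kin.attach_jerk_differences(trials, {("S01", "fighting", "PLA"): 14.0})


class TestWalkingSpeed:
    @pytest.mark.parametrize(
        "times,expected", [([8, 8, 8], 1.25), ([10], 1.0), ([8, 12], 1.0417)]
    )
    def test_examples(self, times, expected):
        assert kin.walking_speed(times) == pytest.approx(expected, abs=1e-4)

    def test_bad_input(self):
        with pytest.raises(MentakinError):
            kin.walking_speed([])
        with pytest.raises(MentakinError):
            kin.walking_speed([5.0, -1.0])


def test_long_format_round_trip(cohort):
    frame = cohort.trajectories_frame()
    rebuilt = {tr.animation_id: tr for tr in kin.trajectories_from_frame(frame)}
    some_id = next(iter(cohort.trajectories))
    orig = cohort.trajectories[some_id]
    assert np.allclose(rebuilt[some_id].xy, orig.xy)
    assert kin.compute_mean_jerk(rebuilt[some_id]) == pytest.approx(
        kin.compute_mean_jerk(orig)
    )
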