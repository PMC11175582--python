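"""Posterior machinery: summaries, determinism, recovery, mixtures, LOO."""

from types import SimpleNamespace

import numpy as np
import pytest

from mentakin import inference as inf
from mentakin.errors import ComparabilityError, MentakinError, SchemaError
from mentakin.formulas import build_model, make_spec
from tests.conftest import FAST


def stub_fit(**draws):
    """Minimal object exposing .draws for summary-level functions."""
    return SimpleNamespace(draws={k: np.asarray(v) for k, v in draws.items()})


class TestSummaries:
    def test_summarise_draws_example(self):
        s = inf.summarise_draws("x", np.array([-1.0, -0.5, 0.5, 1.5]))
        assert s.e_mu == pytest.approx(0.125)
        assert s.p_negative == pytest.approx(0.5)
        assert s.p_positive == pytest.approx(0.5)

    def test_all_negative_draws(self):
        s = inf.summarise_draws("x", -np.abs(np.random.default_rng(0).normal(size=500)) - 0.01)
        assert s.p_negative == 1.0
        assert s.cri_upper < 0

    def test_symmetric_draws_split_sign_probability(self, rng):
        z = rng.normal(size=20001)
        s = inf.summarise_draws("x", np.concatenate([z, -z]))
        assert s.p_negative == pytest.approx(0.5, abs=1e-3)
        assert s.p_negative + s.p_positive == pytest.approx(1.0, abs=1e-4)

    def test_derived_coefficient_arithmetic(self):
        f = stub_fit(a=np.full(100, 0.1), b=np.full(100, 0.2))
        assert inf.derived_coefficient(f, "a", "b").e_mu == pytest.approx(0.3)

    def test_derived_coefficient_identity_when_contrast_zero(self, rng):
        a = rng.normal(size=400)
        f = stub_fit(a=a, zero=np.zeros(400))
        d = inf.derived_coefficient(f, "a", "zero")
        assert d.e_mu == pytest.approx(a.mean())
        assert d.cri_lower == pytest.approx(np.percentile(a, 2.5))

    def test_unknown_term_raises(self):
        with pytest.raises(MentakinError):
            inf.derived_coefficient(stub_fit(a=[1.0]), "a", "missing")


class TestFitBehaviour:
    def test_identical_seed_identical_summaries(self, trial_tab):
        f1 = inf.fit("1.1", trial_tab, seed=5, settings=FAST)
        f2 = inf.fit("1.1", trial_tab, seed=5, settings=FAST)
        for k in f1.draws:
            assert np.array_equal(f1.draws[k], f2.draws[k])

    def test_missing_column_raises_schema_error(self, trial_tab):
        with pytest.raises(SchemaError):
            inf.fit("2.1", trial_tab.drop(columns=["jerk_diff"]), seed=0, settings=FAST)

    def test_small_model_converges(self, walk_tab):
        settings = inf.SamplerSettings(iterations_per_chain=3000, warmup=500, thin=5)
        f = inf.fit("7.1", walk_tab, seed=3, settings=settings)
        assert f.divergences == 0
        assert f.max_rhat <= 1.01
        assert f.converged

    def test_zeroed_effects_concentrate_near_zero(self, trial_tab):
        truth = {"sigma": 2.0}  # all coefficients and random-effect SDs zero
        sim = inf.simulate_from_spec("1.2", trial_tab, truth, seed=9)
        f = inf.fit("1.2", sim, seed=4, settings=FAST)
        for term in ("drugHAL", "mental_statemental", "drugHAL:mental_statemental"):
            s = inf.summarise(f, term)
            assert s.cri_lower < 0 < s.cri_upper
            assert abs(s.e_mu) < 0.5

    def test_gaussian_recovery_within_three_posterior_sds(self, trial_tab):
        truth = {
            "Intercept": 3.0,
            "drugHAL": -0.66,
            "sd_subject_Intercept": 1.0,
            "sd_subject_drug": 0.5,
            "sd_animation_Intercept": 0.6,
            "sigma": 2.2,
        }
        sim = inf.simulate_from_spec("1.1", trial_tab, truth, seed=21)
        f = inf.fit("1.1", sim, seed=22, settings=FAST)
        for term in ("Intercept", "drugHAL"):
            flat = np.ravel(f.draws[term])
            assert abs(flat.mean() - truth[term]) < 3 * flat.std()


class TestMixture:
    def test_known_truth_recovery(self, trial_tab):
        truth = {
            "Intercept": -1.0,
            "mu2": 5.0,
            "theta": 0.5,
            "sigma1": 0.5,
            "sigma2": 0.5,
        }
        sim = inf.simulate_from_spec("5", trial_tab.head(1000), truth, seed=31)
        f, mix = inf.fit_mixture_response(sim, seed=32, settings=FAST)
        assert mix.component_means[0] == pytest.approx(-1.0, abs=0.3)
        assert mix.component_means[1] == pytest.approx(5.0, abs=0.3)
        assert mix.component_means[0] < mix.component_means[1]
        assert 0.4 < mix.mixing_proportion < 0.6
        assert -1.0 < mix.split_point < 5.0
        assert not mix.degenerate

    def test_unimodal_data_flagged_degenerate_or_collapsed(self, trial_tab):
        truth = {"Intercept": 2.0, "mu2": 2.5, "theta": 0.0, "sigma1": 1.0}
        sim = inf.simulate_from_spec("5", trial_tab.head(800), truth, seed=41)
        f, mix = inf.fit_mixture_response(sim, seed=42, settings=FAST)
        gap = mix.component_means[1] - mix.component_means[0]
        collapsed = gap < 1.5 * max(mix.component_sds)
        assert mix.degenerate or collapsed

    def test_component_means_always_ordered(self, trial_tab, rng):
        sim = trial_tab.head(600).copy()
        sim["accuracy"] = rng.normal(1.0, 2.0, len(sim))
        _, mix = inf.fit_mixture_response(sim, seed=43, settings=FAST)
        assert mix.component_means[0] <= mix.component_means[1]


class TestComparison:
    def test_identical_fits_tie(self, walk_tab):
        f = inf.fit("7.1", walk_tab, seed=3, settings=FAST)
        result = inf.compare({"a": f, "b": f})
        assert result.elpd_diff[result.order[0]] == 0.0
        assert abs(result.elpd_diff[result.order[1]]) < 1e-9
        assert sum(result.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert result.weights["a"] == pytest.approx(0.5, abs=0.05)

    def test_generating_model_beats_intercept_only(self, trial_tab):
        truth = {
            "Intercept": 3.0,
            "drugHAL": -2.0,
            "sd_subject_Intercept": 0.5,
            "sigma": 1.5,
        }
        sim = inf.simulate_from_spec("1.1", trial_tab.head(500), truth, seed=51)
        full = inf.fit("1.1", sim, seed=52, settings=FAST)
        null = inf.fit(
            make_spec("null", base="1.1", fixed=""), sim, seed=53, settings=FAST
        )
        result = inf.compare({"full": full, "null": null})
        assert result.order[0] == "full"
        assert result.elpd_diff["null"] < -result.se_diff["null"]

    def test_mismatched_observations_rejected(self, trial_tab, walk_tab):
        f1 = inf.fit("7.1", walk_tab, seed=3, settings=FAST)
        f2 = inf.fit("1.1", trial_tab, seed=3, settings=FAST)
        with pytest.raises(ComparabilityError):
            inf.compare({"a": f1, "b": f2})


class TestTruncatedT:
    def test_recovery_and_sign_probabilities(self, change_tab):
        truth = {
            "Intercept": -0.08,
            "er_change": -0.02,
            "er_change:mental_statemental": 0.07,
            "sigma": 0.18,
            "nu": 25.0,
        }
        sim = inf.simulate_from_spec("4.2", change_tab, truth, seed=61)
        f = inf.fit("4.2", sim, seed=62, settings=FAST)
        for term, val in (
            ("Intercept", -0.08),
            ("er_change", -0.02),
            ("er_change:mental_statemental", 0.07),
        ):
            flat = np.ravel(f.draws[term])
            assert abs(flat.mean() - val) < 3 * flat.std()
        s = inf.summarise(f, "er_change")
        assert s.p_negative + s.p_positive == pytest.approx(1.0)

    def test_response_respects_truncation(self, change_tab):
        sim = inf.simulate_from_spec(
            "4.2", change_tab, {"Intercept": 0.9, "sigma": 0.5, "nu": 3.0}, seed=63
        )
        assert sim["accuracy_change"].between(-1, 1).all()
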