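"""Synthetic-observer psychometric structure: biases, vibration step, fusion."""

import numpy as np
import pytest
from scipy.stats import norm

from headingcues import (
    ConditionSpec,
    ObserverParams,
    condition_psychometric,
    empirical_weights,
    make_cohort,
    respond,
)
from headingcues.observer import p_right


class TestConditionPsychometric:
    def test_vibration_inflates_inertial_sigma_to_group_value(self, default_observer):
        """sigma_I 4.8 deg without vibration, 8.8 deg with any vibration."""
        no_vib = condition_psychometric(default_observer, ConditionSpec("inertial", 0.0))
        assert no_vib[1] == pytest.approx(4.8)
        for amp in (0.10, 0.15, 0.20):
            mu, sigma = condition_psychometric(
                default_observer, ConditionSpec("inertial", amp)
            )
            assert sigma == pytest.approx(8.8)

    def test_vibration_effect_is_a_step_not_a_dose(self, default_observer):
        sigmas = {
            amp: condition_psychometric(default_observer, ConditionSpec("inertial", amp))[1]
            for amp in (0.10, 0.15, 0.20)
        }
        assert len(set(sigmas.values())) == 1

    def test_visual_bias_opposite_gaze_inertial_toward_gaze(self, default_observer):
        """mu > 0 means midline perceived leftward: visual shifts with +bias under
        right gaze (opposite gaze), inertial with -bias (toward gaze)."""
        mu_v_r, _ = condition_psychometric(default_observer, ConditionSpec("visual", gaze="right"))
        mu_i_r, _ = condition_psychometric(default_observer, ConditionSpec("inertial", gaze="right"))
        assert mu_v_r == pytest.approx(9.6)
        assert mu_i_r == pytest.approx(-3.0)

    def test_gaze_symmetry(self, default_observer):
        for modality in ("visual", "inertial", "combined"):
            mu_r, s_r = condition_psychometric(
                default_observer, ConditionSpec(modality, gaze="right")
            )
            mu_l, s_l = condition_psychometric(
                default_observer, ConditionSpec(modality, gaze="left")
            )
            assert mu_l == pytest.approx(-mu_r)
            assert s_l == s_r

    def test_fixed_weight_combination_arithmetic(self):
        """w_I = 0.9 with mu_I = +3.6, mu_V = -7.3 gives mu_VI = 2.51."""
        obs = ObserverParams(
            bias_I=3.6, bias_V=7.3, integration_mode="fixed", w_I_fixed=0.9
        )
        mu, _ = condition_psychometric(obs, ConditionSpec("combined", 0.15, gaze="left"))
        assert mu == pytest.approx(0.9 * 3.6 + 0.1 * (-7.3))

    def test_equal_sigmas_give_equal_weights(self):
        obs = ObserverParams(sigma_V=4.0, sigma_I0=4.0)
        mu_v, _ = condition_psychometric(obs, ConditionSpec("visual", gaze="right"))
        mu_i, _ = condition_psychometric(obs, ConditionSpec("inertial", gaze="right"))
        mu_vi, _ = condition_psychometric(obs, ConditionSpec("combined", gaze="right"))
        assert mu_vi == pytest.approx((mu_v + mu_i) / 2)

    def test_combined_sigma_optimal_fusion(self, default_observer):
        _, sigma = condition_psychometric(
            default_observer, ConditionSpec("combined", 0.0, gaze="right")
        )
        sv, si = 3.6, 4.8
        assert sigma == pytest.approx(sv * si / np.hypot(sv, si))

    def test_weight_round_trip_recovers_configured_w_I(self):
        """Feeding the observer's own means into the empirical-weight formula
        returns the configured inertial weight to machine precision."""
        for w in (0.1, 0.36, 0.9, 1.2):
            obs = ObserverParams(integration_mode="fixed", w_I_fixed=w)
            for gaze in ("left", "right"):
                mu_v, _ = condition_psychometric(obs, ConditionSpec("visual", gaze=gaze))
                mu_i, _ = condition_psychometric(obs, ConditionSpec("inertial", 0.1, gaze=gaze))
                mu_vi, _ = condition_psychometric(obs, ConditionSpec("combined", 0.1, gaze=gaze))
                est = empirical_weights(mu_v, mu_i, mu_vi)
                assert est.w_I == pytest.approx(w, abs=1e-12)


class TestRespond:
    def test_probability_half_at_pse(self, default_observer):
        cond = ConditionSpec("inertial", 0.0, gaze="right")
        mu, _ = condition_psychometric(default_observer, cond)
        assert p_right(default_observer, cond, mu) == pytest.approx(0.5)

    def test_saturates_in_the_tail(self, default_observer):
        cond = ConditionSpec("visual", gaze="left")
        mu, sigma = condition_psychometric(default_observer, cond)
        assert p_right(default_observer, cond, mu + 10 * sigma) > 1 - 1e-6
        rng = np.random.default_rng(0)
        assert respond(default_observer, cond, mu + 10 * sigma, rng) == "right"

    def test_monotone_nondecreasing_in_heading(self, default_observer):
        cond = ConditionSpec("combined", 0.15, gaze="left")
        grid = np.linspace(-60, 60, 241)
        p = p_right(default_observer, cond, grid)
        assert np.all(np.diff(p) >= 0)

    def test_lapse_floors_and_caps_probabilities(self):
        obs = ObserverParams(lapse=0.1)
        cond = ConditionSpec("inertial", 0.0, gaze="right")
        assert p_right(obs, cond, -1e6) == pytest.approx(0.05)
        assert p_right(obs, cond, 1e6) == pytest.approx(0.95)

    def test_empirical_rate_matches_normal_cdf(self):
        """One sigma above the PSE the rightward rate is Phi(1) ~ 0.841."""
        obs = ObserverParams(bias_I=0.0)
        cond = ConditionSpec("inertial", 0.0, gaze="right")
        rng = np.random.default_rng(123)
        n = 100_000
        hits = sum(respond(obs, cond, 4.8, rng) == "right" for _ in range(n))
        assert hits / n == pytest.approx(norm.cdf(1.0), abs=0.004)


class TestMakeCohort:
    def test_seeded_draws_are_deterministic(self):
        a = make_cohort(5, seed=11)
        b = make_cohort(5, seed=11)
        assert a == b
        assert a != make_cohort(5, seed=12)

    def test_degenerate_ranges_give_identical_parameters(self):
        ranges = {
            "sigma_V": (3.6, 3.6),
            "sigma_I0": (4.8, 4.8),
            "vib_inflation": (11 / 6, 11 / 6),
            "bias_V": (9.6, 9.6),
            "bias_I": (3.0, 3.0),
            "w_I_fixed": (0.9, 0.9),
            "p_fixed": 1.0,
        }
        cohort = make_cohort(3, ranges, seed=0)
        assert len({(o.sigma_V, o.sigma_I0, o.w_I_fixed) for o in cohort}) == 1

    def test_default_cohort_contains_inertial_overweighted_observer(self):
        cohort = make_cohort(5, seed=3)
        fixed = [o for o in cohort if o.integration_mode == "fixed"]
        assert fixed and any(o.w_I_fixed >= 0.87 for o in fixed)

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(5, {}, seed=0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(sigma_V=-1)
        with pytest.raises(ValueError):
            ObserverParams(integration_mode="fixed")  # missing w_I_fixed
        with pytest.raises(ValueError):
            ObserverParams(lapse=0.7)
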