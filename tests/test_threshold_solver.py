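"""Critical-GRF solver, curve generation, inversion, and risk classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aclthreshold import (
    ActivationState,
    LandingScenario,
    NoSolutionError,
    SurfaceState,
    angle_of_damage,
    classify_risk,
    critical_grf,
    generate_curve,
)

# Frozen from the independent root-find oracle (bisection on the net torque).
CRITICAL_AT_90 = 1561.2741821605082
CRITICAL_AT_30 = 2499.9420367817634


class TestCriticalGRF:
    def test_ninety_degrees(self, profile, tissue):
        assert critical_grf(90.0, profile, tissue) == pytest.approx(
            CRITICAL_AT_90, abs=1e-6
        )

    def test_thirty_degrees(self, profile, tissue):
        assert critical_grf(30.0, profile, tissue) == pytest.approx(
            CRITICAL_AT_30, abs=1e-6
        )

    def test_diverges_toward_zero_angle(self, profile, tissue):
        values = [critical_grf(a, profile, tissue) for a in (1.0, 0.1, 0.01, 0.001)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[-1] > 1e7

    def test_zero_angle_frictionless_raises(self, profile, tissue):
        with pytest.raises(NoSolutionError):
            critical_grf(0.0, profile, tissue)

    def test_lever_singularity_with_friction_raises(self, profile, tissue):
        # tan(30 deg) ~ 0.577 < mu: the foot cannot load the abduction axis
        with pytest.raises(NoSolutionError):
            critical_grf(30.0, profile, tissue, surface=SurfaceState(mu=0.8))

    def test_array_input_carries_inf_sentinel(self, profile, tissue):
        out = critical_grf(
            np.array([10.0, 45.0]), profile, tissue, surface=SurfaceState(mu=0.5)
        )
        assert np.isinf(out[0]) and np.isfinite(out[1])

    def test_matches_root_find_oracle_on_one_degree_grid(
        self, profile, tissue, root_find_critical_grf, one_degree_grid
    ):
        """Closed form vs independent bisection on the net torque: 1e-6 N."""
        for alpha in one_degree_grid:
            assert critical_grf(float(alpha), profile, tissue) == pytest.approx(
                root_find_critical_grf(float(alpha)), abs=1e-6
            )

    def test_oracle_agreement_with_friction_and_partial_activation(
        self, profile, tissue, root_find_critical_grf
    ):
        act = ActivationState(quad_fraction=0.6, semit_fraction=0.8)
        surf = SurfaceState(mu=0.25)
        for alpha in (30.0, 55.0, 80.0):
            assert critical_grf(
                alpha, profile, tissue, act, surf
            ) == pytest.approx(root_find_critical_grf(alpha, act, surf), abs=1e-6)


class TestMonotonicity:
    def test_strictly_decreasing_in_angle_frictionless(self, profile, tissue):
        """Steeper shin lean always lowers the injury threshold (mu = 0)."""
        curve = generate_curve(profile, tissue)  # default 0.01..90, 0.01 steps
        assert np.all(np.diff(curve.critical_grf_newton) < 0)

    @settings(max_examples=40, deadline=None)
    @given(
        alpha=st.floats(1.0, 89.0),
        mu_lo=st.floats(0.0, 0.3),
        dmu=st.floats(0.01, 0.3),
    )
    def test_friction_raises_threshold(self, profile, tissue, alpha, mu_lo, dmu):
        try:
            lo = critical_grf(alpha, profile, tissue, surface=SurfaceState(mu=mu_lo))
        except NoSolutionError:
            return  # lever already closed at the lower traction
        try:
            hi = critical_grf(
                alpha, profile, tissue, surface=SurfaceState(mu=mu_lo + dmu)
            )
        except NoSolutionError:
            return  # lever closed: threshold became infinite, trivially larger
        assert hi > lo

    @settings(max_examples=40, deadline=None)
    @given(alpha=st.floats(1.0, 90.0), frac=st.floats(0.0, 0.99))
    def test_weaker_quadriceps_lowers_threshold(self, profile, tissue, alpha, frac):
        full = critical_grf(alpha, profile, tissue)
        weak = critical_grf(
            alpha, profile, tissue, ActivationState(quad_fraction=frac)
        )
        assert weak < full


class TestAngleOfDamage:
    def test_inverts_thirty_degree_threshold(self, profile, tissue):
        assert angle_of_damage(CRITICAL_AT_30, profile, tissue) == pytest.approx(
            30.0, abs=1e-6
        )

    def test_inverts_ninety_degree_threshold(self, profile, tissue):
        assert angle_of_damage(CRITICAL_AT_90, profile, tissue) == pytest.approx(
            90.0, abs=1e-6
        )

    def test_no_solution_below_minimum(self, profile, tissue):
        assert angle_of_damage(600.0, profile, tissue) is None

    def test_nonpositive_grf_rejected(self, profile, tissue):
        with pytest.raises(ValueError, match="> 0"):
            angle_of_damage(0.0, profile, tissue)

    @settings(max_examples=60, deadline=None)
    @given(alpha=st.floats(0.01, 90.0))
    def test_round_trip_frictionless(self, profile, tissue, alpha):
        """angle_of_damage(critical_grf(alpha)) == alpha to 1e-6 degrees."""
        fy = critical_grf(alpha, profile, tissue)
        assert angle_of_damage(fy, profile, tissue) == pytest.approx(
            alpha, abs=1e-6
        )

    @settings(max_examples=30, deadline=None)
    @given(alpha=st.floats(30.0, 90.0), mu=st.floats(0.01, 0.5))
    def test_round_trip_with_friction(self, profile, tissue, alpha, mu):
        surface = SurfaceState(mu=mu)
        fy = critical_grf(alpha, profile, tissue, surface=surface)
        back = angle_of_damage(fy, profile, tissue, surface=surface)
        assert back == pytest.approx(alpha, abs=1e-6)


class TestGenerateCurve:
    def test_default_grid_has_9000_points(self, profile, tissue):
        curve = generate_curve(profile, tissue)
        assert len(curve.angles) == 9000
        assert curve.angles[0] == pytest.approx(0.01)
        assert curve.angles[-1] == pytest.approx(90.0)

    def test_bw_track_uses_profile_weight(self, profile, tissue):
        curve = generate_curve(profile, tissue, step=1.0, angle_min=1.0)
        np.testing.assert_allclose(
            curve.critical_grf_bw, curve.critical_grf_newton / 802.0
        )

    def test_subgrid_of_finer_curve_matches_pointwise(self, profile, tissue):
        fine = generate_curve(profile, tissue, angle_min=1.0, step=0.5)
        coarse = generate_curve(profile, tissue, angle_min=1.0, step=1.0)
        np.testing.assert_allclose(
            fine.critical_grf_newton[::2], coarse.critical_grf_newton
        )

    def test_friction_curve_dominates_frictionless(self, profile, tissue):
        base = generate_curve(profile, tissue, angle_min=1.0, step=1.0)
        slick = generate_curve(
            profile, tissue, surface=SurfaceState(mu=0.3), angle_min=1.0, step=1.0
        )
        assert np.all(
            slick.critical_grf_newton[:-1] > base.critical_grf_newton[:-1]
        )
        # independent of traction when the shank is horizontal
        assert slick.critical_grf_newton[-1] == pytest.approx(
            base.critical_grf_newton[-1]
        )

    def test_inf_sentinel_inside_grid(self, profile, tissue):
        curve = generate_curve(
            profile, tissue, surface=SurfaceState(mu=1.0), angle_min=1.0, step=1.0
        )
        assert np.isinf(curve.critical_grf_newton[:40]).all()
        assert np.isfinite(curve.critical_grf_newton[50:]).all()

    @pytest.mark.parametrize(
        "kwargs", [{"angle_min": 50.0, "angle_max": 40.0}, {"step": -0.01},
                   {"angle_min": -1.0}, {"angle_max": 91.0}]
    )
    def test_bad_grid_rejected(self, profile, tissue, kwargs):
        with pytest.raises(ValueError):
            generate_curve(profile, tissue, **kwargs)


class TestClassifyRisk:
    def test_just_above_critical_is_at_risk(self, profile, tissue):
        fy = critical_grf(30.0, profile, tissue)
        risk = classify_risk(LandingScenario(30.0, fy + 1.0, profile), tissue)
        assert risk.at_risk and risk.margin_nm > 0

    def test_exact_balance_is_safe(self, profile, tissue):
        fy = critical_grf(30.0, profile, tissue)
        risk = classify_risk(LandingScenario(30.0, fy, profile), tissue)
        assert not risk.at_risk

    def test_zero_grf_is_safe(self, profile, tissue):
        risk = classify_risk(LandingScenario(45.0, 0.0, profile), tissue)
        assert not risk.at_risk and risk.margin_nm < 0
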