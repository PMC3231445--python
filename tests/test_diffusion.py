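"""Error-function diffusion solution (Step C) and its PDE oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gasbiosense as gb
from gasbiosense.quantities import Quantity


class TestConcentrationAt:
    def test_interface_stays_at_c0(self, diffusion_scenario):
        for t in [0.0, 1e-3, 0.5, 100.0]:
            c = gb.concentration_at(Quantity(0, "m"), Quantity(t, "s"), diffusion_scenario)
            assert c.value == pytest.approx(diffusion_scenario.c0.m_as("M"))

    def test_zero_time_zero_everywhere_else(self, diffusion_scenario):
        c = gb.concentration_at(Quantity(1, "um"), Quantity(0, "s"), diffusion_scenario)
        assert c.value == 0.0

    def test_layer_bottom_above_90_percent_at_half_second(self, diffusion_scenario):
        """x = 2.7 um, t = 0.5 s, D = 1.3e-9 m^2/s -> c/c0 ~ 0.94 > 0.90."""
        c = gb.concentration_at(Quantity(2.7, "um"), Quantity(0.5, "s"), diffusion_scenario)
        ratio = c.m_as("M") / diffusion_scenario.c0.m_as("M")
        assert ratio == pytest.approx(0.9403, abs=1e-3)
        assert ratio > 0.90

    def test_negative_arguments_rejected(self, diffusion_scenario):
        with pytest.raises(gb.DomainError):
            gb.concentration_at(Quantity(-1, "um"), Quantity(1, "s"), diffusion_scenario)
        with pytest.raises(gb.DomainError):
            gb.concentration_at(Quantity(1, "um"), Quantity(-1, "s"), diffusion_scenario)

    @given(
        x_um=st.floats(min_value=0.01, max_value=10.0),
        t_s=st.floats(min_value=1e-4, max_value=10.0),
        alpha=st.sampled_from([0.5, 2.0, 10.0]),
    )
    def test_self_similarity(self, x_um, t_s, alpha, diffusion_scenario):
        """c depends on (x, t) only through x/sqrt(D t): c(a*x, a^2*t) = c(x, t)."""
        c1 = gb.concentration_at(
            Quantity(x_um, "um"), Quantity(t_s, "s"), diffusion_scenario
        )
        c2 = gb.concentration_at(
            Quantity(alpha * x_um, "um"), Quantity(alpha**2 * t_s, "s"), diffusion_scenario
        )
        assert c2.value == pytest.approx(c1.value, rel=1e-9, abs=1e-300)

    @given(
        x_um=st.floats(min_value=0.05, max_value=5.0),
        t_s=st.floats(min_value=1e-3, max_value=5.0),
    )
    def test_bounds_and_monotonicity(self, x_um, t_s, diffusion_scenario):
        c0 = diffusion_scenario.c0.m_as("M")
        c = gb.concentration_at(
            Quantity(x_um, "um"), Quantity(t_s, "s"), diffusion_scenario
        ).m_as("M")
        assert 0.0 <= c <= c0
        deeper = gb.concentration_at(
            Quantity(2 * x_um, "um"), Quantity(t_s, "s"), diffusion_scenario
        ).m_as("M")
        later = gb.concentration_at(
            Quantity(x_um, "um"), Quantity(2 * t_s, "s"), diffusion_scenario
        ).m_as("M")
        assert deeper < c
        assert later > c


class TestBuildProfile:
    def test_rows_match_pointwise_calls(self, diffusion_scenario):
        profile = gb.build_profile(diffusion_scenario, [0.001, 0.01, 0.1, 0.5], 25)
        for i, t in enumerate(profile.times):
            for j, x in enumerate(profile.x_grid):
                expected = gb.concentration_at(
                    Quantity(x, "m"), Quantity(t, "s"), diffusion_scenario
                ).m_as("M")
                assert profile.concentrations[i, j] == pytest.approx(expected)

    def test_curves_monotone_non_increasing(self, diffusion_scenario):
        profile = gb.build_profile(diffusion_scenario, [0.001, 0.01, 0.1, 0.5], 50)
        assert np.all(np.diff(profile.concentrations, axis=1) <= 0)

    def test_two_point_profile_is_endpoints(self, diffusion_scenario):
        profile = gb.build_profile(diffusion_scenario, [0.5], 2)
        assert profile.concentrations[0, 0] == pytest.approx(
            diffusion_scenario.c0.m_as("M")
        )
        bottom = gb.concentration_at(
            diffusion_scenario.layer_depth, Quantity(0.5, "s"), diffusion_scenario
        )
        assert profile.concentrations[0, 1] == pytest.approx(bottom.m_as("M"))

    def test_csv_round_trip(self, diffusion_scenario, tmp_path):
        profile = gb.build_profile(diffusion_scenario, [0.01, 0.1], 10)
        path = tmp_path / "profile.csv"
        profile.to_csv(path)
        back = gb.DiffusionProfile.from_csv(path)
        np.testing.assert_allclose(back.concentrations, profile.concentrations)
        np.testing.assert_allclose(back.x_grid, profile.x_grid)

    def test_bad_arguments_rejected(self, diffusion_scenario):
        with pytest.raises(gb.DomainError):
            gb.build_profile(diffusion_scenario, [], 10)
        with pytest.raises(gb.DomainError):
            gb.build_profile(diffusion_scenario, [0.1], 1)


class TestTimeToFraction:
    def test_t90_of_reference_layer(self, diffusion_scenario):
        """t90 ~ 0.178 s at 2.7 um: comfortably inside the 500 ms bound."""
        t90 = gb.time_to_fraction(Quantity(2.7, "um"), 0.9, diffusion_scenario)
        assert t90.m_as("s") == pytest.approx(0.17756, rel=1e-4)
        assert t90.m_as("s") <= 0.5

    @pytest.mark.parametrize("fraction", [0.5, 0.8, 0.9, 0.99])
    def test_round_trip_with_concentration_at(self, fraction, diffusion_scenario):
        x = Quantity(2.7, "um")
        t = gb.time_to_fraction(x, fraction, diffusion_scenario)
        c = gb.concentration_at(x, t, diffusion_scenario)
        assert c.m_as("M") / diffusion_scenario.c0.m_as("M") == pytest.approx(
            fraction, abs=1e-9
        )

    def test_monotone_in_fraction(self, diffusion_scenario):
        x = Quantity(2.7, "um")
        times = [
            gb.time_to_fraction(x, f, diffusion_scenario).m_as("s")
            for f in [0.5, 0.7, 0.9, 0.99, 0.999]
        ]
        assert times == sorted(times)
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))

    def test_fraction_domain_checked(self, diffusion_scenario):
        for bad in [0.0, 1.0, -0.1, 1.5]:
            with pytest.raises(gb.DomainError):
                gb.time_to_fraction(Quantity(1, "um"), bad, diffusion_scenario)


class TestMinFractionInLayer:
    def test_reference_value(self, diffusion_scenario):
        assert gb.min_fraction_in_layer(
            Quantity(0.5, "s"), diffusion_scenario
        ) == pytest.approx(0.9403, abs=1e-3)

    def test_limits(self, diffusion_scenario):
        assert gb.min_fraction_in_layer(Quantity(1e5, "s"), diffusion_scenario) > 0.999
        assert gb.min_fraction_in_layer(Quantity(1e-9, "s"), diffusion_scenario) < 1e-6


class TestFdOracle:
    def test_agrees_with_closed_form(self, diffusion_scenario):
        """PDE solved numerically matches the erf solution to 1e-3 of c0."""
        dx = Quantity(2.7e-7, "m")
        dt = Quantity(2.7e-7**2 / (6 * 1.3e-9), "s")
        profile = gb.fd_oracle(diffusion_scenario, Quantity(0.5, "s"), dx, dt)
        c0 = diffusion_scenario.c0.m_as("M")
        exact = np.array(
            [
                gb.concentration_at(
                    Quantity(x, "m"), Quantity(0.5, "s"), diffusion_scenario
                ).m_as("M")
                for x in profile.x_grid
            ]
        )
        err = np.abs(profile.concentrations[0] - exact) / c0
        assert err[2:].max() < 1e-3

    def test_zero_initial_condition(self, diffusion_scenario):
        dx = Quantity(1e-6, "m")
        dt = Quantity(1e-6**2 / (6 * 1.3e-9), "s")
        profile = gb.fd_oracle(diffusion_scenario, Quantity(1e-6, "s"), dx, dt)
        # one tiny step: interior still essentially zero beyond the first node
        assert np.all(profile.concentrations[0, 2:] == 0.0)

    def test_refinement_reduces_error_about_4x(self, diffusion_scenario):
        """Halving dx (and dt/4) shrinks the max error ~4x (2nd order in dx)."""
        c0 = diffusion_scenario.c0.m_as("M")
        errors = []
        for dx_m in [5.4e-7, 2.7e-7]:
            # fixed stable ratio r = 1/4 so the dt/4 scaling is exact
            dt_m = dx_m**2 / (4 * 1.3e-9)
            profile = gb.fd_oracle(
                diffusion_scenario, Quantity(0.5, "s"),
                Quantity(dx_m, "m"), Quantity(dt_m, "s"),
            )
            exact = c0 * np.array(
                [
                    gb.concentration_at(
                        Quantity(x, "m"), Quantity(0.5, "s"), diffusion_scenario
                    ).m_as("M")
                    / c0
                    for x in profile.x_grid
                ]
            )
            errors.append(np.abs(profile.concentrations[0] - exact)[2:].max() / c0)
        ratio = errors[0] / errors[1]
        assert 2.5 < ratio < 6.0

    def test_unstable_steps_rejected(self, diffusion_scenario):
        dx = Quantity(1e-7, "m")
        dt_unstable = Quantity(1e-7**2 / (1.3e-9), "s")  # r = 1 > 1/2
        with pytest.raises(gb.ParameterError, match="unstable"):
            gb.fd_oracle(diffusion_scenario, Quantity(0.1, "s"), dx, dt_unstable)

    def test_short_domain_rejected(self, diffusion_scenario):
        dx = Quantity(2.7e-7, "m")
        dt = Quantity(2.7e-7**2 / (6 * 1.3e-9), "s")
        with pytest.raises(gb.ParameterError, match="domain_length"):
            gb.fd_oracle(
                diffusion_scenario, Quantity(0.5, "s"), dx, dt,
                domain_length=Quantity(5, "um"),
            )
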