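"""Closed-form RVE model: units, bookkeeping, stress/strain maps."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fiberweb import model
from fiberweb.exceptions import (
    DegenerateGeometryError,
    FiberwebError,
    InconsistentMeasurementError,
    NonInvertibleError,
)

hyp = settings(derandomize=True, max_examples=100, deadline=None)


# ---------------------------------------------------------------------------
# geometry and porosity
# ---------------------------------------------------------------------------


class TestGeometry:
    def test_ratio_and_angle(self):
        g = model.MembraneGeometry(L=40.0, W=5.0, T=0.11)
        assert g.k == 5.0 / 40.0 == 0.125
        assert g.theta == math.atan(0.125)

    def test_wide_specimen_warns_but_constructs(self):
        with pytest.warns(UserWarning, match="k ="):
            g = model.MembraneGeometry(L=1.0, W=2.0, T=0.1)
        assert g.k == 2.0

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(FiberwebError):
            model.MembraneGeometry(L=0.0, W=1.0, T=0.1)


class TestPorosityFromMass:
    # M1 for a 50 x 5 x 0.11 mm specimen of a 1.3 g/cm^3 solid
    M1 = 50 * 5 * 0.11 * 1e-3 * 1.3

    @pytest.mark.parametrize(
        "m2_frac, expected",
        [(1.0, 0.0), (0.5, 0.5), (0.25, 0.75)],
    )
    def test_mass_fractions(self, m2_frac, expected):
        P = model.porosity_from_mass(self.M1 * m2_frac, 50, 5, 0.11, 1.3)
        assert P == pytest.approx(expected, abs=1e-12)

    def test_overweight_specimen_rejected(self):
        with pytest.raises(InconsistentMeasurementError):
            model.porosity_from_mass(self.M1 * 1.01, 50, 5, 0.11, 1.3)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(FiberwebError):
            model.porosity_from_mass(0.01, 50, -5, 0.11, 1.3)


# ---------------------------------------------------------------------------
# fiber count and lengths
# ---------------------------------------------------------------------------


class TestFiberCount:
    def test_forced_single_fiber(self):
        # choose r so L*T*(1-P) = 2*pi*r^2 exactly -> Nf = 1
        L, T, P = 1.0, 0.1, 0.5
        r = math.sqrt(L * T * (1 - P) / (2 * math.pi))
        assert model.fiber_count(L, T, P, r) == 1

    def test_reference_geometry_against_exact_rational(self):
        # oracle: evaluate the closure formula in exact arithmetic (sympy pi)
        import sympy

        L, T, P, r = 1, Fraction(11, 100), Fraction(3, 4), Fraction(136, 10**6)
        exact = sympy.Rational(L) * T * (1 - P) / (sympy.pi * r * r) - 1
        expected = int(sympy.floor(exact + sympy.Rational(1, 2)))
        assert model.fiber_count(1.0, 0.11, 0.75, 136e-6) == expected

    def test_porosity_closure_roundtrip(self):
        # the returned count reproduces the requested solid volume to < 1 part
        # in Nf (rounding): pi r^2 * L*(Nf+1) ~= L^2 T (1-P)
        L, T, P, r = 1.0, 0.11, 0.75, 136e-6
        Nf = model.fiber_count(L, T, P, r)
        vf = math.pi * r * r * float(model.fiber_lengths(Nf, L).sum())
        assert vf == pytest.approx(L * L * T * (1 - P), rel=2.0 / Nf)

    def test_degenerate_porosity_limit(self):
        with pytest.raises(DegenerateGeometryError):
            model.fiber_count(1.0, 0.11, 1 - 1e-12, 136e-3)


class TestFiberLengths:
    def test_single_fiber_is_diagonal_scale(self):
        assert model.fiber_lengths(1, 3.0).tolist() == [6.0]

    def test_two_fibers(self):
        assert model.fiber_lengths(2, 1.0).tolist() == [1.0, 2.0]

    @pytest.mark.parametrize("Nf", [4, 17, 1000])
    def test_sum_matches_closed_form_exactly(self, Nf):
        # brute-force rational sum of i*(2L/Nf) vs the closed form L*(Nf+1)
        L = Fraction(7, 3)
        brute = sum(Fraction(i) * 2 * L / Nf for i in range(1, Nf + 1))
        assert brute == L * (Nf + 1)
        got = model.fiber_lengths(Nf, float(L))
        assert float(got.sum()) == pytest.approx(float(L * (Nf + 1)), rel=1e-12)

    def test_extremes(self):
        L, Nf = 2.5, 1000
        lens = model.fiber_lengths(Nf, L)
        assert lens.max() == pytest.approx(2 * L, rel=1e-15)
        assert lens.min() == pytest.approx(2 * L / Nf, rel=1e-15)

    def test_million_fiber_sum_is_exact_in_units_of_the_step(self):
        # in units of delta_l the lengths are the integers 1..Nf
        Nf = 10**6
        assert Nf * (Nf + 1) // 2 == sum(range(1, Nf + 1))


def test_specimen_fraction_examples():
    assert model.specimen_fraction(1.0, 1.0) == 1.0
    assert model.specimen_fraction(5.0, 50.0) == pytest.approx(0.1)
    assert model.specimen_fraction(1.0, 8.0) == pytest.approx(0.125)


@pytest.mark.parametrize(
    "alpha, factor",
    [(0.0, 1.0), (math.pi / 2, 0.0), (math.pi / 3, 0.25)],
)
def test_fiber_axial_force_projection(alpha, factor):
    r = 1.36e-4
    expected = 400.0 * math.pi * r * r * factor
    assert model.fiber_axial_force(400.0, r, alpha) == pytest.approx(
        expected, abs=1e-18
    )


# ---------------------------------------------------------------------------
# membrane stress: boundary values, oracle, properties
# ---------------------------------------------------------------------------


def _quadrature_stress(sigma_f: float, P: float, k: float) -> float:
    """Independent oracle: numerical quadrature of the orientation integral.

    Membrane force per unit cross-section: (2 T W (1-P) sigma_f / pi)
    * integral_0^theta cos^2(a) da, divided by T*W.
    """
    theta = math.atan(k)
    integral, _ = quad(lambda a: math.cos(a) ** 2, 0.0, theta, epsabs=1e-14)
    return 2.0 * (1.0 - P) * sigma_f / math.pi * integral


class TestMembraneStress:
    def test_zero_width_ratio_gives_exactly_zero(self):
        for sigma_f in (1.0, 400.0, 12345.6):
            for P in (0.0, 0.5, 0.75, 0.99):
                assert model.membrane_stress(sigma_f, P, 0.0) == 0.0

    def test_wide_limit_approaches_half_solidity(self):
        val = model.membrane_stress(400.0, 0.75, 1e9)
        assert val == pytest.approx((1 - 0.75) * 400.0 / 2, rel=1e-8)

    def test_reference_point_against_quadrature(self):
        got = model.membrane_stress(400.0, 0.75, 0.125)
        assert got == pytest.approx(_quadrature_stress(400.0, 0.75, 0.125), rel=1e-12)
        assert got == pytest.approx(7.876, abs=5e-3)

    def test_quadrature_oracle_over_grid(self):
        for P in np.linspace(0.0, 0.99, 8):
            for k in np.linspace(0.01, 10.0, 8):
                assert model.membrane_stress(111.0, P, k) == pytest.approx(
                    _quadrature_stress(111.0, P, k), rel=1e-10
                )

    def test_angle_and_ratio_forms_agree(self):
        k = np.linspace(0.0, 10.0, 401)
        a = model.orientation_factor(k)
        b = model.orientation_factor_from_angle(np.arctan(k))
        np.testing.assert_allclose(a, b, rtol=1e-13)

    def test_bound_and_monotonicity(self):
        k = np.linspace(0.0, 25.0, 300)
        for P in (0.0, 0.5, 0.9):
            s = model.membrane_stress(1.0, P, k)
            assert np.all(s >= 0)
            assert np.all(s <= (1 - P) / 2 + 1e-15)
            assert np.all(np.diff(s) >= 0)  # nondecreasing in k
        P_grid = np.linspace(0.0, 0.98, 200)
        s = model.membrane_stress(1.0, P_grid, 0.5)
        assert np.all(np.diff(s) < 0)  # strictly decreasing in P

    def test_linear_in_fiber_stress(self):
        s1 = model.membrane_stress(1.0, 0.6, 0.3)
        s400 = model.membrane_stress(400.0, 0.6, 0.3)
        assert s400 == pytest.approx(400 * s1, rel=1e-14)

    def test_exact_mode_subtracts_fiber_cross_section(self):
        L, T, r = 1.0, 0.11, 1.36e-4
        approx = model.membrane_stress(400.0, 0.75, 0.125)
        exact = model.membrane_stress(400.0, 0.75, 0.125, exact=True, L=L, T=T, r=r)
        correction = math.pi * r * r / (L * T) / (1 - 0.75)
        assert exact == pytest.approx(approx * (1 - correction), rel=1e-12)
        with pytest.raises(FiberwebError):
            model.membrane_stress(400.0, 0.75, 0.125, exact=True)

    def test_invalid_domains_rejected(self):
        with pytest.raises(FiberwebError):
            model.membrane_stress(1.0, 1.0, 0.5)
        with pytest.raises(FiberwebError):
            model.membrane_stress(1.0, 0.5, -0.1)


class TestInverse:
    def test_zero_membrane_stress_maps_to_zero(self):
        assert model.fiber_stress_from_membrane(0.0, 0.75, 0.125) == 0.0

    def test_reference_inversion_against_quadrature(self):
        # invert the quadrature oracle at the study conditions
        scale = _quadrature_stress(1.0, 0.75, 0.125)
        expected = 4.11 / scale
        got = model.fiber_stress_from_membrane(4.11, 0.75, 0.125)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(208.7, abs=0.1)

    def test_zero_ratio_not_invertible(self):
        with pytest.raises(NonInvertibleError):
            model.fiber_stress_from_membrane(1.0, 0.5, 0.0)

    @hyp
    @given(
        sigma_f=st.floats(0.0, 1e4),
        P=st.floats(0.0, 0.99),
        k=st.floats(1e-6, 50.0),
    )
    def test_round_trip_identity(self, sigma_f, P, k):
        sigma = model.membrane_stress(sigma_f, P, k)
        back = model.fiber_stress_from_membrane(sigma, P, k)
        assert back == pytest.approx(sigma_f, rel=1e-12, abs=1e-12)

    def test_calibration_constant_round_trips(self):
        sigma = model.membrane_stress(400.0, 0.75, 0.125, calibration=1.4)
        back = model.fiber_stress_from_membrane(sigma, 0.75, 0.125, calibration=1.4)
        assert back == pytest.approx(400.0, rel=1e-12)


# ---------------------------------------------------------------------------
# strain maps
# ---------------------------------------------------------------------------


class TestStrainMaps:
    @pytest.mark.parametrize(
        "alpha, nu, expected_factor",
        [(0.0, 0.7, 1.0), (math.pi / 2, 0.7, -0.7), (math.pi / 4, 1.0, 0.0)],
    )
    def test_angle_map_special_cases(self, alpha, nu, expected_factor):
        assert model.fiber_strain(0.04, alpha, nu) == pytest.approx(
            0.04 * expected_factor, abs=1e-15
        )

    def test_specimen_map_special_cases(self):
        assert model.fiber_strain_specimen(0.04, 0.0, 5.0) == pytest.approx(0.04)
        assert model.fiber_strain_specimen(0.04, 1.0, 0.0) == pytest.approx(0.02)

    @hyp
    @given(
        eps=st.floats(-0.5, 0.5),
        k=st.floats(0.0, 20.0),
        nu=st.floats(0.0, 3.0),
    )
    def test_specimen_map_equals_angle_map_at_cutoff(self, eps, k, nu):
        a = model.fiber_strain_specimen(eps, k, nu)
        b = model.fiber_strain(eps, math.atan(k), nu)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-15)

    def test_contraction_implied_by_study_strains(self):
        # membrane strain 0.049 mapping to fiber strain 0.047 at k = 0.125
        # requires nu ~ 1.65 (solve the specimen map for nu)
        k = 0.125
        nu = (1 - 0.047 / 0.049 * (1 + k * k)) / (k * k)
        assert nu == pytest.approx(1.65, abs=0.01)
        assert model.fiber_strain_specimen(0.049, k, nu) == pytest.approx(0.047)

    def test_contraction_coefficient(self):
        assert model.contraction_coefficient(0.04, 0.04) == 1.0
        assert model.contraction_coefficient(0.0, 0.04) == 0.0
        assert model.contraction_coefficient(0.02, 0.04) == pytest.approx(0.5)
        with pytest.raises(FiberwebError):
            model.contraction_coefficient(0.02, 0.0)


# ---------------------------------------------------------------------------
# curve transform and parametric surface
# ---------------------------------------------------------------------------


class TestTransformCurve:
    def test_per_point_composition_of_the_two_maps(self):
        from fiberweb.curves import StressStrainCurve

        eps = np.linspace(0.001, 0.5, 40)
        sig = 90.0 * eps  # linear membrane record
        curve = StressStrainCurve(strain=eps, stress=sig)
        P, k, nu = 0.75, 0.125, 1.65
        out = model.transform_membrane_curve(curve, P, k, nu)
        np.testing.assert_allclose(
            out.strain, model.fiber_strain_specimen(eps, k, nu), rtol=1e-14
        )
        np.testing.assert_allclose(
            out.stress,
            model.fiber_stress_from_membrane(sig, P, k),
            rtol=1e-14,
        )
        # linear curve in, linear curve out: slope = stress factor/strain factor
        slopes = np.diff(out.stress) / np.diff(out.strain)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)

    def test_strain_profile_callable(self):
        from fiberweb.curves import StressStrainCurve

        eps = np.linspace(0.01, 0.5, 20)
        curve = StressStrainCurve(strain=eps, stress=10 * eps)
        out = model.transform_membrane_curve(curve, 0.5, 0.2, lambda e: 1.0 + e)
        nu = 1.0 + eps
        np.testing.assert_allclose(
            out.strain, model.fiber_strain_specimen(eps, 0.2, nu), rtol=1e-14
        )

    def test_non_monotone_output_rejected(self):
        from fiberweb.curves import StressStrainCurve
        from fiberweb.exceptions import CurveValidationError

        eps = np.linspace(0.01, 0.5, 20)
        curve = StressStrainCurve(strain=eps, stress=10 * eps)
        # nu grows so fast that 1 - nu k^2 changes sign across the range
        with pytest.raises(CurveValidationError):
            model.transform_membrane_curve(curve, 0.5, 1.0, lambda e: 10.0 * e)


class TestParametricSurface:
    def test_zero_ratio_column_and_monotonicity(self):
        P_vals = np.linspace(0.5, 0.95, 10)
        k_vals = np.concatenate([[0.0], np.linspace(0.05, 2.0, 12)])
        grid = model.parametric_stress_surface(P_vals, k_vals, 400.0)
        assert grid.shape == (10, 13)
        np.testing.assert_array_equal(grid[:, 0], 0.0)
        assert np.all(np.diff(grid[:, 1:], axis=0) < 0)  # decreasing in P
        assert np.all(np.diff(grid, axis=1) >= 0)  # nondecreasing in k

    def test_single_cell_matches_point_evaluation(self):
        grid = model.parametric_stress_surface([0.75], [0.125], 400.0)
        assert grid[0, 0] == pytest.approx(7.876, abs=5e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(FiberwebError):
            model.parametric_stress_surface([], [0.1], 400.0)
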