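"""Electron transport: quantum efficiency, NRH kinetics, capacity profiles,
whole-leaf integration and the J_max/V_cmax outputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoacclim.etr import (
    ETRParams,
    capacity_integral_batch,
    capacity_profile,
    cuvette_correction,
    integrate_jleaf,
    jc_rate,
    jleaf_batch,
    operational_jmax,
    quantum_efficiency,
    vcmax,
)
from photoacclim.exceptions import InvalidInputError
from photoacclim.profile import ProfileParams, absorbed_light


class TestQuantumEfficiency:
    def test_reference_value(self):
        assert round(quantum_efficiency(0.0, 0.88), 3) == 0.468

    def test_all_cyclic_flow_gives_zero(self):
        assert quantum_efficiency(1.0, 0.88) == 0.0

    def test_perfect_psii_gives_half(self):
        assert quantum_efficiency(0.0, 1.0) == pytest.approx(0.5)

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            quantum_efficiency(-0.1, 0.88)
        with pytest.raises(InvalidInputError):
            quantum_efficiency(0.0, 0.0)


class TestCuvetteCorrection:
    def test_opaque_leaf(self):
        assert cuvette_correction(0.0, 0.5, 800.0) == (1.0, 800.0)

    def test_black_chamber(self):
        assert cuvette_correction(0.2, 0.0, 800.0) == (1.0, 800.0)

    def test_arithmetic(self):
        w, i0 = cuvette_correction(0.1, 0.5, 1.0)
        assert w == pytest.approx(1 / 1.05, abs=1e-4)
        assert i0 == pytest.approx(1.05)


class TestCapacityProfile:
    def test_unclamped_equals_light_set_value(self, default_profile):
        params = ETRParams(jc_max_mn=0.0, jc_max_mx=np.inf, i_star=300.0,
                           w_u_g=0.9)
        c = np.linspace(0, 40, 11)
        got = capacity_profile(c, params, default_profile, 40.0)
        mod = default_profile.with_k(params.p3 * default_profile.k)
        expected = params.phi * 90.0 * absorbed_light(c, 0.9, 300.0, mod, 40.0)
        assert np.allclose(got, expected, rtol=1e-12)

    def test_zero_acclimation_light_floors_at_minimum(self, default_profile):
        params = ETRParams(jc_max_mn=150.0, jc_max_mx=400.0, i_star=0.0)
        got = capacity_profile(np.linspace(0, 40, 11), params,
                               default_profile, 40.0)
        assert np.allclose(got, 150.0)

    def test_huge_acclimation_light_saturates_at_maximum(self, default_profile):
        params = ETRParams(jc_max_mn=150.0, jc_max_mx=400.0, i_star=1e9)
        got = capacity_profile(np.linspace(0, 40, 11), params,
                               default_profile, 40.0)
        assert np.allclose(got, 400.0)

    def test_inverted_limits_rejected(self):
        with pytest.raises(InvalidInputError):
            ETRParams(jc_max_mn=400.0, jc_max_mx=150.0)


class TestJcRate:
    def test_dark_gives_zero(self):
        assert jc_rate(0.0, 200.0, 0.468, 0.9) == 0.0

    def test_blackman_limit_is_exact_min(self):
        x = 30.0 / 0.468
        assert jc_rate(x, 100.0, 0.468, 1.0) == pytest.approx(30.0, abs=1e-12)
        x = 500.0 / 0.468
        assert jc_rate(x, 100.0, 0.468, 1.0) == pytest.approx(100.0, abs=1e-10)

    def test_against_quadratic_root_oracle(self):
        phi, theta = 0.468, 0.962
        ia, jmax = 100.0 / phi, 100.0
        roots = np.roots([theta, -(phi * ia + jmax), phi * ia * jmax])
        expected = roots.min()
        got = jc_rate(ia, jmax, phi, theta)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(83.69, abs=0.005)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.0, 1e3),
        y=st.floats(1e-3, 1e3),
        theta=st.floats(0.01, 1.0),
    )
    def test_bounded_by_blackman_min(self, x, y, theta):
        j = jc_rate(x, y, 1.0, theta)
        assert 0.0 <= j <= min(x, y) + 1e-9

    def test_blackman_identity_across_sweep(self):
        ia = np.linspace(0, 2000, 101)
        jmax = np.linspace(50, 500, 101)
        blackman = np.minimum(0.468 * ia, jmax)
        nrh = jc_rate(ia, jmax, 0.468, 1.0)
        assert np.max(np.abs(nrh - blackman)) < 1e-10


class TestIntegrateJleaf:
    def test_flat_saturated_integrand(self, default_profile):
        # capacity pinned at J0 everywhere and deeply saturating light
        params = ETRParams(jc_max_mn=100.0, jc_max_mx=100.0, i_star=0.0,
                           theta=1.0, w_u_m=1.0)
        jl = integrate_jleaf(1e7, 40.0, params, default_profile)
        assert jl == pytest.approx(100.0 * 40.0 * 10.0 / 900.0, rel=1e-10)

    def test_light_limited_limit(self, default_profile):
        params = ETRParams(jc_max_mn=300.0, jc_max_mx=900.0, i_star=500.0,
                           w_u_m=0.95)
        i0 = 1e-3
        jl = integrate_jleaf(i0, 40.0, params, default_profile)
        c = np.linspace(0, 40, 20001)
        ia = absorbed_light(c, 0.95, i0, default_profile, 40.0)
        expected = params.phi * np.trapezoid(ia, c)
        assert jl == pytest.approx(expected, rel=1e-4)

    def test_riemann_oracle(self, default_profile):
        params = ETRParams(jc_max_mn=161.0, jc_max_mx=2.6 * 161.0,
                           i_star=300.0, w_u_g=0.9, w_u_m=0.95)
        jl = integrate_jleaf(1000.0, 40.0, params, default_profile)
        c = np.linspace(0, 40, 100001)
        conv = 90.0
        ia = absorbed_light(c, 0.95, 1000.0, default_profile, 40.0) * conv
        jmax = capacity_profile(c, params, default_profile, 40.0)
        ref = np.trapezoid(
            jc_rate(ia, jmax, params.phi, params.theta), c
        ) * 10.0 / 900.0
        assert jl == pytest.approx(ref, rel=1e-3)

    def test_monotone_and_concave_in_light(self, default_profile):
        params = ETRParams(jc_max_mn=100.0, jc_max_mx=400.0, i_star=300.0)
        i0 = np.linspace(10, 2000, 25)
        jl = np.array([
            integrate_jleaf(x, 40.0, params, default_profile) for x in i0
        ])
        assert np.all(np.diff(jl) >= -1e-9)
        assert np.all(np.diff(jl, 2) <= 1e-6)

    def test_unit_audit_lower_bound_leaf_rate(self, default_profile):
        # capacity floor 161 mmol e-/mol Chl/s over 40 ug/cm2 of Chl
        params = ETRParams(jc_max_mn=161.0, jc_max_mx=161.0, i_star=0.0,
                           theta=1.0)
        jl = integrate_jleaf(1e7, 40.0, params, default_profile)
        assert 71.0 <= jl <= 72.0

    def test_batch_kernel_matches_scalar_path(self, default_profile):
        params = ETRParams(jc_max_mn=161.0, jc_max_mx=418.6, i_star=300.0,
                           w_u_g=0.9, w_u_m=0.95)
        for i0 in (100.0, 600.0, 1500.0):
            scalar = integrate_jleaf(i0, 40.0, params, default_profile)
            batch = jleaf_batch(
                i0, 40.0, default_profile.p1ka, default_profile.k, 0.664,
                300.0, 161.0, 418.6, params.phi, params.theta, params.p3,
                0.9, 0.95,
            )
            assert batch[0] == pytest.approx(scalar, rel=2e-4)


class TestJmaxVcmax:
    def test_operational_jmax_monotone_in_reference_light(
            self, default_profile):
        params = ETRParams(jc_max_mn=100.0, jc_max_mx=400.0, i_star=300.0)
        vals = [operational_jmax(params, default_profile, 40.0, i0_ref=x,
                                 T=0.15) for x in (500.0, 1000.0, 1500.0)]
        assert vals[0] <= vals[1] <= vals[2]

    def test_operational_jmax_is_leaf_rate_at_corrected_light(
            self, default_profile):
        params = ETRParams(jc_max_mn=100.0, jc_max_mx=400.0, i_star=300.0)
        w_u_m, i0p = cuvette_correction(0.15, 0.5, 1500.0)
        direct = integrate_jleaf(
            i0p, 40.0, params.replace(w_u_m=w_u_m), default_profile
        )
        assert operational_jmax(params, default_profile, 40.0, T=0.15) == \
            pytest.approx(direct, rel=1e-12)

    def test_saturation_limit_reaches_capacity_integral(self, default_profile):
        params = ETRParams(jc_max_mn=100.0, jc_max_mx=400.0, i_star=300.0,
                           theta=1.0, w_u_m=1.0)
        sat = integrate_jleaf(1e8, 40.0, params, default_profile)
        cap = vcmax(params.replace(p4=1.0), default_profile, 40.0)
        assert sat == pytest.approx(cap, rel=1e-8)

    def test_vcmax_constant_capacity(self, default_profile):
        params = ETRParams(jc_max_mn=100.0, jc_max_mx=100.0, i_star=0.0,
                           p4=0.437)
        assert vcmax(params, default_profile, 40.0) == pytest.approx(
            0.437 * 100.0 * 40.0 * 10.0 / 900.0, rel=1e-10
        )

    def test_vcmax_linear_in_p4(self, default_profile):
        p1 = ETRParams(jc_max_mn=150.0, jc_max_mx=400.0, i_star=300.0, p4=0.2)
        p2 = p1.replace(p4=0.4)
        assert vcmax(p2, default_profile, 40.0) == pytest.approx(
            2.0 * vcmax(p1, default_profile, 40.0), rel=1e-12
        )

    def test_vcmax_ratio_identity(self, default_profile):
        params = ETRParams(jc_max_mn=150.0, jc_max_mx=400.0, i_star=300.0,
                           p4=0.437)
        cap = vcmax(params.replace(p4=1.0), default_profile, 40.0)
        assert vcmax(params, default_profile, 40.0) / cap == pytest.approx(
            0.437, rel=1e-12
        )

    def test_measurement_side_never_touches_vcmax(self, default_profile):
        base = ETRParams(jc_max_mn=150.0, jc_max_mx=400.0, i_star=300.0,
                         w_u_g=0.7, w_u_m=1.0)
        alt = base.replace(w_u_m=0.6)
        assert vcmax(base, default_profile, 40.0) == vcmax(
            alt, default_profile, 40.0
        )

    def test_unclamped_capacity_integral_invariant_to_growth_side(
            self, default_profile):
        # without clamping the two-sided profile integrates to the same
        # total whichever side the light arrives from
        base = ETRParams(jc_max_mn=0.0, jc_max_mx=np.inf, i_star=300.0,
                         w_u_g=0.9)
        alt = base.replace(w_u_g=0.5)
        assert vcmax(base, default_profile, 40.0) == pytest.approx(
            vcmax(alt, default_profile, 40.0), rel=1e-9
        )

    def test_growth_side_changes_both_outputs_when_clamped(
            self, default_profile):
        # partial clamping breaks the two-sided symmetry
        base = ETRParams(jc_max_mn=280.0, jc_max_mx=360.0, i_star=300.0,
                         w_u_g=0.9)
        alt = base.replace(w_u_g=0.5)
        assert vcmax(base, default_profile, 40.0) != pytest.approx(
            vcmax(alt, default_profile, 40.0), rel=1e-6
        )
        assert integrate_jleaf(800.0, 40.0, base, default_profile) != \
            pytest.approx(
                integrate_jleaf(800.0, 40.0, alt, default_profile), rel=1e-6
            )

    def test_capacity_batch_matches_vcmax(self, default_profile):
        params = ETRParams(jc_max_mn=161.0, jc_max_mx=418.6, i_star=300.0,
                           w_u_g=0.9, p4=0.437)
        batch = 0.437 * capacity_integral_batch(
            40.0, default_profile.p1ka, default_profile.k, 0.664, 300.0,
            161.0, 418.6, params.phi, params.p3, 0.9,
        )
        assert batch[0] == pytest.approx(
            vcmax(params, default_profile, 40.0), rel=2e-4
        )
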