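"""Two-stream radiation transfer: closed form, Fresnel boundaries,
inversion and synthetic spectra."""

import types

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from photoacclim.exceptions import InvalidInputError, NoSolutionError
from photoacclim.optics import (
    InterfaceReflectances,
    SpectralGrid,
    TwoStreamCoefficients,
    TwoStreamSolution,
    default_absorption_table,
    diffuse_interface_reflectance,
    invert_RT,
    solve_two_stream,
    synth_leaf_spectrum,
)
from photoacclim.profile import LeafTraits


def _fresnel_reference(n1, n2):
    """Independent oracle: adaptive quadrature of the unpolarized Fresnel
    reflectance with cosine weighting (TIR handled by the integrand)."""

    def f(theta):
        s2 = n1 / n2 * np.sin(theta)
        if s2 >= 1.0:
            r = 1.0
        else:
            c1, c2 = np.cos(theta), np.sqrt(1 - s2**2)
            rs = ((n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)) ** 2
            rp = ((n2 * c1 - n1 * c2) / (n2 * c1 + n1 * c2)) ** 2
            r = 0.5 * (rs + rp)
        return r * 2 * np.sin(theta) * np.cos(theta)

    if n1 > n2:
        crit = np.arcsin(n2 / n1)
        val, _ = integrate.quad(f, 0, crit, limit=200)
        return val + (1 - (n2 / n1) ** 2)
    val, _ = integrate.quad(f, 0, np.pi / 2, limit=200)
    return val


class TestDiffuseInterface:
    def test_matched_index_reflects_nothing(self):
        iface = diffuse_interface_reflectance(1.0)
        assert iface.r_e == 0.0 and iface.r_i == 0.0

    def test_against_adaptive_quadrature_oracle(self):
        iface = diffuse_interface_reflectance(1.5)
        assert iface.r_e == pytest.approx(_fresnel_reference(1.0, 1.5), abs=1e-8)
        assert iface.r_i == pytest.approx(_fresnel_reference(1.5, 1.0), abs=1e-6)
        assert 0.08 < iface.r_e < 0.10  # the classic ~0.09 diffuse value
        assert iface.r_i > 5 * iface.r_e

    @pytest.mark.parametrize("n", [1.1, 1.33, 1.4, 1.5, 1.7])
    def test_radiance_invariance_identity(self, n):
        iface = diffuse_interface_reflectance(n)
        assert (1 - iface.r_i) == pytest.approx((1 - iface.r_e) / n**2,
                                                abs=1e-6)
        assert iface.r_i >= iface.r_e

    def test_limits_to_zero_as_n_to_one(self):
        iface = diffuse_interface_reflectance(1.0001)
        assert iface.r_e < 1e-3 and iface.r_i < 2e-2

    def test_rejects_subunity_index(self):
        with pytest.raises(InvalidInputError):
            diffuse_interface_reflectance(0.9)


def _bvp_oracle(ks, ka, re, ri, chl):
    """Independent numerical two-point boundary-value solution."""

    def rhs(c, y):
        Id, Iu = y
        return np.vstack([-(ks + ka) * Id + ks * Iu,
                          (ks + ka) * Iu - ks * Id])

    def bc(y0, y1):
        return np.array([y0[0] - (1 - re) - ri * y0[1],
                         y1[1] - ri * y1[0]])

    c = np.linspace(0, chl, 201)
    guess = np.vstack([np.exp(-(ks + ka) * c), np.zeros_like(c)])
    sol = integrate.solve_bvp(rhs, bc, c, guess, tol=1e-10, max_nodes=40000)
    assert sol.status == 0
    R = sol.y[1][0] * (1 - ri) + re
    T = sol.y[0][-1] * (1 - ri)
    return R, T, sol


class TestTwoStreamSolution:
    def test_transparent_slab(self):
        prof, R, T = solve_two_stream(
            TwoStreamCoefficients(0.0, 0.0), InterfaceReflectances.none(), 50.0
        )
        assert R == pytest.approx(0.0, abs=1e-14)
        assert T == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(prof.I_d, 1.0) and np.allclose(prof.I_u, 0.0)

    def test_beer_lambert_limit(self):
        _, R, T = solve_two_stream(
            TwoStreamCoefficients(0.0, 0.02), InterfaceReflectances.none(), 50.0
        )
        assert T == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert R == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize(
        "ks,ka,re,ri,chl",
        [
            (0.01, 0.02, 0.05, 0.4, 50.0),
            (0.05, 0.001, 0.09, 0.6, 40.0),
            (0.002, 0.1, 0.0, 0.0, 30.0),
            (0.08, 0.03, 0.09, 0.59, 70.0),
        ],
    )
    def test_matches_bvp_oracle(self, ks, ka, re, ri, chl):
        prof, R, T = solve_two_stream(
            TwoStreamCoefficients(ks, ka), InterfaceReflectances(re, ri), chl
        )
        R_ref, T_ref, sol = _bvp_oracle(ks, ka, re, ri, chl)
        assert R == pytest.approx(R_ref, abs=1e-6)
        assert T == pytest.approx(T_ref, abs=1e-6)
        ref = sol.sol(prof.c)
        assert np.max(np.abs(prof.I_d - ref[0])) < 1e-6
        assert np.max(np.abs(prof.I_u - ref[1])) < 1e-6

    def test_boundary_conditions_satisfied(self):
        sol = TwoStreamSolution(0.03, 0.01, 0.09, 0.55, 45.0)
        (Id0, IdL), (Iu0, IuL) = sol.fluxes(np.array([0.0, 45.0]))
        assert Id0 == pytest.approx((1 - 0.09) + 0.55 * Iu0, abs=1e-12)
        assert IuL == pytest.approx(0.55 * IdL, abs=1e-12)

    def test_energy_conservation(self):
        for ks, ka, re, ri, chl in [
            (0.02, 0.03, 0.05, 0.4, 50.0),
            (0.1, 0.005, 0.09, 0.6, 60.0),
            (0.0, 0.05, 0.09, 0.6, 25.0),
        ]:
            sol = TwoStreamSolution(ks, ka, re, ri, chl)
            c = np.linspace(0, chl, 4001)
            Id, Iu = sol.fluxes(c)
            absorbed = integrate.simpson(ka * (Id + Iu), x=c)
            assert sol.R + sol.T + absorbed == pytest.approx(1.0, abs=1e-6)

    def test_extreme_optical_depth_does_not_overflow(self):
        sol = TwoStreamSolution(0.5, 5.0, 0.09, 0.6, 500.0)
        assert np.isfinite(sol.R) and np.isfinite(sol.T)
        assert sol.T == pytest.approx(0.0, abs=1e-200)
        assert 0 <= sol.R < 1

    def test_vectorized_matches_scalar(self):
        ks = np.array([0.01, 0.05])
        ka = np.array([0.02, 0.005])
        sol = TwoStreamSolution(ks, ka, 0.05, 0.4, 50.0)
        for i in range(2):
            s = TwoStreamSolution(ks[i], ka[i], 0.05, 0.4, 50.0)
            assert sol.R[i] == pytest.approx(float(s.R), abs=1e-14)
            assert sol.T[i] == pytest.approx(float(s.T), abs=1e-14)


class TestInvertRT:
    def test_beer_lambert_inversion(self):
        coeffs = invert_RT(0.0, np.exp(-1.0), InterfaceReflectances.none(), 50.0)
        assert coeffs.k_a == pytest.approx(0.02, abs=1e-8)
        assert coeffs.k_s == pytest.approx(0.0, abs=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ks=st.floats(1e-4, 0.2),
        ka=st.floats(1e-4, 0.2),
        ri=st.floats(0.0, 0.7),
    )
    def test_roundtrip_identity(self, ks, ka, ri):
        re = ri / 6.0
        iface = InterfaceReflectances(re, ri)
        _, R, T = solve_two_stream(TwoStreamCoefficients(ks, ka), iface, 40.0)
        back = invert_RT(R, T, iface, 40.0)
        assert back.k_s == pytest.approx(ks, abs=1e-6)
        assert back.k_a == pytest.approx(ka, abs=1e-6)

    def test_energy_violation_rejected(self):
        with pytest.raises(NoSolutionError, match="energy"):
            invert_RT(0.6, 0.5, InterfaceReflectances.none(), 40.0)

    def test_reflectance_below_interface_rejected(self):
        with pytest.raises(NoSolutionError, match="r_e"):
            invert_RT(0.01, 0.3, InterfaceReflectances(0.09, 0.6), 40.0)


class TestSpectralGrid:
    def test_par_grid(self):
        g = SpectralGrid.par()
        assert g.wavelengths[0] == 400.0 and g.wavelengths[-1] == 700.0
        assert len(g) == 61

    def test_rejects_bad_grids(self):
        with pytest.raises(InvalidInputError):
            SpectralGrid(np.array([500.0, 480.0]))
        with pytest.raises(InvalidInputError):
            SpectralGrid(np.array([300.0, 500.0]))


class TestSynthSpectrum:
    def test_non_absorbing_slab_conserves_energy(self):
        empty = types.SimpleNamespace(chl=0.0, car=0.0, lma=0.0)
        spec = synth_leaf_spectrum(empty, jitter_sd=0.0)
        assert np.allclose(spec.R + spec.T, 1.0, atol=1e-6)

    def test_doubling_chl_darkens_transmittance(self):
        lo = synth_leaf_spectrum(LeafTraits(25.0, 5.0, 40.0), jitter_sd=0.0)
        hi = synth_leaf_spectrum(LeafTraits(50.0, 5.0, 40.0), jitter_sd=0.0)
        assert np.all(hi.T <= lo.T + 1e-12)

    def test_deterministic_given_seed(self):
        t = LeafTraits(40.0, 8.0, 40.0)
        a = synth_leaf_spectrum(t, seed=11)
        b = synth_leaf_spectrum(t, seed=11)
        assert np.array_equal(a.R, b.R) and np.array_equal(a.T, b.T)
        c = synth_leaf_spectrum(t, seed=12)
        assert not np.array_equal(a.R, c.R)

    def test_coefficient_table_hook(self):
        grid = SpectralGrid.par()
        table = default_absorption_table(grid)
        spec = synth_leaf_spectrum(
            LeafTraits(40.0, 8.0, 40.0), coefficient_table=table,
            jitter_sd=0.0,
        )
        ref = synth_leaf_spectrum(LeafTraits(40.0, 8.0, 40.0), jitter_sd=0.0)
        assert np.allclose(spec.R, ref.R)

    def test_short_coefficient_table_rejected(self):
        grid = SpectralGrid.par()
        table = default_absorption_table(grid)
        short = table[table["wavelength_nm"] <= 600.0]
        with pytest.raises(InvalidInputError, match="covers"):
            synth_leaf_spectrum(
                LeafTraits(40.0, 8.0, 40.0), coefficient_table=short
            )
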