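"""Broadband integration and the stretched-exponential light profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoacclim.exceptions import GridMismatchError, InvalidInputError
from photoacclim.illuminant import Illuminant
from photoacclim.optics import (
    InterfaceReflectances,
    RadiationProfile,
    SpectralGrid,
    TwoStreamCoefficients,
    TwoStreamSolution,
)
from photoacclim.profile import (
    LeafTraits,
    ProfileParams,
    absorbed_light,
    broadband_profile,
    fit_profile_params,
    leaf_profile_pipeline,
    normalized_capacity_curve,
)


class TestLeafTraits:
    def test_ratio_consistency_enforced(self):
        LeafTraits(chl=50.0, car=10.0, lma=40.0, chl2car=5.0)
        with pytest.raises(InvalidInputError, match="chl2car"):
            LeafTraits(chl=50.0, car=10.0, lma=40.0, chl2car=6.0)

    def test_from_chl2car(self):
        t = LeafTraits.from_chl2car(50.0, 5.0, 40.0)
        assert t.car == pytest.approx(10.0)

    def test_positivity(self):
        with pytest.raises(InvalidInputError):
            LeafTraits(chl=0.0, car=1.0, lma=1.0)


class TestIlluminant:
    def test_d55_weights_normalized(self):
        ill = Illuminant.d55(SpectralGrid.par())
        assert ill.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ill.weights >= 0)

    def test_delta_puts_all_weight_on_one_node(self):
        ill = Illuminant.delta(SpectralGrid.par(), 550.0)
        assert ill.weights.max() == 1.0 and ill.weights.sum() == 1.0


def _spectral_profiles(ks, ka, chl, n_c=51):
    sol = TwoStreamSolution(ks, ka, 0.05, 0.4, chl)
    return sol.profile(n_c), TwoStreamCoefficients(ks, ka)


class TestBroadbandProfile:
    def test_delta_illuminant_selects_single_wavelength(self):
        grid = SpectralGrid.par()
        ks = np.linspace(0.01, 0.05, len(grid))
        ka = np.linspace(0.05, 0.01, len(grid))
        prof, coeffs = _spectral_profiles(ks, ka, 40.0)
        ill = Illuminant.delta(grid, 550.0)
        idx = int(np.argmax(ill.weights))
        I_c, ka_eff = broadband_profile(prof, coeffs, ill)
        assert np.allclose(I_c, prof.total[:, idx])
        assert ka_eff == pytest.approx(ka[idx])

    def test_flat_illuminant_constant_coefficients(self):
        grid = SpectralGrid.par()
        ks = np.full(len(grid), 0.02)
        ka = np.full(len(grid), 0.03)
        prof, coeffs = _spectral_profiles(ks, ka, 40.0)
        I_c, ka_eff = broadband_profile(prof, coeffs, Illuminant.flat(grid))
        assert np.allclose(I_c, prof.total[:, 0])
        assert ka_eff == pytest.approx(0.03)

    def test_two_wavelength_hand_computation(self):
        grid = SpectralGrid(np.array([450.0, 650.0]))
        ks = np.array([0.02, 0.01])
        ka = np.array([0.05, 0.02])
        prof, coeffs = _spectral_profiles(ks, ka, 40.0)
        ill = Illuminant(grid, np.array([0.25, 0.75]))
        I_c, ka_eff = broadband_profile(prof, coeffs, ill)
        assert np.allclose(I_c, 0.25 * prof.total[:, 0] + 0.75 * prof.total[:, 1])
        assert ka_eff == pytest.approx(0.25 * 0.05 + 0.75 * 0.02)

    def test_effectiveness_weighting_partitions_absorption(self):
        grid = SpectralGrid(np.array([450.0, 650.0]))
        ka = np.array([0.04, 0.04])
        prof, coeffs = _spectral_profiles(np.array([0.02, 0.02]), ka, 40.0)
        ill = Illuminant(grid, np.array([0.5, 0.5]))
        fractions = {"chl": np.array([0.5, 1.0]),
                     "car": np.array([0.5, 0.0])}
        _, ka_eff = broadband_profile(prof, coeffs, ill,
                                      absorption_fractions=fractions)
        # chl weight 1.0, car weight 0.7
        expected = 0.04 * 0.5 * (0.5 + 0.7 * 0.5) + 0.04 * 0.5 * 1.0
        assert ka_eff == pytest.approx(expected)

    def test_grid_mismatch_raises(self):
        grid = SpectralGrid.par()
        prof, coeffs = _spectral_profiles(
            np.full(10, 0.02), np.full(10, 0.03), 40.0
        )
        with pytest.raises(GridMismatchError):
            broadband_profile(prof, coeffs, Illuminant.flat(grid))


class TestFitProfileParams:
    def test_self_consistency(self):
        c = np.linspace(0, 50, 101)
        y = 1.1 * np.exp(-0.02 * c**0.664)
        params, rmse = fit_profile_params(y, c, 50.0)
        assert params.p1 == pytest.approx(1.1, abs=1e-6)
        assert params.k == pytest.approx(0.02, abs=1e-6)
        assert params.p2 == pytest.approx(0.664, abs=1e-6)
        assert rmse < 1e-8

    def test_fixed_p2_never_beats_free_p2(self):
        c = np.linspace(0, 50, 101)
        y = 1.1 * np.exp(-0.02 * c**0.664)
        _, rmse_free = fit_profile_params(y, c, 50.0)
        _, rmse_fixed = fit_profile_params(y, c, 50.0, fix_p2=1.0)
        assert rmse_fixed >= rmse_free

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_profile_params(np.ones(5), np.linspace(0, 1, 5), 50.0)


class TestAbsorbedLight:
    def test_one_sided_limit_reduces_to_single_exponential(
            self, default_profile):
        c = np.linspace(0, 40, 21)
        got = absorbed_light(c, 1.0, 1000.0, default_profile, 40.0)
        expected = 1000.0 * 0.033 * np.exp(-0.10 * c**0.664)
        assert np.allclose(got, expected, rtol=1e-12)

    def test_symmetric_incidence(self, default_profile):
        c = np.linspace(0, 40, 21)
        ia = absorbed_light(c, 0.5, 500.0, default_profile, 40.0)
        assert np.allclose(ia, ia[::-1], rtol=1e-12)

    def test_hand_arithmetic_example(self):
        # independently evaluated two-sided form
        params = ProfileParams.from_p1ka(0.012, 0.18, 0.664)
        got = absorbed_light(10.0, 0.9, 1000.0, params, 50.0)
        expected = 1000.0 * 0.012 * (
            0.9 * np.exp(-0.18 * 10.0**0.664)
            + 0.1 * np.exp(-0.18 * 40.0**0.664)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.01, 0.5), p2=st.floats(0.3, 1.5))
    def test_strictly_decreasing_for_topside_incidence(self, k, p2):
        params = ProfileParams(p1=1.2, p2=p2, k=k, ka=0.03)
        c = np.linspace(0, 40, 201)
        ia = absorbed_light(c, 1.0, 100.0, params, 40.0)
        assert np.all(np.diff(ia) < 0)

    def test_out_of_range_depth_rejected(self, default_profile):
        with pytest.raises(InvalidInputError):
            absorbed_light(41.0, 1.0, 100.0, default_profile, 40.0)


class TestNormalizedCapacityCurve:
    def test_unit_at_surface(self, default_profile):
        cn = normalized_capacity_curve(
            np.linspace(0, 40, 11), default_profile, 0.54, 0.9, 40.0
        )
        assert cn[0] == pytest.approx(1.0, abs=1e-12)

    def test_flat_limit_for_small_p3(self, default_profile):
        cn = normalized_capacity_curve(
            np.linspace(0, 40, 11), default_profile, 1e-8, 0.9, 40.0
        )
        assert np.allclose(cn, 1.0, atol=1e-5)

    def test_symmetry_for_balanced_incidence(self, default_profile):
        c = np.linspace(0, 40, 21)
        cn = normalized_capacity_curve(c, default_profile, 0.54, 0.5, 40.0)
        assert np.allclose(cn, cn[::-1], rtol=1e-12)

    def test_nonpositive_p3_rejected(self, default_profile):
        with pytest.raises(InvalidInputError):
            normalized_capacity_curve(
                np.linspace(0, 40, 11), default_profile, 0.0, 0.9, 40.0
            )


class TestPipeline:
    def test_pipeline_outputs_are_positive_and_reasonable(self, tomato_traits):
        out = leaf_profile_pipeline(tomato_traits, jitter_sd=0.0)
        assert 0 < out["p1ka"] < 0.2
        assert 0 < out["k"] < 1.0
        assert 0 < out["T"] < 1.0
        assert out["p2"] == 0.664

    def test_free_p2_below_one_for_real_leaf(self, tomato_traits):
        out = leaf_profile_pipeline(tomato_traits, jitter_sd=0.0, fix_p2=None)
        assert out["p2"] < 1.0
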