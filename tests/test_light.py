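"""Light field: Aiba response, Beer-Lambert attenuation, depth averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cyanopbr import (
    GROWTH_RESPONSE,
    LightConfig,
    OpticalParams,
    PhotoResponseParams,
    attenuation_coefficient,
    depth_averaged_response,
    local_intensity,
    optimal_intensity,
    photoresponse,
)


class TestPhotoresponse:
    def test_dark_limit_is_zero(self):
        assert photoresponse(0.0, GROWTH_RESPONSE) == 0.0

    def test_direct_evaluation(self):
        # I/(I + ks + I^2/ki) at I=457, ks=165, ki=457: 457/(457+165+457)
        assert photoresponse(457.0, GROWTH_RESPONSE) == pytest.approx(457.0 / 1079.0, rel=1e-12)

    def test_maximized_at_sqrt_ks_ki(self):
        I_star = optimal_intensity(GROWTH_RESPONSE)
        assert I_star == pytest.approx(np.sqrt(165.0 * 457.0), rel=1e-12)
        k_star = photoresponse(I_star, GROWTH_RESPONSE)
        for I in (0.5 * I_star, 0.99 * I_star, 1.01 * I_star, 3 * I_star):
            assert photoresponse(I, GROWTH_RESPONSE) < k_star

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            photoresponse(-1.0, GROWTH_RESPONSE)

    @given(I=st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, I):
        k = photoresponse(I, GROWTH_RESPONSE)
        assert 0.0 <= k < 1.0


class TestAttenuation:
    def test_bubble_only_limit(self, optics):
        assert attenuation_coefficient(0.0, optics) == pytest.approx(
            3 * 0.0067 / 0.002, rel=1e-12
        )

    def test_cell_term_dominates_at_half_gram(self, optics):
        # At 0.5 g/L the cell term (63 m^-1) is ~6.3x the bubble term (10.05);
        # commonly quoted rounded to "7 times".
        a = attenuation_coefficient(0.5, optics)
        assert a == pytest.approx(63.0 + 10.05, rel=1e-12)
        assert 63.0 / 10.05 == pytest.approx(6.27, abs=0.01)

    def test_high_density(self, optics):
        assert attenuation_coefficient(12.0, optics) == pytest.approx(1522.05, rel=1e-12)

    def test_negative_biomass_rejected(self, optics):
        with pytest.raises(ValueError):
            attenuation_coefficient(-0.1, optics)


class TestLocalIntensity:
    def test_surface_value(self, optics):
        lc = LightConfig(I0=92.0, L=0.025)
        assert local_intensity(0.0, 1.0, optics, lc) == pytest.approx(92.0)

    def test_back_face_attenuated(self, optics):
        lc = LightConfig(I0=92.0, L=0.025)
        expected = 92.0 * np.exp(-(126.0 + 10.05) * 0.025)
        assert local_intensity(0.025, 1.0, optics, lc) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.07, abs=0.01)

    def test_two_sided_mirror_symmetry(self, optics):
        lc = LightConfig(I0=200.0, L=0.1, n_surfaces=2)
        for z in (0.0, 0.013, 0.05, 0.09):
            assert local_intensity(z, 2.0, optics, lc) == pytest.approx(
                local_intensity(0.1 - z, 2.0, optics, lc), rel=1e-12
            )

    def test_depth_outside_reactor_rejected(self, optics):
        lc = LightConfig(I0=92.0, L=0.025)
        with pytest.raises(ValueError):
            local_intensity(0.03, 1.0, optics, lc)


class TestDepthAverage:
    def test_transparent_medium_recovers_surface_response(self, transparent_optics):
        lc = LightConfig(I0=457.0, L=0.025)
        kbar = depth_averaged_response(2.0, transparent_optics, lc, GROWTH_RESPONSE)
        assert kbar == pytest.approx(photoresponse(457.0, GROWTH_RESPONSE), rel=1e-12)

    def test_twenty_intervals_close_to_reference_at_high_density(self, optics):
        lc = LightConfig(I0=457.0, L=0.025)
        k20 = depth_averaged_response(12.0, optics, lc, GROWTH_RESPONSE)
        kref = depth_averaged_response(12.0, optics, lc, GROWTH_RESPONSE, n_steps=10_000)
        assert abs(k20 - kref) / kref < 0.10

    def test_decreasing_in_biomass(self, optics):
        lc = LightConfig(I0=92.0, L=0.025)
        k = [depth_averaged_response(X, optics, lc, GROWTH_RESPONSE) for X in (0.5, 1.0, 1.8)]
        assert k[0] > k[1] > k[2]

    def test_bounded_by_peak_response(self, optics):
        lc = LightConfig(I0=914.0, L=0.2, n_surfaces=2)
        k_star = photoresponse(optimal_intensity(GROWTH_RESPONSE), GROWTH_RESPONSE)
        for X in (0.0, 0.5, 3.0, 12.0):
            kbar = depth_averaged_response(X, optics, lc, GROWTH_RESPONSE)
            assert 0.0 <= kbar <= k_star

    def test_two_sided_at_least_one_sided(self, optics):
        for X in (0.1, 1.0, 5.0):
            one = depth_averaged_response(
                X, optics, LightConfig(I0=457.0, L=0.1, n_surfaces=1), GROWTH_RESPONSE
            )
            two = depth_averaged_response(
                X, optics, LightConfig(I0=457.0, L=0.1, n_surfaces=2), GROWTH_RESPONSE
            )
            assert two >= one

    def test_substitution_quadrature_oracle(self, optics):
        # For one-sided light, (1/L) * int k(I(z)) dz equals, by the
        # substitution u = I0*exp(-a z),
        # (1/(a L)) * int_{I(L)}^{I0} du / (u + ks + u^2/ki).
        X, I0, L = 3.0, 457.0, 0.05
        p = GROWTH_RESPONSE
        a = attenuation_coefficient(X, optics)
        lc = LightConfig(I0=I0, L=L)
        I_L = I0 * np.exp(-a * L)
        exact, _ = quad(lambda u: 1.0 / (u + p.ks + u**2 / p.ki), I_L, I0)
        exact /= a * L
        trap = depth_averaged_response(X, optics, lc, p, n_steps=4000)
        assert trap == pytest.approx(exact, rel=1e-5)
        # and the composite trapezoid converges toward the exact value
        coarse = depth_averaged_response(X, optics, lc, p, n_steps=20)
        assert abs(trap - exact) < abs(coarse - exact)

    @given(
        X=st.floats(0.01, 15.0),
        I0=st.floats(10.0, 274.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_more_biomass_never_brightens_one_sided(self, optics, X, I0):
        # Strict monotone decrease in X holds for sub-inhibitory incident
        # light (I0 below the Aiba optimum sqrt(ks*ki) ~ 275): every layer
        # then sits on the rising branch of k(I), so dimming can only
        # lower the average.  Above the optimum, self-shading can relieve
        # photoinhibition near the surface and the average may rise.
        lc = LightConfig(I0=I0, L=0.025)
        p = PhotoResponseParams(ks=165.0, ki=457.0)
        k1 = depth_averaged_response(X, optics, lc, p)
        k2 = depth_averaged_response(X * 1.5, optics, lc, p)
        assert k2 < k1
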