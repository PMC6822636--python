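"""Closed-form stress/pressure model: frozen oracle values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssn_poro import (
    BoundaryStress,
    GrowthStressParams,
    PressureProfileParams,
    RadialProfile,
    TransportProperties,
    alpha_from_transport,
    compression_stress_profiles,
    fluid_pressure_profile,
    growth_stress_profiles,
    normalize_growth_profile,
    peak_ssn,
    ssn_profile,
)
from ssn_poro.model_core import sinh_ratio


def naive_ssn(alpha, r):
    """Direct-formula oracle, valid for moderate alpha where sinh does not overflow."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        out = 1.0 - np.sinh(alpha * r) / (r * math.sinh(alpha))
    out = np.where(r == 0, 1.0 - alpha / math.sinh(alpha), out)
    return out


class TestAlphaFromTransport:
    def test_identity_and_linear_scaling(self):
        tp = TransportProperties(lp=1.0, k=1.0, sv=1.0)  # (Lp/k)*SV = 1 m^-2
        assert alpha_from_transport(1000.0, tp) == pytest.approx(1.0, rel=1e-14)  # a = 1 m
        assert alpha_from_transport(2000.0, tp) == pytest.approx(
            2 * alpha_from_transport(1000.0, tp), rel=1e-14
        )
        assert alpha_from_transport(3000.0, tp) == pytest.approx(3.0, rel=1e-14)

    @pytest.mark.parametrize("bad", [{"lp": -1}, {"k": 0}, {"sv": -0.5}])
    def test_nonpositive_inputs_rejected(self, bad):
        fields = {"lp": 1.0, "k": 1.0, "sv": 1.0}
        fields.update(bad)
        with pytest.raises(ValueError, match=list(bad)[0]):
            TransportProperties(**fields)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="a_mm"):
            alpha_from_transport(0.0, TransportProperties(1.0, 1.0, 1.0))


class TestFluidPressure:
    @pytest.mark.parametrize("alpha", [0.3, 3.0, 33.0])
    def test_zero_at_boundary(self, alpha):
        p = PressureProfileParams(alpha=alpha, psi_kpa=2.5, a_mm=4.0)
        assert fluid_pressure_profile(p, [1.0]).values[0] == pytest.approx(0.0, abs=1e-14 * 2.5)

    def test_center_equals_p0(self):
        p = PressureProfileParams(alpha=3.0, psi_kpa=2.0, a_mm=4.0)
        prof = fluid_pressure_profile(p, [0.0])
        assert prof.values[0] == pytest.approx(2.0 * (1 - 3.0 / math.sinh(3.0)), rel=1e-12)
        assert prof.values[0] == pytest.approx(p.p0_kpa, rel=1e-12)

    def test_frozen_oracle_value(self):
        # 1 - sinh(1.5)/(0.5*sinh(3)) evaluated independently
        p = PressureProfileParams(alpha=3.0, psi_kpa=1.0, a_mm=1.0)
        assert fluid_pressure_profile(p, [0.5]).values[0] == pytest.approx(0.574904, abs=5e-7)

    def test_radii_outside_unit_interval_rejected(self):
        p = PressureProfileParams(alpha=3.0, psi_kpa=1.0, a_mm=1.0)
        with pytest.raises(ValueError, match="radii"):
            fluid_pressure_profile(p, [0.2, 1.5])

    def test_w_consistency_enforced(self):
        PressureProfileParams(alpha=2.0, psi_kpa=0.25, a_mm=1.0, w_kpa=1.0)
        with pytest.raises(ValueError, match="inconsistent"):
            PressureProfileParams(alpha=2.0, psi_kpa=0.3, a_mm=1.0, w_kpa=1.0)


class TestCompressionStress:
    def test_zero_amplitude_gives_constant_profiles(self):
        b = BoundaryStress(s_RR_a=-1.2, s_thth_a=-0.7)
        p = PressureProfileParams(alpha=5.0, psi_kpa=0.0, a_mm=1.0)
        r = np.linspace(0, 1, 11)
        rad, circ = compression_stress_profiles(b, p, r)
        assert np.allclose(rad.values, -1.2) and np.allclose(circ.values, -0.7)

    def test_boundary_values_and_frozen_interior(self):
        b = BoundaryStress(s_RR_a=-1.0, s_thth_a=-0.5)
        p = PressureProfileParams(alpha=3.0, psi_kpa=1.0, a_mm=1.0)
        rad, circ = compression_stress_profiles(b, p, [0.5, 1.0])
        assert rad.values[-1] == pytest.approx(-1.0, abs=1e-14)
        assert circ.values[-1] == pytest.approx(-0.5, abs=1e-14)
        assert rad.values[0] == pytest.approx(-1.574904, abs=5e-7)


class TestGrowthStress:
    STANDARD = dict(omega_bR=0.4, omega_pR=0.2, omega_bT=0.0, omega_pT=0.6)

    def test_boundary_values_printed_set(self):
        g = GrowthStressParams(alpha=33.0, **self.STANDARD)
        rad, circ = growth_stress_profiles(g, [1.0])
        assert rad.values[0] == pytest.approx(-0.4, abs=1e-14)
        assert circ.values[0] == pytest.approx(0.0, abs=1e-14)

    def test_zero_peak_amplitudes_give_constants(self):
        g = GrowthStressParams(omega_bR=0.4, omega_pR=0.0, omega_bT=0.1, omega_pT=0.0, alpha=3.0)
        rad, circ = growth_stress_profiles(g, np.linspace(0, 1, 7))
        assert np.allclose(rad.values, -0.4) and np.allclose(circ.values, -0.1)

    def test_center_value_large_alpha(self):
        # -0.4 - 0.2*(1 - 33*cosech(33)); the cosech term is ~3e-13
        g = GrowthStressParams(alpha=33.0, **self.STANDARD)
        rad, _ = growth_stress_profiles(g, [0.0])
        assert rad.values[0] == pytest.approx(-0.6, abs=1e-10)
        assert rad.values[0] == pytest.approx(g.peak_radial_kpa, rel=1e-14)


class TestSsnProfile:
    @pytest.mark.parametrize("alpha", [0.05, 0.3, 3.0, 33.0, 1e4])
    def test_zero_at_boundary_and_range(self, alpha):
        prof = ssn_profile(alpha, np.linspace(0, 1, 101))
        assert prof.values[-1] == pytest.approx(0.0, abs=1e-14)
        assert np.all(np.isfinite(prof.values))
        assert np.all(prof.values >= 0) and np.all(prof.values <= peak_ssn(alpha) + 1e-14)

    def test_frozen_value(self):
        assert ssn_profile(3.0, [0.5]).values[0] == pytest.approx(0.574904, abs=5e-7)

    def test_small_alpha_parabolic_limit(self):
        alpha = 0.05
        r = np.linspace(0, 1, 201)
        prof = ssn_profile(alpha, r)
        parabola = (alpha**2 / 6.0) * (1 - r**2)
        sup_rel = np.max(np.abs(prof.values - parabola)) / prof.values[0]
        assert sup_rel < 1e-3

    @given(alpha=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_r(self, alpha):
        r = np.linspace(0.01, 1.0, 64)
        vals = ssn_profile(alpha, r).values
        assert np.all(np.diff(vals) <= 0)
        # strict wherever the value is resolvable from the large-alpha plateau at 1
        resolvable = vals[:-1] < 1.0 - 1e-12
        assert np.all(np.diff(vals)[resolvable] < 0)

    def test_matches_naive_formula_at_moderate_alpha(self):
        r = np.linspace(0, 1, 33)
        for alpha in (0.2, 1.0, 7.5, 40.0):
            np.testing.assert_allclose(
                ssn_profile(alpha, r).values, naive_ssn(alpha, r), rtol=1e-12, atol=1e-14
            )


class TestPeakSsn:
    def test_frozen_values(self):
        assert peak_ssn(3.0) == pytest.approx(0.700535, abs=5e-7)
        assert peak_ssn(0.3) == pytest.approx(0.014843, abs=1.5e-6)

    def test_limits_and_monotonicity(self):
        grid = np.logspace(-2, 2, 50)
        vals = np.array([peak_ssn(a) for a in grid])
        assert np.all(np.diff(vals) >= 0)
        # strictly increasing wherever the value is resolvable from the limit 1
        resolvable = vals[1:] < 1.0 - 1e-15
        assert np.all(np.diff(vals)[resolvable] > 0)
        assert peak_ssn(1e-6) < 1e-11
        assert 0 < peak_ssn(1e4) <= 1.0 and np.isfinite(peak_ssn(1e4))

    def test_agrees_with_direct_formula(self):
        for alpha in (0.5, 2.0, 10.0, 50.0):
            assert peak_ssn(alpha) == pytest.approx(1 - alpha / math.sinh(alpha), rel=1e-12)


class TestNormalizationIdentity:
    """Growth- and compression-induced stress share the SSn spatial shape."""

    @given(
        alpha=st.floats(0.05, 80.0),
        omega_b=st.floats(-1.0, 1.0),
        omega_p=st.floats(0.05, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_randomized_growth_normalization(self, alpha, omega_b, omega_p):
        r = np.linspace(0, 1, 17)
        g = GrowthStressParams(
            omega_bR=omega_b, omega_pR=omega_p, omega_bT=-omega_b, omega_pT=2 * omega_p, alpha=alpha
        )
        ssn = ssn_profile(alpha, r).values
        for component in ("radial", "circumferential"):
            norm = normalize_growth_profile(g, r, component=component).values
            np.testing.assert_allclose(norm, ssn, atol=1e-12, rtol=0)

    def test_circumferential_equals_radial_standard_set(self):
        r = np.linspace(0, 1, 41)
        g = GrowthStressParams(alpha=33.0, **TestGrowthStress.STANDARD)
        np.testing.assert_allclose(
            normalize_growth_profile(g, r, "radial").values,
            normalize_growth_profile(g, r, "circumferential").values,
            atol=1e-12,
        )

    def test_zero_peak_amplitude_is_degenerate(self):
        g = GrowthStressParams(omega_bR=0.4, omega_pR=0.0, omega_bT=0.0, omega_pT=0.6, alpha=3.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_growth_profile(g, [0.0, 1.0], "radial")


class TestNumericalStability:
    def test_huge_alpha_interior_plateau(self):
        prof = ssn_profile(1e4, np.linspace(0, 1, 101))
        assert np.all(np.isfinite(prof.values))
        assert prof.values[50] == pytest.approx(1.0, abs=1e-12)

    def test_sinh_ratio_near_zero_radius(self):
        for alpha in (0.5, 5.0, 500.0):
            assert sinh_ratio(alpha, 1e-12) == pytest.approx(
                sinh_ratio(alpha, 0.0), rel=1e-12
            )


class TestRadialProfileValidation:
    def test_rejects_unsorted_and_out_of_range(self):
        with pytest.raises(ValueError, match="ascending"):
            RadialProfile(r=[0.5, 0.2], values=[1.0, 2.0])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            RadialProfile(r=[0.5, 1.2], values=[1.0, 2.0])
        with pytest.raises(ValueError, match="equal length"):
            RadialProfile(r=[0.5], values=[1.0, 2.0])
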