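"""Viscosity shifting, blending, and mixture-property rules."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from strutcast.materials import (
    Blend,
    Material,
    MaterialError,
    RefutasDomainError,
    WLFDomainError,
    _blend_index,
    _index_to_viscosity,
    blend_viscosity,
    density_at_T,
    mixture_contact_angle,
    mixture_density,
    mixture_surface_tension,
    refutas_blend,
    wlf_viscosity,
)


class TestWLF:
    @pytest.mark.parametrize("eta,T", [(2211.35, 120.0), (1.0, 25.0), (5e4, 140.0)])
    def test_identity_at_reference(self, eta, T):
        assert wlf_viscosity(eta, T, T) == eta

    @pytest.mark.parametrize(
        "T,expected",
        [
            # frozen from independent evaluation of eta_ref*exp(-8.86 dT/(101.6+dT))
            (130.0, 999.6964248117431),
            (140.0, 514.9766838886335),
        ],
    )
    def test_shift_from_120C(self, T, expected):
        assert wlf_viscosity(2211.35, 120.0, T) == pytest.approx(expected, rel=1e-9)

    @given(
        eta=st.floats(1e-3, 1e5),
        T_ref=st.floats(80.0, 160.0),
        dT=st.floats(0.1, 40.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing_in_T(self, eta, T_ref, dT):
        assert wlf_viscosity(eta, T_ref, T_ref + dT) < wlf_viscosity(eta, T_ref, T_ref + dT / 2)

    def test_singular_denominator_raises(self):
        with pytest.raises(WLFDomainError):
            wlf_viscosity(1000.0, 150.0, 150.0 - 101.6)


class TestRefutas:
    def test_identity_on_equal_components(self):
        for basis in ("kinematic_cSt", "dynamic_cP"):
            eta = refutas_blend([5.0, 5.0], [0.5, 0.5], [1100.0, 1100.0], basis=basis)
            assert eta == pytest.approx(5.0, rel=1e-9)

    def test_hand_computed_50_50_kinematic(self):
        # 100 cSt and 10 cSt components at rho = 1000 kg/m^3, so the Pa·s
        # inputs are 0.1 and 0.01; frozen blend value from an independent
        # evaluation of the index equations: 26.672406 cSt.
        eta = refutas_blend([0.1, 0.01], [0.5, 0.5], [1000.0, 1000.0], basis="kinematic_cSt")
        assert eta / 1000.0 * 1e6 == pytest.approx(26.672406112, rel=1e-6)

    def test_bounds_between_components(self):
        eta = refutas_blend([2.0, 0.05], [0.6, 0.4], [1200.0, 1400.0])
        assert 0.05 < eta < 2.0

    def test_more_thin_component_lowers_viscosity(self):
        etas = [
            refutas_blend([2.0, 0.05], [1 - x, x], [1200.0, 1400.0])
            for x in (0.1, 0.2, 0.3, 0.4)
        ]
        assert all(a > b for a, b in zip(etas, etas[1:]))

    @given(
        v=st.tuples(st.floats(1.0, 1e6), st.floats(1.0, 1e6), st.floats(1.0, 1e6)),
        x=st.tuples(st.floats(0.05, 1.0), st.floats(0.05, 1.0), st.floats(0.05, 1.0)),
    )
    @settings(max_examples=100, derandomize=True)
    def test_index_blending_is_associative(self, v, x):
        """Blending three components at once equals pairwise index blending."""
        total = sum(x)
        x = tuple(xi / total for xi in x)
        A_direct = sum(xi * _blend_index(vi) for vi, xi in zip(v, x))
        x12 = x[0] + x[1]
        A_pair = x12 * (
            (x[0] / x12) * _blend_index(v[0]) + (x[1] / x12) * _blend_index(v[1])
        ) + x[2] * _blend_index(v[2])
        assert _index_to_viscosity(A_pair) == pytest.approx(
            _index_to_viscosity(A_direct), rel=1e-12
        )

    def test_domain_error_names_component(self):
        with pytest.raises(RefutasDomainError, match="DMSO2"):
            refutas_blend(
                [2.0, 1e-7],
                [0.5, 0.5],
                [1200.0, 1400.0],
                names=["PCL", "DMSO2"],
            )

    def test_floor_rescues_thin_component(self):
        eta = refutas_blend([2.0, 1e-7], [0.5, 0.5], [1200.0, 1400.0], floor=1.0)
        assert 0 < eta < 2.0


class TestDensity:
    def test_reference_identity(self, pcl):
        assert density_at_T(pcl, pcl.T_ref_density) == pcl.density_ref

    def test_pcl_at_120(self, pcl):
        # 1145 / (1 + 3*165e-6*95), frozen from direct evaluation
        assert density_at_T(pcl, 120.0) == pytest.approx(1093.5746519901625, rel=1e-9)

    def test_strictly_decreasing(self, pcl):
        temps = [25.0, 60.0, 100.0, 140.0]
        rhos = [density_at_T(pcl, T) for T in temps]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))

    def test_linear_as_volumetric_mode(self, pcl):
        rho3 = density_at_T(pcl, 120.0, "volumetric_from_linear")
        rho1 = density_at_T(pcl, 120.0, "linear_as_volumetric")
        assert rho1 > rho3  # smaller effective expansion


class TestMixtures:
    def test_specific_volume_mean(self):
        a = Material("A", 1000.0, 25.0, 0.0, 1.0, 120.0, 0.04, 90.0)
        b = Material("B", 1500.0, 25.0, 0.0, 1.0, 120.0, 0.04, 90.0)
        blend = Blend.of((a, 0.5), (b, 0.5))
        assert mixture_density(blend, 25.0) == pytest.approx(1200.0, rel=1e-12)
        assert mixture_density(blend, 25.0, mode="linear") == pytest.approx(1250.0, rel=1e-12)

    def test_pure_blend_matches_component(self, pcl):
        blend = Blend.of((pcl, 1.0))
        assert mixture_density(blend, 133.0) == density_at_T(pcl, 133.0)

    def test_surface_tension_linear(self, pcl, dmso2):
        assert mixture_surface_tension(Blend.of((pcl, 1.0))) == pytest.approx(0.040)
        assert mixture_surface_tension(Blend.of((dmso2, 1.0))) == pytest.approx(0.060)
        b = Blend.of((pcl, 0.9), (dmso2, 0.1))
        assert mixture_surface_tension(b) == pytest.approx(0.042, rel=1e-12)

    def test_contact_angle_linear(self, pcl, dmso2):
        b = Blend.of((pcl, 0.9), (dmso2, 0.1))
        assert mixture_contact_angle(b) == pytest.approx(0.9 * 75 + 0.1 * 40, rel=1e-12)


class TestBlendViscosity:
    def test_pure_pcl_reference(self, pcl):
        assert blend_viscosity(Blend.of((pcl, 1.0)), 120.0) == pytest.approx(2211.35)

    def test_pure_reduces_to_wlf(self, pcl):
        blend = Blend.of((pcl, 1.0))
        for T in (110.0, 125.0, 155.0):
            assert blend_viscosity(blend, T) == wlf_viscosity(pcl.eta_ref, 120.0, T)

    def test_regression_pcl_d10_at_120(self, blend_series):
        """Frozen value from an independent hand evaluation of the WLF +
        Refutas chain on the kinematic basis (floor 1 cSt)."""
        eta = blend_viscosity(blend_series["pcl_d10"], 120.0)
        assert eta == pytest.approx(42.13159241812159, rel=1e-9)

    def test_composite_ordering(self, blend_series):
        """More thin diluent means lower blend viscosity at any temperature."""
        for T in (120.0, 130.0, 140.0):
            etas = [
                blend_viscosity(blend_series[k], T)
                for k in ("pcl", "pcl_d10", "pcl_d20", "pcl_d30")
            ]
            assert all(a > b for a, b in zip(etas, etas[1:]))

    def test_outside_validity_window_raises(self, blend_series):
        with pytest.raises(MaterialError):
            blend_viscosity(blend_series["pcl"], 200.0)

    def test_strict_mode_propagates_domain_error(self, blend_series):
        with pytest.raises(RefutasDomainError):
            blend_viscosity(blend_series["pcl_d10"], 140.0, floor=None)


class TestValidation:
    def test_blend_fractions_must_sum_to_one(self, pcl, dmso2):
        with pytest.raises(MaterialError):
            Blend.of((pcl, 0.6), (dmso2, 0.6))

    def test_material_invariants(self):
        with pytest.raises(MaterialError):
            Material("bad", -1.0, 25.0, 0.0, 1.0, 120.0, 0.04, 90.0)
        with pytest.raises(MaterialError):
            Material("bad", 1000.0, 25.0, 0.0, 1.0, 120.0, 0.04, 190.0)
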