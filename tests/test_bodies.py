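"""Geometry, mixture densities and piecewise density fields."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelletsink.bodies import (
    AdmixtureSpec,
    DomainSpec,
    FluidMedium,
    PelletBody,
    PelletGeometry,
    cap_area_fraction,
    center_of_mass,
    chord_for_area_fraction,
    nonuniform_density_field,
    uniform_mixture_density,
)


class TestUniformMixture:
    @pytest.mark.parametrize(
        "base,ps,f,expected",
        [(1140, 1050, 0.0, 1140.0), (1140, 1050, 1.0, 1050.0),
         (1140, 1050, 0.5, 1095.0), (1140, 1050, 0.0625, 1134.375)],
    )
    def test_examples(self, base, ps, f, expected):
        assert uniform_mixture_density(base, ps, f) == pytest.approx(expected)

    @given(f=st.floats(0, 1), g=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, f, g):
        lo, hi = sorted((f, g))
        a = uniform_mixture_density(1140, 1050, lo)
        b = uniform_mixture_density(1140, 1050, hi)
        assert b <= a  # PS is lighter, more PS -> lighter pellet
        assert 1050.0 <= b <= 1140.0

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            uniform_mixture_density(1140, 1050, 1.2)


class TestBandGeometry:
    def test_literal_quarter_cap_area(self):
        # cap beyond half the semi-axis covers ~19.6% of the ellipse
        assert cap_area_fraction(0.5) == pytest.approx(0.196, abs=5e-4)

    def test_whole_pellet_limit(self):
        field, frac = nonuniform_density_field(
            PelletGeometry(100, 20), 1140, 950, band_axis_fraction=0.999999
        )
        assert frac == pytest.approx(1.0, abs=1e-4)
        assert field(np.array([-4.9e-5]), np.array([0.0]))[0] == 950

    def test_default_band_area_tuned(self):
        body = PelletBody(
            PelletGeometry(100, 20),
            admixture=AdmixtureSpec(mode="nonuniform", nmp_density=950),
        )
        assert body.band_area_fraction == pytest.approx(0.276, abs=1e-3)

    def test_quarter_axis_band(self):
        field, frac = nonuniform_density_field(
            PelletGeometry(100, 20), 1140, 950, band_axis_fraction=0.25
        )
        assert frac == pytest.approx(cap_area_fraction(0.5))
        # band occupies x >= b/2
        assert field(np.array([3e-5]), np.array([0.0]))[0] == 950
        assert field(np.array([0.0]), np.array([0.0]))[0] == 1140

    def test_monte_carlo_area_agreement(self):
        """Band area fraction vs rejection sampling at 1e6 points."""
        rng = np.random.default_rng(42)
        a, b = 10e-6, 50e-6
        n = 10**6
        x = rng.uniform(-b, b, n)
        y = rng.uniform(-a, a, n)
        inside = (x / b) ** 2 + (y / a) ** 2 < 1.0
        t = chord_for_area_fraction(0.276)
        in_band = inside & (x >= t * b)
        frac = in_band.sum() / inside.sum()
        se = np.sqrt(0.276 * 0.724 / inside.sum())
        assert abs(frac - 0.276) < 3 * se


class TestCenterOfMass:
    def test_uniform_body_symmetric(self):
        assert center_of_mass(PelletBody(PelletGeometry(100, 20))) == 0.0

    def test_band_with_equal_density(self):
        body = PelletBody(
            PelletGeometry(100, 20),
            admixture=AdmixtureSpec(mode="nonuniform", nmp_density=1140.0),
        )
        assert center_of_mass(body) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("rho,sign", [(1200.0, +1), (950.0, -1)])
    def test_offset_sign_toward_heavier_material(self, rho, sign):
        body = PelletBody(
            PelletGeometry(100, 20),
            admixture=AdmixtureSpec(mode="nonuniform", nmp_density=rho),
        )
        assert np.sign(center_of_mass(body)) == sign

    def test_against_monte_carlo_centroid(self):
        """2D density-weighted centroid vs area-sampling oracle, <0.5%."""
        body = PelletBody(
            PelletGeometry(100, 20),
            admixture=AdmixtureSpec(mode="nonuniform", nmp_density=1200.0),
        )
        rng = np.random.default_rng(7)
        a, b = body.geometry.a, body.geometry.b
        n = 2 * 10**6
        x = rng.uniform(-b, b, n)
        y = rng.uniform(-a, a, n)
        keep = (x / b) ** 2 + (y / a) ** 2 < 1.0
        x = x[keep]
        rho = body.density_field()(x, np.zeros_like(x))
        mc = (rho * x).sum() / rho.sum()
        se = np.sqrt(np.var(rho * (x - mc)) / len(x)) / rho.mean()
        assert abs(body.com_offset - mc) < 3 * se
        assert abs(body.com_offset - mc) < 0.005 * b


class TestMassAndInertia:
    def test_uniform_mass_is_density_times_ellipse_area(self):
        body = PelletBody(PelletGeometry(100, 20))
        assert body.mass == pytest.approx(
            1140.0 * np.pi * 10e-6 * 50e-6, rel=1e-12
        )

    def test_banded_mass_matches_area_weighted_density(self):
        body = PelletBody(
            PelletGeometry(100, 20),
            admixture=AdmixtureSpec(mode="nonuniform", nmp_density=950.0),
        )
        f = body.band_area_fraction
        expect = ((1 - f) * 1140 + f * 950) * body.area
        assert body.mass == pytest.approx(expect, rel=1e-12)

    def test_uniform_inertia_closed_form(self):
        body = PelletBody(PelletGeometry(100, 20))
        a, b = 10e-6, 50e-6
        assert body.moment_of_inertia == pytest.approx(
            body.mass * (a * a + b * b) / 4.0, rel=1e-9
        )


class TestValidation:
    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            PelletGeometry(20, 100)  # width > length
        with pytest.raises(ValueError):
            PelletGeometry(100, 0)

    def test_medium_invariants(self):
        with pytest.raises(ValueError):
            FluidMedium(density=-1)
        with pytest.raises(ValueError):
            FluidMedium(dynamic_viscosity=0)

    def test_release_depth_inside_column(self):
        with pytest.raises(ValueError):
            DomainSpec(release_depth_um=7000)
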