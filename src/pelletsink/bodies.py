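"""Pellet geometry, density fields and the surrounding fluid medium.

A copepod fecal pellet is idealised as a rigid 2D ellipse with short
semi-axis ``A`` (half the measured width) and long semi-axis ``B`` (half
the measured length).  Nano/microplastic (NMP) admixture is encoded either
as a uniform change of the bulk density (homogeneous incorporation of
polystyrene) or as a piecewise-constant density band occupying one end of
the long axis (nonuniform incorporation).

All public constructors accept micrometres, the unit the measurements are
reported in; everything derived (mass, centroid, inertia) is SI, per unit
depth of the 2D model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate, optimize

UM = 1e-6  # micrometre in metres

#: typical bulk density of copepod fecal pellets, kg/m^3
PELLET_DENSITY = 1140.0
#: polystyrene density, kg/m^3
PS_DENSITY = 1050.0
#: seawater density, kg/m^3
SEAWATER_DENSITY = 1030.0
#: dynamic viscosity of seawater at 20 degC, 31 psu, Pa s
SEAWATER_VISCOSITY = 1.05e-3


@dataclass(frozen=True)
class FluidMedium:
    """Properties of the water column. Gravity acts along -y."""

    density: float = SEAWATER_DENSITY
    dynamic_viscosity: float = SEAWATER_VISCOSITY
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("fluid density must be positive")
        if self.dynamic_viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.gravity < 0:
            raise ValueError("gravity must be non-negative")


@dataclass(frozen=True)
class PelletGeometry:
    """Full axes of the elliptical pellet, in micrometres."""

    length_um: float
    width_um: float

    def __post_init__(self) -> None:
        if not (self.length_um >= self.width_um > 0):
            raise ValueError(
                f"need length >= width > 0, got length={self.length_um}, "
                f"width={self.width_um}"
            )

    @property
    def a(self) -> float:
        """Short semi-axis in metres."""
        return 0.5 * self.width_um * UM

    @property
    def b(self) -> float:
        """Long semi-axis in metres."""
        return 0.5 * self.length_um * UM

    @property
    def area(self) -> float:
        """Cross-section area pi*A*B in m^2 (per unit depth)."""
        return np.pi * self.a * self.b


@dataclass(frozen=True)
class DomainSpec:
    """Rectangular water-column domain, micrometres."""

    width_um: float = 2000.0
    height_um: float = 6000.0
    release_depth_um: float = 500.0

    def __post_init__(self) -> None:
        if self.release_depth_um >= self.height_um:
            raise ValueError("release depth must be smaller than column height")

    @property
    def width(self) -> float:
        return self.width_um * UM

    @property
    def height(self) -> float:
        return self.height_um * UM

    def release_point(self) -> tuple[float, float]:
        """Centre of the pellet at release: mid-width, release depth below top."""
        return 0.5 * self.width, self.height - self.release_depth_um * UM


AdmixtureMode = Literal["none", "uniform", "nonuniform"]


@dataclass(frozen=True)
class AdmixtureSpec:
    """How plastic is incorporated into the pellet.

    mode="uniform": a fraction ``ps_fraction`` of the pellet area is
    polystyrene, lowering the bulk density through the area-weighted mean.

    mode="nonuniform": a band at the +x end of the long axis, bounded by a
    chord perpendicular to that axis, has density ``nmp_density``.  The band
    is specified either by ``band_axis_fraction`` (fraction of the full
    length it occupies) or, by default, by ``band_area_fraction`` (fraction
    of the ellipse area it covers; 0.276 by default).
    """

    mode: AdmixtureMode = "none"
    ps_fraction: float = 0.0
    ps_density: float = PS_DENSITY
    nmp_density: float = PS_DENSITY
    band_axis_fraction: float | None = None
    band_area_fraction: float | None = 0.276

    def __post_init__(self) -> None:
        if self.mode not in ("none", "uniform", "nonuniform"):
            raise ValueError(f"unknown admixture mode {self.mode!r}")
        if not 0.0 <= self.ps_fraction <= 1.0:
            raise ValueError("ps_fraction must lie in [0, 1]")
        if self.band_axis_fraction is not None and not (
            0.0 < self.band_axis_fraction < 1.0
        ):
            raise ValueError("band_axis_fraction must lie in (0, 1)")


def uniform_mixture_density(
    base_density: float, ps_density: float, ps_fraction: float
) -> float:
    """Bulk density of a pellet with homogeneously incorporated polystyrene.

    Area-fraction-weighted arithmetic mean:
    ``(1 - f) * rho_base + f * rho_PS``.
    """
    if not 0.0 <= ps_fraction <= 1.0:
        raise ValueError(f"ps_fraction must lie in [0, 1], got {ps_fraction}")
    if base_density <= 0 or ps_density <= 0:
        raise ValueError("densities must be positive")
    return (1.0 - ps_fraction) * base_density + ps_fraction * ps_density


# ---------------------------------------------------------------------------
# Exact end-cap integrals on the ellipse x^2/b^2 + y^2/a^2 = 1.
# The cap is {x >= c}; t = c/b in [-1, 1].

def cap_area_fraction(t: float) -> float:
    """Fraction of ellipse area in the cap beyond the chord at x = t*b."""
    t = float(np.clip(t, -1.0, 1.0))
    return (np.arccos(t) - t * np.sqrt(1.0 - t * t)) / np.pi


def chord_for_area_fraction(area_fraction: float) -> float:
    """Chord position t = c/b whose end-cap covers the given area fraction."""
    if not 0.0 < area_fraction < 1.0:
        raise ValueError("area fraction must lie in (0, 1)")
    return optimize.brentq(
        lambda t: cap_area_fraction(t) - area_fraction, -1.0, 1.0, xtol=1e-14
    )


def _cap_first_moment(a: float, b: float, t: float) -> float:
    """Integral of x over the cap x >= t*b (m^3 per unit depth)."""
    return (2.0 * a * b * b / 3.0) * (1.0 - t * t) ** 1.5


def _cap_second_moment(a: float, b: float, t: float) -> float:
    """Integral of (x^2 + y^2) over the cap x >= t*b."""

    def integrand(x: float) -> float:
        half_h = (a / b) * np.sqrt(max(b * b - x * x, 0.0))
        # strip of half-height half_h at position x
        return 2.0 * half_h * x * x + (2.0 / 3.0) * half_h**3

    val, _ = integrate.quad(integrand, t * b, b, limit=200)
    return val


@dataclass(frozen=True)
class PelletBody:
    """A rigid elliptical pellet with a (piecewise-constant) density field.

    In the body frame the long axis is x; the NMP band, if any, sits at the
    +x end.  ``com_offset`` is the signed distance (m) of the centre of mass
    from the geometric centre along the long axis.
    """

    geometry: PelletGeometry
    base_density: float = PELLET_DENSITY
    admixture: AdmixtureSpec = field(default_factory=AdmixtureSpec)

    def __post_init__(self) -> None:
        if self.base_density <= 0:
            raise ValueError("base density must be positive")

    # --- band geometry -----------------------------------------------------
    @property
    def band_chord(self) -> float | None:
        """Chord position t = c/b of the band boundary, or None."""
        if self.admixture.mode != "nonuniform":
            return None
        adm = self.admixture
        if adm.band_axis_fraction is not None:
            # band occupies a fraction lam of the full length 2b at the +x end
            return 1.0 - 2.0 * adm.band_axis_fraction
        if adm.band_area_fraction is None:
            raise ValueError("nonuniform admixture needs an axis or area fraction")
        return chord_for_area_fraction(adm.band_area_fraction)

    @property
    def band_area_fraction(self) -> float:
        """Exact ellipse-area fraction covered by the band (0 if no band)."""
        t = self.band_chord
        return 0.0 if t is None else cap_area_fraction(t)

    # --- densities ---------------------------------------------------------
    @property
    def bulk_density(self) -> float:
        """Area-averaged density, kg/m^3."""
        adm = self.admixture
        if adm.mode == "none":
            return self.base_density
        if adm.mode == "uniform":
            return uniform_mixture_density(
                self.base_density, adm.ps_density, adm.ps_fraction
            )
        f = self.band_area_fraction
        return (1.0 - f) * self.base_density + f * adm.nmp_density

    def density_field(self) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        """Density as a function of body-frame coordinates (metres)."""
        adm = self.admixture
        if adm.mode == "nonuniform":
            c = self.band_chord * self.geometry.b
            base, band = self.base_density, adm.nmp_density

            def rho(x: np.ndarray, y: np.ndarray) -> np.ndarray:
                return np.where(np.asarray(x) >= c, band, base)

            return rho
        value = self.bulk_density

        def rho_const(x: np.ndarray, y: np.ndarray) -> np.ndarray:
            return np.full_like(np.asarray(x, dtype=float), value)

        return rho_const

    # --- integral properties (per unit depth) ------------------------------
    @property
    def area(self) -> float:
        return self.geometry.area

    @property
    def mass(self) -> float:
        """Mass per unit depth, kg/m."""
        return self.bulk_density * self.area

    @property
    def com_offset(self) -> float:
        """Centre-of-mass offset from geometric centre along +x, metres."""
        t = self.band_chord
        if t is None:
            return 0.0
        a, b = self.geometry.a, self.geometry.b
        excess = self.admixture.nmp_density - self.base_density
        return excess * _cap_first_moment(a, b, t) / self.mass

    @property
    def moment_of_inertia(self) -> float:
        """Rotational inertia per unit depth about the centre of mass, kg m."""
        a, b = self.geometry.a, self.geometry.b
        # uniform ellipse about its centre
        i_centre = self.base_density * self.area * (a * a + b * b) / 4.0
        t = self.band_chord
        if t is not None:
            excess = self.admixture.nmp_density - self.base_density
            i_centre += excess * _cap_second_moment(a, b, t)
        return i_centre - self.mass * self.com_offset**2


def nonuniform_density_field(
    geometry: PelletGeometry,
    base_density: float,
    nmp_density: float,
    band_axis_fraction: float,
):
    """Density field for a band covering ``band_axis_fraction`` of the long axis.

    Returns ``(field, area_fraction)`` where ``field(x, y)`` maps body-frame
    metres to kg/m^3 and ``area_fraction`` is the exact ellipse-area fraction
    of the band.
    """
    if geometry.a <= 0 or geometry.b <= 0:
        raise ValueError("degenerate geometry")
    body = PelletBody(
        geometry,
        base_density,
        AdmixtureSpec(
            mode="nonuniform",
            nmp_density=nmp_density,
            band_axis_fraction=band_axis_fraction,
            band_area_fraction=None,
        ),
    )
    return body.density_field(), body.band_area_fraction


def center_of_mass(body: PelletBody) -> float:
    """Density-weighted centroid minus geometric centre, metres along +x."""
    return body.com_offset
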