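"""Scenario families for the settling simulations.

Three families are studied:

* ``size_sweep`` — 9 pellets, lengths {50, 100, 200} x widths {10, 20, 30}
  micrometres, all at the typical pellet density 1140 kg/m^3;
* ``uniform_admixture`` — the 20 x 100 um pellet with polystyrene
  homogeneously incorporated at 6.25 / 12.5 / 25 / 50 %;
* ``nonuniform_admixture`` — the 20 x 100 um pellet with an NMP band
  (~27.6 % of the area at one end of the long axis) of density
  950 / 1050 / 1200 kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .bodies import (
    PELLET_DENSITY,
    AdmixtureSpec,
    DomainSpec,
    FluidMedium,
    PelletBody,
    PelletGeometry,
)

SIZE_SWEEP_LENGTHS_UM = (50.0, 100.0, 200.0)
SIZE_SWEEP_WIDTHS_UM = (10.0, 20.0, 30.0)
UNIFORM_PS_FRACTIONS = (0.0625, 0.125, 0.25, 0.50)
NONUNIFORM_NMP_DENSITIES = (950.0, 1050.0, 1200.0)
BASE_LENGTH_UM = 100.0
BASE_WIDTH_UM = 20.0


@dataclass(frozen=True)
class Scenario:
    """One solver-ready configuration."""

    name: str
    body: PelletBody
    domain: DomainSpec = field(default_factory=DomainSpec)
    medium: FluidMedium = field(default_factory=FluidMedium)

    def to_dict(self) -> dict:
        adm = self.body.admixture
        return {
            "name": self.name,
            "pellet": {
                "length_um": self.body.geometry.length_um,
                "width_um": self.body.geometry.width_um,
                "base_density": self.body.base_density,
            },
            "admixture": {
                "mode": adm.mode,
                "ps_fraction": adm.ps_fraction,
                "ps_density": adm.ps_density,
                "nmp_density": adm.nmp_density,
                "band_axis_fraction": adm.band_axis_fraction,
                "band_area_fraction": adm.band_area_fraction,
            },
            "fluid": {
                "density": self.medium.density,
                "viscosity": self.medium.dynamic_viscosity,
                "gravity": self.medium.gravity,
            },
            "domain": {
                "width_um": self.domain.width_um,
                "height_um": self.domain.height_um,
                "release_depth_um": self.domain.release_depth_um,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        p = d["pellet"]
        adm = d.get("admixture", {})
        fl = d.get("fluid", {})
        dom = d.get("domain", {})
        body = PelletBody(
            PelletGeometry(p["length_um"], p["width_um"]),
            p.get("base_density", PELLET_DENSITY),
            AdmixtureSpec(
                mode=adm.get("mode", "none"),
                ps_fraction=adm.get("ps_fraction", 0.0),
                ps_density=adm.get("ps_density", 1050.0),
                nmp_density=adm.get("nmp_density", 1050.0),
                band_axis_fraction=adm.get("band_axis_fraction"),
                band_area_fraction=adm.get("band_area_fraction", 0.276),
            ),
        )
        return cls(
            name=d.get("name", "scenario"),
            body=body,
            domain=DomainSpec(
                dom.get("width_um", 2000.0),
                dom.get("height_um", 6000.0),
                dom.get("release_depth_um", 500.0),
            ),
            medium=FluidMedium(
                fl.get("density", 1030.0),
                fl.get("viscosity", 1.05e-3),
                fl.get("gravity", 9.81),
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def base_scenario(name: str = "base") -> Scenario:
    """The 20 x 100 um, 1140 kg/m^3 pellet with no admixture."""
    return Scenario(
        name=name,
        body=PelletBody(PelletGeometry(BASE_LENGTH_UM, BASE_WIDTH_UM)),
    )


def build_scenarios(family: str) -> list[Scenario]:
    """Construct the solver configurations of one scenario family."""
    if family == "size_sweep":
        return [
            Scenario(
                name=f"size_L{length:g}_W{width:g}",
                body=PelletBody(PelletGeometry(length, width)),
            )
            for length in SIZE_SWEEP_LENGTHS_UM
            for width in SIZE_SWEEP_WIDTHS_UM
        ]
    if family == "uniform_admixture":
        return [
            Scenario(
                name=f"unif_f{f:g}",
                body=PelletBody(
                    PelletGeometry(BASE_LENGTH_UM, BASE_WIDTH_UM),
                    admixture=AdmixtureSpec(mode="uniform", ps_fraction=f),
                ),
            )
            for f in UNIFORM_PS_FRACTIONS
        ]
    if family == "nonuniform_admixture":
        return [
            Scenario(
                name=f"nonunif_rho{rho:g}",
                body=PelletBody(
                    PelletGeometry(BASE_LENGTH_UM, BASE_WIDTH_UM),
                    admixture=AdmixtureSpec(mode="nonuniform", nmp_density=rho),
                ),
            )
            for rho in NONUNIFORM_NMP_DENSITIES
        ]
    raise ValueError(f"unknown scenario family {family!r}")


def write_scenario_list(scenarios: Iterable[Scenario], out_dir: str | Path) -> list[Path]:
    """Emit one YAML config per sweep member with a stable naming scheme."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sc in scenarios:
        path = out / f"{sc.name}.yaml"
        sc.save(path)
        paths.append(path)
    return paths
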