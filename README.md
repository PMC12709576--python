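# pelletsink

Copepod fecal pellets are a major vehicle of the ocean's biological carbon
pump: they package surface carbon into dense, fast-sinking particles.
Ingested nano- and microplastics (NMPs) end up inside these pellets and
change their size, density and density *distribution* — and therefore how
fast they sink. `pelletsink` is a Python package for quantifying that
effect. It provides:

* a **2D coupled fluid–rigid-body settling model**: a rigid elliptical
  pellet (short semi-axis *A*, long semi-axis *B*) sediments in a
  2000 × 6000 μm water column governed by the incompressible laminar
  Navier–Stokes equations, with no-slip side walls, open top/bottom
  boundaries under hydrostatic compensation, and full no-slip coupling on
  the moving interface. The traction
  `f = n·{−pI + μ(∇u + ∇uᵀ) − (2/3)μ(∇·u)I}` integrated over the
  interface drives the pellet's three rigid degrees of freedom via
  `F = f − ρ_solid V_solid g` (per unit depth), including rotation of
  pellets whose centre of mass is offset by a plastic-rich density band;
* an independent **steady Stokes oracle** that computes terminal
  velocities from the drag balance `k(θ)·v = Δρ·πAB·g` in seconds, used
  to cross-check the transient solver;
* the **measurement-side pipeline** of a 27-treatment NMP × diatom
  exposure design: equivalent-ellipsoid volumes
  `V = (4/3)π(L/2)(W/2)²`, production rates, relative fluorescence,
  size-frequency distributions, and normality-gated rank tests;
* a calibrated **synthetic-data generator** for that design, so the whole
  morphometry pipeline is testable without any raw data.

Scenario families built in: a 3 × 3 pellet size sweep (lengths
50/100/200 μm × widths 10/20/30 μm at 1140 kg/m³), homogeneous
polystyrene admixture (6.25–50 %, mixture density
`(1−f)·1140 + f·1050` kg/m³), and a nonuniform NMP band covering 27.6 %
of the pellet area at densities 950/1050/1200 kg/m³.

## Worked example

```python
from pelletsink import (PelletBody, PelletGeometry, AdmixtureSpec,
                        run_settling_simulation, terminal_statistics,
                        terminal_velocity, percent_change)
from pelletsink.protocol import desk_config

base = PelletBody(PelletGeometry(100, 20))          # 20 x 100 um, 1140 kg/m3
traj = run_settling_simulation(base, config=desk_config(seed=1))
stats = terminal_statistics(traj, "base", base)
print(f"transient terminal speed: {stats.mean_speed:.1f} m/day")
print(f"steady-state oracle:      {terminal_velocity(base, mesh_scale=0.8):.1f} m/day")

banded = PelletBody(PelletGeometry(100, 20),
                    admixture=AdmixtureSpec(mode="nonuniform",
                                            nmp_density=950.0))
traj_b = run_settling_simulation(banded, config=desk_config(seed=1, t_end=6.0))
stats_b = terminal_statistics(traj_b, "band950", banded)
print(f"950 kg/m3 band: {stats_b.mean_speed:.1f} m/day "
      f"({percent_change(stats, stats_b):+.1f} %)")
```

prints

```
transient terminal speed: 33.9 m/day
steady-state oracle:      34.0 m/day
950 kg/m3 band: 21.6 m/day (-36.1 %)
```

The base pellet sinks at ~34 m/day, and the transient solver agrees with
the independent steady oracle to under 1 %. The pellet carrying a light
(950 kg/m³) plastic band at one end does two things at once: its bulk
density falls (1087.6 kg/m³), and the centre-of-mass offset rotates it
heavy-end-down until the long axis is vertical — the drag anisotropy of
the vertical attitude partly offsetting the lost density contrast. The
net effect is a ~36 % slower descent; at 4000 m seabed depth that is the
difference between a ~118-day and a ~185-day journey
(`time_to_depth(33.9, 4000)` vs `time_to_depth(21.6, 4000)`).

A command-line interface mirrors the library:

```
pelletsink scenarios --family size_sweep --out configs/
pelletsink simulate --config configs/size_L100_W20.yaml --out runs/ --seed 1
pelletsink oracle --config configs/size_L100_W20.yaml
pelletsink sensitivity --config configs/size_L100_W20.yaml --mode oracle
pelletsink synth --seed 0 --out measurements.tsv
pelletsink morph --measurements measurements.tsv --out tables/
```

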