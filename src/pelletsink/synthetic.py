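"""Synthetic measurement tables emulating the 27-treatment exposure design.

The design crosses two plastic bead classes (NP, 200 nm; MP, 5 um) at four
concentrations (40/200/1000/5000 ug/L) plus a no-plastic control, with
three diatom food levels (0, 1e4, 1e5 cells/mL), six replicate vials of
three copepods each, over 24 h.

Pellet dimensions are drawn from truncated-normal distributions whose
parameters are solved so the *truncated* mean and sd equal the configured
targets exactly.  Diatom level sets the base size; plastic exposure scales
pellet volume through a per-(class, concentration) multiplier table and a
debris sub-population of short fragments that also produces the negative
skew of the volume distribution.  Pellet counts follow Poisson production
rates calibrated to the printed control and high-food rates, so production
per individual per day matches in expectation.

Calibration note: the six pooled volume-reduction targets (two class
marginals and four concentration marginals against a shared control) are
mutually inconsistent under a balanced design — their equal-weight means
differ by 5.65 multiplier points.  The multiplier table therefore uses the
max-norm-optimal even-split allocation: each pooled marginal reduction
lands exactly 2.825 points from its target, the closest any single table
can come to all six at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DIATOM_LEVELS = ("0", "1e4", "1e5")
NMP_CLASSES = ("NP", "MP")
CONCENTRATIONS = (40, 200, 1000, 5000)


def treatment_id(nmp_class: str, concentration: int, diatom: str) -> str:
    """Stable treatment identifier, e.g. 'ctrl-0-1e4' or 'MP-5000-0'."""
    return f"{nmp_class}-{concentration}-{diatom}"


def all_treatments() -> list[tuple[str, int, str]]:
    """The 27 cells: (class, concentration, diatom)."""
    cells: list[tuple[str, int, str]] = []
    for d in DIATOM_LEVELS:
        cells.append(("ctrl", 0, d))
        for k in NMP_CLASSES:
            for c in CONCENTRATIONS:
                cells.append((k, c, d))
    return cells


def parse_treatment(tid: str) -> tuple[str, int, str]:
    k, c, d = tid.split("-")
    return k, int(c), d


def _default_production() -> dict:
    """Per-treatment production rates, 10^6 um^3 / individual / day.

    Anchored to the printed control rates (0.13 no-food, 4.58 high-food)
    and the printed no-food 5000 ug/L rates (0.11 NP, 1.00 MP); the other
    cells are smooth interpolations (marked as such: the full per-cell
    table is not printed in the main text).
    """
    base = {"0": 0.13, "1e4": 1.50, "1e5": 4.58}
    q_np = {40: 0.96, 200: 0.93, 1000: 0.89, 5000: 0.846}   # 0.13*0.846=0.11
    q_mp = {40: 1.30, 200: 1.90, 1000: 3.50, 5000: 7.692}   # 0.13*7.692=1.00
    rates = {}
    for k, c, d in all_treatments():
        if k == "ctrl":
            rates[treatment_id(k, c, d)] = base[d]
        elif k == "NP":
            rates[treatment_id(k, c, d)] = base[d] * q_np[c]
        else:
            rates[treatment_id(k, c, d)] = base[d] * q_mp[c]
    return rates


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic measurement generator."""

    # base pellet size by diatom level (um); truncated-normal targets
    length_mean: dict = field(
        default_factory=lambda: {"0": 45.6, "1e4": 100.6, "1e5": 142.5}
    )
    length_sd: dict = field(
        default_factory=lambda: {"0": 23.6, "1e4": 34.2, "1e5": 34.4}
    )
    # width follows length proportionally (ratio and cv from the control
    # marginals 20.1/124.2 and 4.6/20.1); per-cell widths are interpolated
    width_ratio: float = 0.1618
    width_cv: float = 0.2288
    # pooled volume-reduction targets
    class_reduction: dict = field(
        default_factory=lambda: {"NP": 0.236, "MP": 0.65}
    )
    conc_reduction: dict = field(
        default_factory=lambda: {40: 0.27, 200: 0.358, 1000: 0.423, 5000: 0.495}
    )
    # fragment sub-population under plastic exposure (negative volume skew)
    debris_fraction: float = 0.10
    debris_length_factor: float = 0.3
    # production model
    production_rate: dict = field(default_factory=_default_production)
    replicates: int = 6
    individuals: int = 3
    duration_days: float = 1.0
    # fluorescence semi-quantification model (arbitrary units)
    fluor_amplitude: float = 100.0
    fluor_noise_sd: float = 5.0
    fluor_conc_exponent: float = 0.5
    fluor_diatom_attenuation: dict = field(
        default_factory=lambda: {"0": 1.0, "1e4": 0.6, "1e5": 0.36}
    )
    seed: int = 0

    # ------------------------------------------------------------------
    def volume_multipliers(self) -> dict:
        """Per-(class, concentration) total volume multipliers.

        Even-split allocation: class targets M_k = 1 - class_reduction and
        concentration targets mu_c = 1 - conc_reduction are shifted toward
        each other by half their mean discrepancy, then combined additively
        so both (adjusted) marginal sets hold exactly under equal weights.
        """
        M = {k: 1.0 - self.class_reduction[k] for k in NMP_CLASSES}
        mu = {c: 1.0 - self.conc_reduction[c] for c in CONCENTRATIONS}
        m_cls = float(np.mean(list(M.values())))
        m_con = float(np.mean(list(mu.values())))
        shift = 0.5 * (m_con - m_cls)
        grand = m_cls + shift
        table = {}
        for k in NMP_CLASSES:
            for c in CONCENTRATIONS:
                val = (M[k] + shift) + (mu[c] - shift) - grand
                if not 0.0 < val <= 1.0:
                    raise ValueError(
                        f"impossible calibration: multiplier {val:.3f} for ({k}, {c})"
                    )
                table[(k, c)] = val
        return table

    def calibrated_marginal_reductions(self) -> dict:
        """Pooled reductions the balanced design actually encodes.

        Keys 'class:NP', 'class:MP', 'conc:40', ...; each differs from its
        printed target by the even-split residual (+-2.825 points).
        """
        table = self.volume_multipliers()
        out = {}
        for k in NMP_CLASSES:
            out[f"class:{k}"] = 1.0 - float(
                np.mean([table[(k, c)] for c in CONCENTRATIONS])
            )
        for c in CONCENTRATIONS:
            out[f"conc:{c}"] = 1.0 - float(
                np.mean([table[(k, c)] for k in NMP_CLASSES])
            )
        return out

    # ------------------------------------------------------------------
    def dimension_params(self, nmp_class: str, concentration: int, diatom: str):
        """Underlying truncated-normal parameters and scale for one cell.

        Returns ``(muL, sigL, muW, sigW, scale, debris)`` where the
        base distributions are moment-matched to the diatom-level targets
        and ``scale`` shrinks dimensions so the total expected volume
        multiplier (including the debris sub-population) is achieved.
        """
        mL, sL = self.length_mean[diatom], self.length_sd[diatom]
        mW = self.width_ratio * mL
        sW = self.width_cv * mW
        muL, sigL = _solve_truncnorm(mL, sL)
        muW, sigW = _solve_truncnorm(mW, sW)
        if nmp_class == "ctrl":
            return muL, sigL, muW, sigW, 1.0, 0.0
        m = self.volume_multipliers()[(nmp_class, concentration)]
        d = self.debris_fraction
        f = self.debris_length_factor
        scale = (m / (1.0 - d * (1.0 - f))) ** (1.0 / 3.0)
        return muL, sigL, muW, sigW, scale, d

    def expected_treatment_table(self) -> pd.DataFrame:
        """Exact expected mean length/width/volume per treatment."""
        rows = []
        for k, c, d in all_treatments():
            muL, sigL, muW, sigW, s, dbf = self.dimension_params(k, c, d)
            mL, sL = _truncnorm_moments(muL, sigL)
            mW, sW = _truncnorm_moments(muW, sigW)
            f = self.debris_length_factor
            mean_len = s * mL * (1.0 - dbf * (1.0 - f))
            var_len = (
                (1.0 - dbf) * (sL**2 + mL**2) + dbf * (f**2) * (sL**2 + mL**2)
            ) * s**2 - mean_len**2
            mean_wid = s * mW
            # E[V] = (pi/6) E[L] E[W^2], L and W independent
            mean_vol = (
                (np.pi / 6.0)
                * (s**3)
                * mL * (1.0 - dbf * (1.0 - f))
                * (sW**2 + mW**2)
            )
            rows.append(
                {
                    "treatment": treatment_id(k, c, d),
                    "nmp_class": k,
                    "concentration": c,
                    "diatom": d,
                    "length_mean": mean_len,
                    "length_sd": float(np.sqrt(max(var_len, 0.0))),
                    "width_mean": mean_wid,
                    "width_sd": s * sW,
                    "volume_mean": mean_vol,
                }
            )
        return pd.DataFrame(rows)

    def expected_count(self, nmp_class: str, concentration: int, diatom: str) -> float:
        """Expected pellets per replicate under the production model."""
        tid = treatment_id(nmp_class, concentration, diatom)
        rate = self.production_rate[tid]
        tab = self.expected_treatment_table()
        vol = float(tab.loc[tab.treatment == tid, "volume_mean"].iloc[0])
        return rate * 1e6 * self.individuals * self.duration_days / vol


_TN_CACHE: dict = {}


def _truncnorm_moments(mu: float, sigma: float) -> tuple[float, float]:
    a = -mu / sigma
    return (
        float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sigma)),
        float(stats.truncnorm.std(a, np.inf, loc=mu, scale=sigma)),
    )


def _solve_truncnorm(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Parameters (mu, sigma) whose zero-truncated moments hit the targets."""
    key = (round(target_mean, 9), round(target_sd, 9))
    if key in _TN_CACHE:
        return _TN_CACHE[key]
    if target_mean <= 0 or target_sd < 0:
        raise ValueError("impossible calibration: non-positive target mean")

    def resid(p):
        mu, log_sig = p
        m, s = _truncnorm_moments(mu, np.exp(log_sig))
        return [m - target_mean, s - target_sd]

    sol, info, ier, msg = optimize.fsolve(
        resid, [target_mean, np.log(target_sd)], full_output=True
    )
    if ier != 1 or not np.all(np.isfinite(sol)):
        raise ValueError(f"impossible calibration ({target_mean}, {target_sd}): {msg}")
    out = (float(sol[0]), float(np.exp(sol[1])))
    _TN_CACHE[key] = out
    return out


def _truncnorm_ppf(u: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    a = -mu / sigma
    return stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)


def generate_measurements(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    n_per_treatment: int | None = None,
    common_random_base: bool = False,
) -> pd.DataFrame:
    """Generate a pellet measurement table for the full 27-treatment design.

    By default pellet counts per replicate are Poisson with the
    production-calibrated expectation.  ``n_per_treatment`` forces a fixed
    total count per treatment (split over replicates), as used by the
    large-n calibration-recovery checks.  ``common_random_base`` reuses the
    same base uniform draws across the nine class x concentration cells
    within each (diatom level, replicate), a common-random-numbers mode
    that removes Monte-Carlo noise from treatment-vs-control volume ratios;
    replicates remain independent.  Fixed seed gives identical output.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    expected = None
    if n_per_treatment is None:
        tab = config.expected_treatment_table().set_index("treatment")
        expected = {
            tid: config.production_rate[tid] * 1e6 * config.individuals
            * config.duration_days / float(tab.loc[tid, "volume_mean"])
            for tid in tab.index
        }
    rows = []
    for d in DIATOM_LEVELS:
        cells = [("ctrl", 0, d)] + [
            (k, c, d) for k in NMP_CLASSES for c in CONCENTRATIONS
        ]
        for rep in range(1, config.replicates + 1):
            if n_per_treatment is not None:
                base_n = n_per_treatment // config.replicates
                extra = n_per_treatment % config.replicates
                count = base_n + (1 if rep <= extra else 0)
                counts = {cell: count for cell in cells}
            else:
                counts = {
                    cell: int(rng.poisson(expected[treatment_id(*cell)]))
                    for cell in cells
                }
            shared = None
            if common_random_base:
                n_max = max(counts.values())
                shared = {
                    "uL": rng.random(n_max),
                    "uW": rng.random(n_max),
                    "ud": rng.random(n_max),
                }
            for cell in cells:
                k, c, _ = cell
                n = counts[cell]
                if n == 0:
                    continue
                muL, sigL, muW, sigW, s, dbf = config.dimension_params(*cell)
                if shared is not None:
                    uL, uW, ud = (shared[x][:n] for x in ("uL", "uW", "ud"))
                else:
                    uL, uW, ud = rng.random(n), rng.random(n), rng.random(n)
                L = _truncnorm_ppf(uL, muL, sigL)
                W = _truncnorm_ppf(uW, muW, sigW)
                if shared is not None and cell[0] != "ctrl":
                    # calibration mode: volume-ordered systematic debris
                    # sampling, then rescale so the realised replicate volume
                    # total equals the configured multiplier times the shared
                    # base total — treatment/control volume ratios then carry
                    # no Monte-Carlo noise at all
                    vol0 = L * W * W
                    order = np.argsort(vol0)
                    ticks = np.floor((np.arange(n) + 1) * dbf) > np.floor(
                        np.arange(n) * dbf
                    )
                    debris = np.zeros(n, dtype=bool)
                    debris[order[ticks]] = True
                    L = np.where(debris, L * config.debris_length_factor, L)
                    m = config.volume_multipliers()[(cell[0], cell[1])]
                    realised = np.where(debris, config.debris_length_factor, 1.0)
                    s = (m * vol0.sum() / (realised * vol0).sum()) ** (1.0 / 3.0)
                else:
                    debris = ud < dbf
                    L = np.where(debris, L * config.debris_length_factor, L)
                L = L * s
                W = W * s
                for li, wi in zip(L, W):
                    rows.append(
                        (treatment_id(*cell), rep, float(li), float(wi))
                    )
    return pd.DataFrame(
        rows, columns=["treatment", "replicate", "length_um", "width_um"]
    )


def generate_fluorescence(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    n_per_treatment: int = 30,
) -> pd.DataFrame:
    """Per-pellet mean fluorescence intensities for the 27 treatments.

    Intensity rises with bead concentration (power law) and falls with
    diatom supply (attenuation factors); controls carry only the
    zero-centred noise floor.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 104729
    )
    rows = []
    per_rep = max(1, n_per_treatment // config.replicates)
    for k, c, d in all_treatments():
        if k == "ctrl":
            signal = 0.0
        else:
            signal = (
                config.fluor_amplitude
                * (c / max(CONCENTRATIONS)) ** config.fluor_conc_exponent
                * config.fluor_diatom_attenuation[d]
            )
        for rep in range(1, config.replicates + 1):
            vals = signal + rng.normal(0.0, config.fluor_noise_sd, per_rep)
            for v in vals:
                rows.append((treatment_id(k, c, d), rep, float(v)))
    return pd.DataFrame(rows, columns=["treatment", "replicate", "fluorescence"])
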