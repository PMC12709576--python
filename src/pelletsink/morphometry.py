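"""Measurement-side statistics: volumes, production, fluorescence, tests.

Consumes delimited-text measurement tables with columns
``treatment, replicate, length_um, width_um, fluorescence`` (fluorescence
optional) and produces the per-treatment summaries the exposure study
reports: equivalent-ellipsoid volumes, production rates in
10^6 um^3 per individual per day, relative fluorescence, size-frequency
histograms, and normality-gated rank-test group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MEASUREMENT_COLUMNS = ["treatment", "replicate", "length_um", "width_um"]


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def ellipsoid_volume(length_um, width_um):
    """Equivalent-ellipsoid pellet volume V = (4/3) pi (L/2) (W/2)^2, um^3.

    Pellets are long and thicker in the middle, so each is generalised to
    a prolate ellipsoid with the measured length as the long axis and the
    measured width as both short axes.
    """
    length_um = np.asarray(length_um, dtype=float)
    width_um = np.asarray(width_um, dtype=float)
    if np.any(length_um <= 0) or np.any(width_um <= 0):
        raise ValueError("pellet dimensions must be positive")
    vol = (4.0 / 3.0) * np.pi * (length_um / 2.0) * (width_um / 2.0) ** 2
    return float(vol) if vol.ndim == 0 else vol


@dataclass(frozen=True)
class ProductionRate:
    """Fecal pellet volume production, 10^6 um^3 per individual per day."""

    rate: float
    n_pellets: int
    empty: bool  # True when no pellets settled (rate 0, flagged)


def production_rate(
    measurements: pd.DataFrame, individuals: int = 3, duration_days: float = 1.0
) -> ProductionRate:
    """Summed pellet volume per individual per day for one replicate.

    All settled pellets, fragments included, are counted.
    """
    if individuals <= 0 or duration_days <= 0:
        raise ValueError("individuals and duration must be positive")
    if len(measurements) == 0:
        return ProductionRate(0.0, 0, empty=True)
    vols = ellipsoid_volume(
        measurements["length_um"].to_numpy(), measurements["width_um"].to_numpy()
    )
    total = np.atleast_1d(vols).sum()
    return ProductionRate(
        rate=float(total / 1e6 / individuals / duration_days),
        n_pellets=len(measurements),
        empty=False,
    )


def production_rate_table(
    measurements: pd.DataFrame, individuals: int = 3, duration_days: float = 1.0
) -> pd.DataFrame:
    """Per-(treatment, replicate) production rates for a full table."""
    rows = []
    for (trt, rep), grp in measurements.groupby(["treatment", "replicate"]):
        pr = production_rate(grp, individuals, duration_days)
        rows.append(
            {"treatment": trt, "replicate": rep, "rate": pr.rate,
             "n_pellets": pr.n_pellets, "empty": pr.empty}
        )
    return pd.DataFrame(rows)


def relative_fluorescence(
    measurements: pd.DataFrame, reference_treatment: str
) -> pd.DataFrame:
    """Per-treatment mean fluorescence divided by the reference mean.

    Returns a frame with columns ``treatment, relative_mean, relative_sd,
    n``; the sd is the per-treatment dispersion scaled by the reference
    mean (propagated dispersion of the ratio numerator).
    """
    if "fluorescence" not in measurements.columns:
        raise ValueError("no fluorescence column in the measurement table")
    grouped = measurements.groupby("treatment")["fluorescence"]
    means = grouped.mean()
    sds = grouped.std()
    ns = grouped.size()
    if reference_treatment not in means.index:
        raise ValueError(f"reference treatment {reference_treatment!r} absent")
    ref = means[reference_treatment]
    if ref == 0:
        raise ValueError("reference mean fluorescence is zero")
    return pd.DataFrame(
        {
            "treatment": means.index,
            "relative_mean": (means / ref).to_numpy(),
            "relative_sd": (sds / abs(ref)).to_numpy(),
            "n": ns.to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class GroupComparison:
    """Normality-gated rank-test record for a two-sample comparison."""

    shapiro_p_a: float
    shapiro_p_b: float
    normal: bool            # both samples pass Shapiro-Wilk at alpha=0.05
    test: str               # rank test actually applied
    statistic: float
    p_value: float
    direction: int          # sign of median(B) - median(A)
    tied: bool = False


def compare_groups(
    sample_a, sample_b, paired: bool = False, alpha: float = 0.05
) -> GroupComparison:
    """Compare two samples with Shapiro-Wilk gating and a rank test.

    Normality of each sample is assessed first (recorded, not used to
    switch to a t-test: the study design calls for the nonparametric
    route).  The default comparison is the unpaired Wilcoxon rank-sum
    (Mann-Whitney) test; ``paired=True`` applies the signed-rank test to
    matched samples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    direction = int(np.sign(np.median(b) - np.median(a)))

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # degenerate constant sample: clearly non-normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro(a), _shapiro(b)
    all_tied = np.ptp(np.concatenate([a, b])) == 0 or (
        paired and np.ptp(b - a) == 0
    )
    if all_tied:
        return GroupComparison(pa, pb, normal=False, test="degenerate",
                               statistic=np.nan, p_value=1.0,
                               direction=0, tied=True)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal sample sizes")
        res = stats.wilcoxon(a, b)
        test = "wilcoxon-signed-rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon-rank-sum"
    return GroupComparison(
        shapiro_p_a=pa,
        shapiro_p_b=pb,
        normal=(pa > alpha and pb > alpha),
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
    )


@dataclass(frozen=True)
class SizeFrequency:
    """2D size-frequency histogram with conserved marginals."""

    counts: np.ndarray          # (n_length_bins, n_width_bins)
    length_edges: np.ndarray
    width_edges: np.ndarray
    length_marginal: np.ndarray
    width_marginal: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def size_frequency_distribution(
    measurements: pd.DataFrame,
    length_bins=20,
    width_bins=20,
) -> SizeFrequency:
    """Joint (length, width) histogram plus its one-dimensional marginals."""
    counts, le, we = np.histogram2d(
        measurements["length_um"].to_numpy(),
        measurements["width_um"].to_numpy(),
        bins=[length_bins, width_bins],
    )
    return SizeFrequency(
        counts=counts,
        length_edges=le,
        width_edges=we,
        length_marginal=counts.sum(axis=1),
        width_marginal=counts.sum(axis=0),
    )


def treatment_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of length, width and volume per treatment."""
    df = measurements.copy()
    df["volume_um3"] = ellipsoid_volume(
        df["length_um"].to_numpy(), df["width_um"].to_numpy()
    )
    agg = df.groupby("treatment").agg(
        n=("length_um", "size"),
        length_mean=("length_um", "mean"),
        length_sd=("length_um", "std"),
        width_mean=("width_um", "mean"),
        width_sd=("width_um", "std"),
        volume_mean=("volume_um3", "mean"),
        volume_sd=("volume_um3", "std"),
    )
    return agg.reset_index()


def volume_reduction(
    measurements: pd.DataFrame,
    treatments: list[str],
    control_treatments: list[str],
    diatom_of: dict[str, str],
) -> float:
    """Percent reduction in mean pellet volume vs control, standardised by
    diatom level.

    Mean volumes are computed per diatom level separately for the exposed
    and control groups, then combined with the exposed group's own pellet
    count weights, so that differences in diatom composition do not
    confound the plastic effect.  Returns 100 * (1 - V_exposed / V_control).
    """
    df = measurements.copy()
    df["volume_um3"] = ellipsoid_volume(
        df["length_um"].to_numpy(), df["width_um"].to_numpy()
    )
    df["diatom"] = df["treatment"].map(diatom_of)
    exp = df[df["treatment"].isin(treatments)]
    ctl = df[df["treatment"].isin(control_treatments)]
    if len(exp) == 0 or len(ctl) == 0:
        raise ValueError("empty exposed or control selection")
    v_exp = exp.groupby("diatom")["volume_um3"].mean()
    v_ctl = ctl.groupby("diatom")["volume_um3"].mean()
    weights = exp.groupby("diatom").size()
    common = v_exp.index.intersection(v_ctl.index)
    w = weights[common] / weights[common].sum()
    ratio = float((w * (v_exp[common] / v_ctl[common])).sum())
    return 100.0 * (1.0 - ratio)
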