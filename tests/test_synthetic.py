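"""Generator calibration, determinism and round-trip recovery."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, wilcoxon

from pelletsink.morphometry import production_rate_table
from pelletsink.synthetic import (
    CONCENTRATIONS,
    DIATOM_LEVELS,
    NMP_CLASSES,
    GeneratorConfig,
    all_treatments,
    generate_fluorescence,
    generate_measurements,
    treatment_id,
)


def test_design_has_27_treatments():
    cells = all_treatments()
    assert len(cells) == 27
    assert len({treatment_id(*c) for c in cells}) == 27


def test_same_seed_identical_tables(generator_config):
    a = generate_measurements(generator_config, seed=5, n_per_treatment=50)
    b = generate_measurements(generator_config, seed=5, n_per_treatment=50)
    assert a.equals(b)
    c = generate_measurements(generator_config, seed=6, n_per_treatment=50)
    assert not a.equals(c)


def test_impossible_calibration_rejected():
    cfg = GeneratorConfig(length_mean={"0": -5.0, "1e4": 100.6, "1e5": 142.5})
    with pytest.raises(ValueError):
        generate_measurements(cfg, n_per_treatment=10)


def test_multiplier_table_monotone_and_bounded(generator_config):
    m = generator_config.volume_multipliers()
    for k in NMP_CLASSES:
        vals = [m[(k, c)] for c in CONCENTRATIONS]
        assert all(0 < v <= 1 for v in vals)
        assert vals == sorted(vals, reverse=True)  # more plastic, less volume
    for c in CONCENTRATIONS:
        assert m[("MP", c)] < m[("NP", c)]  # MP reduces volume more


def test_high_diatom_control_calibration(generator_config):
    """Pooled control sample at n=1e4 recovers 142.5 +- 34.4 um lengths."""
    df = generate_measurements(generator_config, seed=1, n_per_treatment=10_000)
    ctl = df[df.treatment == treatment_id("ctrl", 0, "1e5")]
    assert ctl.length_um.mean() == pytest.approx(142.5, rel=0.01)
    assert ctl.length_um.std() == pytest.approx(34.4, rel=0.05)


def test_diatom_supply_orders_pellet_length(independent_table):
    """Marginal length means ordered: no diatoms < 1e4 < 1e5 cells/mL."""
    means = [
        independent_table[
            independent_table.treatment == treatment_id("ctrl", 0, d)
        ].length_um.mean()
        for d in DIATOM_LEVELS
    ]
    assert means[0] < means[1] < means[2]


def test_group_means_recovered_within_three_se(independent_table,
                                               generator_config):
    """Every configured treatment mean (length and width) is recovered
    within 3 standard errors at 1000 pellets/treatment."""
    exp = generator_config.expected_treatment_table().set_index("treatment")
    for tid, grp in independent_table.groupby("treatment"):
        for col, target in (
            ("length_um", exp.loc[tid, "length_mean"]),
            ("width_um", exp.loc[tid, "width_mean"]),
        ):
            x = grp[col].to_numpy()
            se = x.std(ddof=1) / np.sqrt(len(x))
            assert abs(x.mean() - target) < 3 * se, (tid, col)


def test_negative_volume_skew_under_exposure(independent_table):
    """The debris sub-population skews exposed volume distributions left."""
    from scipy.stats import skew

    mp = independent_table[
        independent_table.treatment == treatment_id("MP", 5000, "1e5")
    ]
    vol = np.log((np.pi / 6) * mp.length_um * mp.width_um**2)
    assert skew(vol) < -0.3


def test_production_rates_match_printed_anchors(generator_config):
    """Poisson counts reproduce the control production rates in expectation."""
    df = generate_measurements(generator_config, seed=2)
    rates = production_rate_table(df)

    def check(tid, target):
        r = rates[rates.treatment == tid].rate
        assert abs(r.mean() - target) < 2 * max(r.std(), 1e-6), tid

    check(treatment_id("ctrl", 0, "1e5"), 4.58)
    check(treatment_id("ctrl", 0, "0"), 0.13)
    check(treatment_id("MP", 5000, "0"), 1.00)


class TestFluorescence:
    def test_zero_noise_exact_configured_means(self):
        cfg = GeneratorConfig(fluor_noise_sd=0.0)
        fl = generate_fluorescence(cfg, seed=0)
        mp = fl[fl.treatment == treatment_id("MP", 5000, "0")]
        assert np.allclose(mp.fluorescence, cfg.fluor_amplitude)
        ctl = fl[fl.treatment == treatment_id("ctrl", 0, "0")]
        assert np.allclose(ctl.fluorescence, 0.0)

    def test_concentration_series_strictly_increasing(self, generator_config):
        """Per-diatom-level concentration means increase in >=95% of seeds."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            fl = generate_fluorescence(generator_config, seed=seed)
            good = True
            for d in DIATOM_LEVELS:
                for k in NMP_CLASSES:
                    means = [
                        fl[fl.treatment == treatment_id(k, c, d)]
                        .fluorescence.mean()
                        for c in CONCENTRATIONS
                    ]
                    good &= means == sorted(means)
            ok += good
        assert ok >= 0.95 * n_seeds

    def test_diatom_supply_attenuates_signal(self, generator_config):
        fl = generate_fluorescence(generator_config, seed=3)
        means = [
            fl[fl.treatment == treatment_id("MP", 5000, d)].fluorescence.mean()
            for d in DIATOM_LEVELS
        ]
        assert means[0] > means[1] > means[2]

    def test_controls_sit_on_noise_floor(self, generator_config):
        """Signed-rank test of control intensities against zero: median p
        across seeds is comfortably non-significant."""
        ps = []
        for seed in range(20):
            fl = generate_fluorescence(generator_config, seed=seed)
            ctl = fl[fl.treatment == treatment_id("ctrl", 0, "1e4")]
            ps.append(wilcoxon(ctl.fluorescence).pvalue)
        assert np.median(ps) > 0.05
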