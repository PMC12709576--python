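"""Ellipsoid volumes, production, fluorescence, rank tests, histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pelletsink.morphometry import (
    compare_groups,
    ellipsoid_volume,
    production_rate,
    production_rate_table,
    relative_fluorescence,
    size_frequency_distribution,
    treatment_summary,
)


class TestEllipsoidVolume:
    def test_sphere_limit(self):
        assert ellipsoid_volume(2.0, 2.0) == pytest.approx(4 * np.pi / 3)

    def test_base_pellet_dimensions(self):
        assert ellipsoid_volume(100, 20) == pytest.approx(20943.951, abs=0.01)

    def test_control_mean_dimensions(self):
        # volume of the mean control dimensions; note the study's reported
        # mean volume (29,628 um^3) averages per-pellet volumes instead
        assert ellipsoid_volume(124.2, 20.1) == pytest.approx(26273.2, abs=1.0)

    @given(k=st.floats(0.1, 10), L=st.floats(1, 500), r=st.floats(0.05, 1))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_three(self, k, L, r):
        W = L * r
        assert ellipsoid_volume(k * L, k * W) == pytest.approx(
            (k**3) * ellipsoid_volume(L, W), rel=1e-9
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(0, 10)


class TestProductionRate:
    def _table(self, volumes_um3):
        # invert V=(pi/6) L W^2 with W=L/5
        L = (6 * np.asarray(volumes_um3) / np.pi * 25) ** (1 / 3)
        return pd.DataFrame(
            {"treatment": "t", "replicate": 1, "length_um": L,
             "width_um": L / 5}
        )

    def test_three_unit_megapellets(self):
        pr = production_rate(self._table([1e6, 1e6, 1e6]), individuals=3,
                             duration_days=1.0)
        assert pr.rate == pytest.approx(1.0, rel=1e-9)
        assert not pr.empty

    def test_empty_set_flagged_zero(self):
        pr = production_rate(self._table([]).iloc[:0], individuals=3,
                             duration_days=1.0)
        assert pr.rate == 0.0
        assert pr.empty

    def test_additive_over_disjoint_subsets(self):
        vols = [2e5, 5e5, 1e6, 3e6]
        whole = production_rate(self._table(vols)).rate
        parts = (production_rate(self._table(vols[:2])).rate
                 + production_rate(self._table(vols[2:])).rate)
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_table_covers_all_replicates(self):
        df = pd.concat([
            self._table([1e6]).assign(replicate=r) for r in (1, 2, 3)
        ])
        out = production_rate_table(df)
        assert len(out) == 3


class TestRelativeFluorescence:
    def _df(self):
        return pd.DataFrame({
            "treatment": ["ref"] * 4 + ["a"] * 4 + ["b"] * 4,
            "replicate": 1,
            "fluorescence": [10, 12, 8, 10] + [10, 12, 8, 10]
            + [20, 24, 16, 20],
        })

    def test_reference_is_unity_and_doubling_is_two(self):
        out = relative_fluorescence(self._df(), "ref").set_index("treatment")
        assert out.loc["ref", "relative_mean"] == pytest.approx(1.0)
        assert out.loc["a", "relative_mean"] == pytest.approx(1.0)
        assert out.loc["b", "relative_mean"] == pytest.approx(2.0)

    def test_zero_reference_rejected(self):
        df = self._df()
        df.loc[df.treatment == "ref", "fluorescence"] = 0.0
        with pytest.raises(ValueError):
            relative_fluorescence(df, "ref")


class TestCompareGroups:
    def test_identical_samples_null_center(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value >= 0.99

    def test_constant_tied_samples_flagged(self):
        res = compare_groups([5, 5, 5], [5, 5, 5])
        assert res.tied
        assert res.p_value == 1.0

    def test_separated_triples_exact_rank_p(self):
        """{1,2,3} vs {10,11,12}: the most extreme of C(6,3)=20 labellings,
        two-sided exact p = 2/20 = 0.1."""
        res = compare_groups([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1, rel=1e-9)
        assert res.direction == 1
        assert res.test == "wilcoxon-rank-sum"

    def test_exact_p_matches_permutation_enumeration(self):
        """Brute-force enumeration of rank-sum labellings as the oracle."""
        from itertools import combinations

        a = np.array([1.3, 2.1, 5.0])
        b = np.array([2.8, 6.2, 7.1])
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:3].sum()
        sums = [sum(c) for c in combinations(ranks, 3)]
        centre = ranks.sum() / 2
        p_exact = np.mean([abs(s - centre) >= abs(obs - centre) for s in sums])
        res = compare_groups(a, b)
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_paired_signed_rank_available(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 3.5, 4.0, 5.5, 6.0, 8.0]
        res = compare_groups(a, b, paired=True)
        assert res.test == "wilcoxon-signed-rank"
        assert res.direction == 1

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [3, 4, 5])

    def test_shapiro_gate_recorded(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        assert 0 <= res.shapiro_p_a <= 1
        assert res.normal in (True, False)


class TestSizeFrequency:
    def test_single_measurement_single_bin(self):
        df = pd.DataFrame({"treatment": ["t"], "replicate": [1],
                           "length_um": [100.0], "width_um": [20.0]})
        sf = size_frequency_distribution(df, length_bins=5, width_bins=5)
        assert sf.total == 1
        assert sf.counts.max() == 1
        assert sf.length_marginal.sum() == 1
        assert sf.width_marginal.sum() == 1

    @given(n=st.integers(1, 200))
    @settings(max_examples=20, deadline=None)
    def test_totals_conserved(self, n):
        rng = np.random.default_rng(n)
        df = pd.DataFrame({
            "treatment": "t", "replicate": 1,
            "length_um": rng.uniform(10, 250, n),
            "width_um": rng.uniform(3, 40, n),
        })
        sf = size_frequency_distribution(df)
        assert sf.total == n
        assert sf.length_marginal.sum() == n
        assert sf.width_marginal.sum() == n

    def test_treatment_summary_columns(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "treatment": ["a"] * 10 + ["b"] * 10, "replicate": 1,
            "length_um": rng.uniform(50, 150, 20),
            "width_um": rng.uniform(10, 30, 20),
        })
        out = treatment_summary(df)
        assert set(out.treatment) == {"a", "b"}
        assert (out.volume_mean > 0).all()
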