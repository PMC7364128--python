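"""Genome-scan statistics: LOD values, thresholds, intervals, models."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlconverge.containers import GenotypeMatrix, MarkerMap, PhenotypeVector
from qtlconverge.errors import ScanError
from qtlconverge.scan import (
    LodCurve,
    fit_multi_qtl,
    pair_scan,
    permutation_thresholds,
    single_scan,
    support_interval,
)
from qtlconverge.simulate import (
    QtlArchitecture,
    simulate_phenotype,
    simulate_ri_genotypes,
    uniform_marker_map,
)

from conftest import phenotype_for


def anova_lod(code: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: two-group ANOVA LOD from group means."""
    mask = ~np.isnan(code)
    code, y = code[mask], y[mask]
    n = len(y)
    rss0 = ((y - y.mean()) ** 2).sum()
    rss1 = 0.0
    for allele in (0.0, 1.0):
        grp = y[code == allele]
        if len(grp):
            rss1 += ((grp - grp.mean()) ** 2).sum()
    if rss1 == 0:
        return 300.0
    return (n / 2.0) * np.log10(rss0 / rss1)


class TestSingleScan:
    def test_constant_phenotype_gives_zero_lod(self, tiny_genotypes):
        y = phenotype_for(tiny_genotypes, np.ones(20))
        curve = single_scan(tiny_genotypes, y)
        assert (curve.table["lod"] == 0).all()

    def test_closed_form_lod_at_half_r_squared(self):
        # 20 strains, marker explaining exactly half the variance:
        # LOD = -(20/2) * log10(1 - 0.5) = 10 * log10(2)
        mm = MarkerMap(["m1"], ["1"], [100])
        code = np.array([0.0] * 10 + [1.0] * 10)
        g = GenotypeMatrix([f"S{i}" for i in range(20)], mm, code[:, None])
        y = phenotype_for(g, code - 0.5 + np.tile([0.5, -0.5], 10))
        curve = single_scan(g, y)
        assert curve.lod_of("m1") == pytest.approx(10 * np.log10(2), abs=1e-9)
        assert curve.lod_of("m1") == pytest.approx(anova_lod(code, y.series.to_numpy()), abs=1e-9)

    def test_agrees_with_anova_oracle_everywhere(self):
        mm = uniform_marker_map(n_chromosomes=3, markers_per_chromosome=8)
        g = simulate_ri_genotypes(60, mm, 0.3, seed=5)
        rng = np.random.default_rng(6)
        y = phenotype_for(g, g.calls[:, 4] + rng.standard_normal(60))
        curve = single_scan(g, y)
        yv = y.series.to_numpy()
        for _, row in curve.table.iterrows():
            expected = anova_lod(g.column(row["marker"]), yv)
            assert row["lod"] == pytest.approx(expected, abs=1e-9)

    def test_sign_tracks_increaser_allele(self, tiny_genotypes):
        code = tiny_genotypes.calls[:, 2]
        up = phenotype_for(tiny_genotypes, code * 2.0 + 0.1)
        down = phenotype_for(tiny_genotypes, -code * 2.0)
        assert single_scan(tiny_genotypes, up).table["sign"].iloc[2] == 1
        assert single_scan(tiny_genotypes, down).table["sign"].iloc[2] == -1

    def test_monomorphic_marker_has_zero_lod_and_sign(self, small_map):
        calls = np.ones((10, 5))
        calls[:, 1] = np.tile([0.0, 1.0], 5)
        g = GenotypeMatrix([f"S{i}" for i in range(10)], small_map, calls)
        y = phenotype_for(g, np.arange(10, dtype=float))
        t = single_scan(g, y).table
        assert t.loc[t["marker"] == "m1", "lod"].iloc[0] == 0
        assert t.loc[t["marker"] == "m1", "sign"].iloc[0] == 0

    def test_markers_with_too_few_observations_are_flagged(self, small_map):
        calls = np.random.default_rng(0).integers(0, 2, (10, 5)).astype(float)
        calls[2:, 0] = np.nan
        g = GenotypeMatrix([f"S{i}" for i in range(10)], small_map, calls)
        y = phenotype_for(g, np.arange(10, dtype=float))
        curve = single_scan(g, y)
        assert "m1" not in set(curve.table["marker"])
        assert curve.skipped and curve.skipped[0][0] == "m1"

    def test_planted_locus_is_recovered_as_genome_peak(self):
        mm = uniform_marker_map()
        planted = str(mm.marker[mm.indices_on("1")[7]])
        arch = QtlArchitecture(additive=((planted, 0.15),))
        hits = 0
        for s in range(100):
            g = simulate_ri_genotypes(100, mm, 0.25, seed=500 + s)
            y = simulate_phenotype(g, arch, seed=900 + s)
            if single_scan(g, y).peak_marker() == planted:
                hits += 1
        assert hits >= 90

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0), flip=st.booleans())
    def test_lod_invariant_under_affine_phenotype_transform(self, a, b, flip):
        mm = uniform_marker_map(n_chromosomes=2, markers_per_chromosome=5)
        g = simulate_ri_genotypes(40, mm, 0.3, seed=11)
        rng = np.random.default_rng(12)
        base = g.calls[:, 3] + rng.standard_normal(40)
        scale = -a if flip else a
        lod1 = single_scan(g, phenotype_for(g, base)).table["lod"].to_numpy()
        lod2 = single_scan(g, phenotype_for(g, scale * base + b)).table["lod"].to_numpy()
        assert np.max(np.abs(lod1 - lod2)) < 1e-9


class TestPermutationThresholds:
    def test_deterministic_given_seed(self, tiny_genotypes):
        y = phenotype_for(tiny_genotypes, np.random.default_rng(1).standard_normal(20))
        with pytest.warns(UserWarning):
            a = permutation_thresholds(tiny_genotypes, y, n_perm=50, seed=9)
            b = permutation_thresholds(tiny_genotypes, y, n_perm=50, seed=9)
        assert a == b

    def test_significant_at_least_suggestive(self, tiny_genotypes):
        y = phenotype_for(tiny_genotypes, np.random.default_rng(2).standard_normal(20))
        t = permutation_thresholds(tiny_genotypes, y, n_perm=200, seed=3)
        assert t.significant >= t.suggestive >= 0

    def test_low_permutation_count_warns_but_returns(self, tiny_genotypes):
        y = phenotype_for(tiny_genotypes, np.random.default_rng(3).standard_normal(20))
        with pytest.warns(UserWarning):
            t = permutation_thresholds(tiny_genotypes, y, n_perm=20, seed=4)
        assert t.n_perm == 20


class TestSupportInterval:
    def make_curve(self, lods):
        return LodCurve(
            table=pd.DataFrame(
                {
                    "marker": ["m1", "m2", "m3", "m4", "m5"],
                    "chrom": ["4"] * 5,
                    "pos_bp": [10_000_000, 20_000_000, 30_000_000, 40_000_000, 50_000_000],
                    "lod": lods,
                    "sign": [1] * 5,
                    "n": [20] * 5,
                }
            )
        )

    def test_hand_walked_drop_example(self):
        # peak 4.0 at 30 Mb, threshold 2.5: first drops at 20 and 40 Mb
        iv = support_interval(self.make_curve([1.0, 2.0, 4.0, 2.4, 1.0]), "m3")
        assert (iv.left_bp, iv.right_bp) == (20_000_000, 40_000_000)
        assert iv.drop == 1.5

    def test_clamped_at_chromosome_ends(self):
        iv = support_interval(self.make_curve([5.0, 4.9, 4.8, 4.7, 4.6]), "m1")
        assert iv.left_bp == 10_000_000
        assert iv.right_bp == 50_000_000

    def test_unknown_peak_marker_rejected(self):
        with pytest.raises(ScanError):
            support_interval(self.make_curve([1, 2, 3, 2, 1]), "nope")


class TestMultiQtl:
    def test_noiseless_single_locus_explains_everything(self, tiny_genotypes):
        y = phenotype_for(tiny_genotypes, tiny_genotypes.calls[:, 1])
        model = fit_multi_qtl(tiny_genotypes, y, loci=["m2"])
        assert model.total_percent == pytest.approx(100.0, abs=1e-6)

    def test_drop_one_percents_recover_planted_fractions(self):
        # covered at scale by the acceptance suite; spot-check one seed here
        mm = uniform_marker_map()
        m1 = str(mm.marker[mm.indices_on("1")[7]])
        m2 = str(mm.marker[mm.indices_on("2")[7]])
        arch = QtlArchitecture(additive=((m1, 0.1138), (m2, 0.1560)))
        g = simulate_ri_genotypes(200, mm, 0.25, seed=31)
        y = simulate_phenotype(g, arch, seed=32)
        model = fit_multi_qtl(g, y, loci=[m1, m2])
        assert model.percent_of(m1) == pytest.approx(11.38, abs=8)
        assert model.percent_of(m2) == pytest.approx(15.60, abs=8)

    def test_adding_terms_never_decreases_total_percent(self, tiny_genotypes):
        rng = np.random.default_rng(7)
        y = phenotype_for(tiny_genotypes, tiny_genotypes.calls[:, 0] + rng.standard_normal(20))
        small = fit_multi_qtl(tiny_genotypes, y, loci=["m1"])
        bigger = fit_multi_qtl(tiny_genotypes, y, loci=["m1", "m3"])
        biggest = fit_multi_qtl(tiny_genotypes, y, loci=["m1", "m3"], interactions=[("m1", "m3")])
        assert small.total_percent <= bigger.total_percent + 1e-9
        assert bigger.total_percent <= biggest.total_percent + 1e-9
        assert biggest.total_percent >= max(p for _, p in biggest.term_percents) - 1e-9

    def test_monomorphic_term_is_excluded_and_reported(self, small_map):
        calls = np.random.default_rng(1).integers(0, 2, (12, 5)).astype(float)
        calls[:, 4] = 1.0
        g = GenotypeMatrix([f"S{i}" for i in range(12)], small_map, calls)
        y = phenotype_for(g, calls[:, 0] + np.random.default_rng(2).standard_normal(12))
        model = fit_multi_qtl(g, y, loci=["m1", "m5"])
        assert ("m5", "monomorphic") in model.excluded

    def test_empty_loci_rejected(self, tiny_genotypes):
        y = phenotype_for(tiny_genotypes, np.arange(20, dtype=float))
        with pytest.raises(ScanError):
            fit_multi_qtl(tiny_genotypes, y, loci=[])

    def test_sequential_decomposition_sums_to_total(self, tiny_genotypes):
        rng = np.random.default_rng(8)
        y = phenotype_for(
            tiny_genotypes, tiny_genotypes.calls[:, 0] + rng.standard_normal(20)
        )
        model = fit_multi_qtl(
            tiny_genotypes, y, loci=["m1", "m3"], decomposition="sequential"
        )
        assert sum(p for _, p in model.term_percents) == pytest.approx(
            model.total_percent, abs=1e-9
        )


class TestPairScan:
    def test_interaction_lod_is_nonnegative(self):
        mm = uniform_marker_map(n_chromosomes=3, markers_per_chromosome=4)
        g = simulate_ri_genotypes(60, mm, 0.3, seed=41)
        y = phenotype_for(g, np.random.default_rng(42).standard_normal(60))
        result = pair_scan(g, y)
        assert result.interaction_lod >= 0

    def test_planted_epistatic_pair_is_recovered(self):
        mm = uniform_marker_map(n_chromosomes=4, markers_per_chromosome=5)
        ma = str(mm.marker[mm.indices_on("1")[2]])
        mb = str(mm.marker[mm.indices_on("2")[2]])
        hits = 0
        for s in range(100):
            g = simulate_ri_genotypes(200, mm, 0.3, seed=600 + s)
            za = g.column(ma) - g.column(ma).mean()
            zb = g.column(mb) - g.column(mb).mean()
            rng = np.random.default_rng(700 + s)
            y = phenotype_for(g, za * zb * 2.0 + 0.5 * rng.standard_normal(200))
            result = pair_scan(g, y)
            if {result.marker_a, result.marker_b} == {ma, mb}:
                hits += 1
        assert hits >= 90

    def test_additive_trait_shows_no_significant_interaction(self):
        mm = uniform_marker_map(n_chromosomes=3, markers_per_chromosome=5)
        m1 = str(mm.marker[mm.indices_on("1")[2]])
        m2 = str(mm.marker[mm.indices_on("2")[2]])
        arch = QtlArchitecture(additive=((m1, 0.15), (m2, 0.15)))
        below = 0
        for s in range(50):
            g = simulate_ri_genotypes(100, mm, 0.3, seed=800 + s)
            y = simulate_phenotype(g, arch, seed=900 + s)
            result = pair_scan(g, y, n_perm=60, seed=1000 + s)
            threshold = np.quantile(np.array(result.perm_interaction_max), 0.95)
            if result.interaction_lod <= threshold:
                below += 1
        assert below >= 45

    def test_permutation_p_value_deterministic(self):
        mm = uniform_marker_map(n_chromosomes=2, markers_per_chromosome=4)
        g = simulate_ri_genotypes(50, mm, 0.3, seed=51)
        y = phenotype_for(g, np.random.default_rng(52).standard_normal(50))
        a = pair_scan(g, y, n_perm=50, seed=5)
        b = pair_scan(g, y, n_perm=50, seed=5)
        assert a == b

    def test_no_eligible_pairs_rejected(self):
        mm = uniform_marker_map(n_chromosomes=1, markers_per_chromosome=3)
        g = simulate_ri_genotypes(30, mm, 0.3, seed=61)
        y = phenotype_for(g, np.random.default_rng(62).standard_normal(30))
        with pytest.raises(ScanError):
            pair_scan(g, y, min_separation="chromosome")
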