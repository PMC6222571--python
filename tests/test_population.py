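"""Synthetic F2 generator: map structure, meiosis, degradation, phenotypes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acylqtl.errors import InvalidConfigError, InvalidInputError
from acylqtl.genome import MarkerMap
from acylqtl.genotypes import spacing_stats
from acylqtl.phenotypes import derive_traits
from acylqtl.population import (
    CausalLocus,
    PopulationConfig,
    _gamete_phases,
    build_marker_map,
    default_causal_loci,
    degrade_calls,
    simulate_f2,
    simulate_phenotypes,
)


class TestBuildMarkerMap:
    def test_default_density_matches_gbs_spacing(self):
        mm = build_marker_map(PopulationConfig(seed=2))
        assert len(mm) == 8062
        mean_gap = spacing_stats(mm)["mean_gap_bp"]
        # GBS-like density: mean adjacent gap within 2x of 255 kb
        assert 255_000 / 2 < mean_gap < 255_000 * 2

    def test_ten_markers_give_one_per_chromosome(self):
        mm = build_marker_map(PopulationConfig(n_markers=10, seed=3))
        counts = mm.table.groupby("chrom").size()
        assert (counts == 1).all()
        assert spacing_stats(mm)["n_gaps"] == 0

    def test_chromosome_one_can_hold_the_acylation_locus(self):
        mm = build_marker_map(PopulationConfig(seed=4))
        assert mm.chrom_lengths[1] >= 301_476_924

    def test_terminal_regions_are_denser(self):
        cfg = PopulationConfig(n_markers=8062, end_density_boost=3.0, seed=5)
        mm = build_marker_map(cfg)
        chr1 = mm.table[mm.table.chrom == 1]
        L = mm.chrom_lengths[1]
        frac = chr1.pos.to_numpy() / L
        in_ends = ((frac < 0.1) | (frac > 0.9)).mean()
        assert in_ends > 0.25  # uniform would give ~0.20

    def test_seeded_runs_identical(self):
        cfg = PopulationConfig(n_markers=500, seed=9)
        a = build_marker_map(cfg)
        b = build_marker_map(cfg)
        assert a.table.equals(b.table)

    def test_invalid_chromosome_length_rejected(self):
        with pytest.raises(InvalidConfigError):
            PopulationConfig(chrom_lengths={1: -5})


class TestMeiosis:
    def test_het_frequency_mendelian(self, population):
        g, _ = population
        het = (g.codes == 1.0).mean(axis=1)
        se = np.sqrt(0.5 * 0.5 / g.n_samples)
        # overall het frequency near 1/2 at essentially every marker
        assert abs(het.mean() - 0.5) < 3 * se
        assert (np.abs(het - 0.5) < 5 * se).mean() > 0.98

    def test_zero_distance_fully_linked(self):
        lengths = {1: 10_000_000}
        mm = MarkerMap(
            pd.DataFrame({"chrom": [1, 1], "pos": [5_000_000, 5_000_001]}),
            lengths, {1: 0.7},
        )
        cfg = PopulationConfig(
            n_individuals=500, n_markers=2, residual_founder_het=0.0,
            chrom_lengths=lengths, seed=21,
        )
        g = simulate_f2(mm, [], cfg)
        # 1 bp apart: essentially zero recombination, codes identical
        assert np.array_equal(g.codes[0], g.codes[1])

    @pytest.mark.parametrize("d_cm", [5.0, 20.0, 50.0])
    def test_haldane_recombination_fraction(self, d_cm):
        # oracle: Haldane closed form r = (1 - exp(-2d/100)) / 2
        rng = np.random.default_rng(123)
        n_gametes = 20_000
        phases = _gamete_phases(rng, np.array([10.0, 10.0 + d_cm]), 200.0, n_gametes)
        r_hat = (phases[:, 0] != phases[:, 1]).mean()
        r = (1.0 - np.exp(-2.0 * d_cm / 100.0)) / 2.0
        se = np.sqrt(r * (1 - r) / n_gametes)
        assert abs(r_hat - r) < 3 * se

    def test_one_to_two_to_one_segregation(self):
        cfg = PopulationConfig(
            n_individuals=10_000, n_markers=20, residual_founder_het=0.05, seed=17
        )
        mm = build_marker_map(cfg)
        g = simulate_f2(mm, [], cfg)
        for i in range(g.n_markers):
            counts = [
                int((g.codes[i] == c).sum()) for c in (0.0, 1.0, 2.0)
            ]
            _, p = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
            assert p > 0.001

    def test_empty_map_rejected(self):
        import pandas as pd

        mm = MarkerMap(pd.DataFrame({"chrom": [], "pos": []}))  # noqa: F841
        with pytest.raises(InvalidInputError):
            simulate_f2(mm, [], PopulationConfig(seed=1))

    def test_residual_het_creates_third_alleles(self, population):
        g, _ = population
        calls = set(np.unique(g.raw_calls))
        assert "CC" in calls or "AC" in calls


class TestDegradeCalls:
    def test_zero_rates_identity(self, population, pop_config):
        g, _ = population
        out = degrade_calls(g, pop_config)
        assert np.array_equal(out.codes, g.codes, equal_nan=True)
        assert np.array_equal(out.raw_calls, g.raw_calls)

    def test_full_missing_saturates(self, population, pop_config):
        g, _ = population
        cfg = dataclasses.replace(pop_config, missing_rate=1.0)
        out = degrade_calls(g, cfg)
        assert np.isnan(out.codes).all()
        assert out.n_markers == g.n_markers  # map retained even when all-missing

    def test_missing_fraction_binomial(self, population, pop_config):
        g, _ = population
        cfg = dataclasses.replace(pop_config, missing_rate=0.2)
        out = degrade_calls(g, cfg)
        n_cells = g.codes.size
        frac = np.isnan(out.codes).mean()
        se = np.sqrt(0.2 * 0.8 / n_cells)
        assert abs(frac - 0.2) < 3 * se

    def test_het_miscalls_become_homozygotes(self, population, pop_config):
        g, _ = population
        cfg = dataclasses.replace(pop_config, het_miscall_rate=1.0)
        out = degrade_calls(g, cfg)
        assert not (out.codes == 1.0).any()

    def test_causal_truth_never_degraded(self, population, pop_config):
        g, _ = population
        cfg = dataclasses.replace(pop_config, missing_rate=0.9, het_miscall_rate=0.9)
        out = degrade_calls(g, cfg)
        assert out.causal_genotypes.equals(g.causal_genotypes)


class TestSimulatePhenotypes:
    def test_null_model_returns_baseline(self, pop_config):
        cfg = dataclasses.replace(
            pop_config, n_markers=10, acylation_sd=0.0, ac_noise_sigma=0.0,
            replicate_cv_pct=0.0,
        )
        loci = [
            dataclasses.replace(loc, effects={}) for loc in default_causal_loci()
        ]
        mm = build_marker_map(cfg)
        g = simulate_f2(mm, loci, cfg)
        ph = simulate_phenotypes(g, loci, cfg)
        assert np.allclose(ph.table.ac_mg_kg, cfg.ac_baseline)

    def test_recessive_mutant_count_near_quarter(self, population):
        _, ph = population
        count = ph.table.is_reduced_acylation.sum()
        se = np.sqrt(128 * 0.25 * 0.75)
        assert abs(count - 32) < 3 * se

    def test_bimodal_class_means(self, population, pop_config):
        _, ph = population
        t = ph.table
        mut = t[t.is_reduced_acylation == 1]
        wt = t[t.is_reduced_acylation == 0]
        tol_mut = 3 * pop_config.acylation_sd / np.sqrt(len(mut))
        tol_wt = 3 * pop_config.acylation_sd / np.sqrt(len(wt))
        assert abs(mut.acylation_pct.mean() - 15.0) < tol_mut
        assert abs(wt.acylation_pct.mean() - 70.8) < tol_wt

    def test_round_trip_through_derivation(self, population, pop_config):
        _, ph = population
        traits = derive_traits(ph.peaks, standard_total_area=pop_config.standard_total_area)
        merged = traits.set_index("sample").loc[ph.table["sample"]]
        assert np.allclose(merged.ac_mg_kg, ph.table.ac_mg_kg, rtol=1e-9)
        assert np.allclose(merged.acylation_pct, ph.table.acylation_pct, rtol=1e-9)

    def test_replicate_cv_calibration(self, population, pop_config):
        _, ph = population
        traits = derive_traits(ph.peaks, standard_total_area=pop_config.standard_total_area)
        mean_cv = traits.cv_pct.mean()
        # half-normal spread of a two-replicate CV around its mean
        cv_sd = traits.cv_pct.std(ddof=1)
        se = cv_sd / np.sqrt(len(traits))
        assert abs(mean_cv - 3.09) < 3 * se

    def test_right_skewed_ac(self, population):
        _, ph = population
        ac = ph.table.ac_mg_kg
        assert stats.skew(ac) > 0

    def test_negative_class_mean_rejected(self):
        with pytest.raises(InvalidConfigError):
            PopulationConfig(acylation_mut_mean=-1.0)

    def test_seeded_phenotypes_reproducible(self, pop_config, causal_loci):
        cfg = dataclasses.replace(pop_config, n_markers=50)
        mm = build_marker_map(cfg)
        g = simulate_f2(mm, causal_loci, cfg)
        a = simulate_phenotypes(g, causal_loci, cfg)
        b = simulate_phenotypes(g, causal_loci, cfg)
        assert a.table.equals(b.table)
        assert a.peaks.equals(b.peaks)

    def test_requires_single_acylation_locus(self, population, pop_config):
        g, _ = population
        loci = [dataclasses.replace(l, is_acylation_locus=True) for l in default_causal_loci()]
        with pytest.raises(InvalidConfigError):
            simulate_phenotypes(g, loci, pop_config)
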