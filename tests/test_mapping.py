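"""Marker scans against a brute-force OLS oracle; stepwise selection; intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acylqtl.errors import DegenerateTraitError
from acylqtl.genome import MarkerMap
from acylqtl.genotypes import GenotypeMatrix
from acylqtl.mapping import (
    Threshold,
    bonferroni,
    manhattan_export,
    scan_single_marker,
    significant_interval,
    stepwise_scan,
)


def ols_oracle(y, x, covs=()):
    """Independent per-marker OLS: normal-equations solve + t survival function."""
    X = np.column_stack([np.ones(len(y)), x] + [np.asarray(c, float) for c in covs])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return beta[1], p


def _matrix(codes, positions=None, chrom=1, length=None):
    codes = np.asarray(codes, dtype=float)
    m, n = codes.shape
    positions = positions or [1000 * (i + 1) for i in range(m)]
    length = length or max(positions) + 1000
    mm = MarkerMap(
        pd.DataFrame({"chrom": chrom, "pos": positions}), {chrom: length}, {chrom: 0.7}
    )
    return GenotypeMatrix(mm, [f"s{j}" for j in range(n)], codes)


class TestBonferroni:
    def test_gbs_panel_threshold(self):
        thr = bonferroni(0.05, 8062)
        assert thr.per_test_p == pytest.approx(6.2019e-6, rel=1e-4)
        assert 5.2074 <= thr.minus_log10 <= 5.2075

    def test_single_test(self):
        assert bonferroni(0.05, 1).per_test_p == 0.05

    def test_hundred_tests(self):
        assert bonferroni(0.05, 100).per_test_p == pytest.approx(5e-4)

    def test_relaxed_threshold_constructor(self):
        thr = Threshold.from_per_test_p(1e-4)
        assert thr.per_test_p == 1e-4
        assert thr.minus_log10 == pytest.approx(4.0)


class TestScanAgainstOracle:
    def test_four_point_example(self):
        g = _matrix([[0.0, 0.0, 2.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = scan_single_marker(g, y)
        b_o, p_o = ols_oracle(y, g.codes[0])
        assert res.table.loc[0, "beta"] == pytest.approx(1.0)
        assert res.table.loc[0, "p"] == pytest.approx(p_o, abs=1e-10)

    def test_random_markers_match_oracle(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(30, 40)).astype(float)
        y = rng.normal(size=40)
        g = _matrix(codes)
        res = scan_single_marker(g, y)
        for i in range(30):
            b_o, p_o = ols_oracle(y, codes[i])
            assert res.table.loc[i, "beta"] == pytest.approx(b_o, abs=1e-10)
            assert res.table.loc[i, "p"] == pytest.approx(p_o, abs=1e-10)

    def test_covariate_scan_matches_oracle(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 3, size=(20, 50)).astype(float)
        y = codes[3] * 1.5 + rng.normal(size=50)
        g = _matrix(codes)
        res = scan_single_marker(g, y, covariates=[3])
        for i in range(20):
            if i == 3:
                assert res.table.loc[i, "flag"] == "collinear"
                assert res.table.loc[i, "p"] == 1.0
                continue
            b_o, p_o = ols_oracle(y, codes[i], covs=[codes[3]])
            assert res.table.loc[i, "beta"] == pytest.approx(b_o, abs=1e-10)
            assert res.table.loc[i, "p"] == pytest.approx(p_o, abs=1e-10)

    def test_missing_data_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 3, size=(10, 60)).astype(float)
        codes[rng.uniform(size=codes.shape) < 0.15] = np.nan
        y = rng.normal(size=60)
        g = _matrix(codes)
        res = scan_single_marker(g, y)
        for i in range(10):
            v = ~np.isnan(codes[i])
            b_o, p_o = ols_oracle(y[v], codes[i, v])
            assert res.table.loc[i, "n_used"] == v.sum()
            assert res.table.loc[i, "beta"] == pytest.approx(b_o, abs=1e-10)
            assert res.table.loc[i, "p"] == pytest.approx(p_o, abs=1e-10)

    def test_missing_data_with_covariates_matches_oracle(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(8, 60)).astype(float)
        codes[rng.uniform(size=codes.shape) < 0.1] = np.nan
        y = rng.normal(size=60)
        g = _matrix(codes)
        res = scan_single_marker(g, y, covariates=[0])
        for i in range(1, 8):
            v = ~np.isnan(codes[i]) & ~np.isnan(codes[0])
            b_o, p_o = ols_oracle(y[v], codes[i, v], covs=[codes[0, v]])
            assert res.table.loc[i, "beta"] == pytest.approx(b_o, abs=1e-10)
            assert res.table.loc[i, "p"] == pytest.approx(p_o, abs=1e-10)

    def test_monomorphic_marker_flagged(self):
        g = _matrix([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 0.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = scan_single_marker(g, y)
        assert res.table.loc[0, "flag"] == "monomorphic"
        assert res.table.loc[0, "p"] == 1.0

    def test_constant_trait_is_degenerate(self):
        g = _matrix([[0.0, 1.0, 2.0]])
        with pytest.raises(DegenerateTraitError):
            scan_single_marker(g, np.array([5.0, 5.0, 5.0]))

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        g = _matrix([[0.0, 0.0, 2.0, 2.0], [0.0, 2.0, 0.0, 2.0]])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        plain = scan_single_marker(g, y)
        with_cov = scan_single_marker(g, y, covariates=[1])
        assert with_cov.table.loc[0, "beta"] == pytest.approx(
            plain.table.loc[0, "beta"], abs=1e-12
        )


class TestStepwise:
    def test_monogenic_trait_selects_single_qtl(self, population):
        g, ph = population
        thr = bonferroni(0.05, g.n_markers)
        y = ph.table.is_reduced_acylation.to_numpy(dtype=float)
        res = stepwise_scan(g, y, thr)
        assert len(res.selected) == 1
        row = res.rounds[0].table.loc[res.selected[0]]
        assert row["chrom"] == 1
        assert abs(row["pos"] - 300_173_138) <= 10_000_000

    def test_two_locus_trait_recovers_both(self, population):
        g, ph = population
        thr = bonferroni(0.05, g.n_markers)
        truth = g.causal_genotypes
        y = (
            50.0 * (truth.loc["aat1"].to_numpy(dtype=float) == 2)
            + 40.0 * (truth.loc["in1"].to_numpy(dtype=float) == 2)
            + np.random.default_rng(3).normal(0, 1.0, g.n_samples)
        )
        res = stepwise_scan(g, y, thr)
        assert len(res.selected) == 2
        found = {
            int(res.rounds[0].table.loc[i, "chrom"]) for i in res.selected
        }
        assert found == {1, 7}
        for i in res.selected:
            row = res.rounds[0].table.loc[i]
            target = 300_173_138 if row["chrom"] == 1 else 88_000_000
            assert abs(row["pos"] - target) <= 10_000_000

    def test_noise_trait_selects_nothing(self, population):
        g, _ = population
        thr = bonferroni(0.05, g.n_markers)
        misses = 0
        n_seeds = 20
        for seed in range(n_seeds):
            y = np.random.default_rng(seed).normal(size=g.n_samples)
            res = stepwise_scan(g, y, thr)
            misses += len(res.selected) > 0
        assert misses <= 1  # family-wise control: >=95% of null scans empty

    def test_permuted_trait_loses_significance(self, population):
        g, ph = population
        thr = bonferroni(0.05, g.n_markers)
        y = ph.table.acylation_pct.to_numpy()
        rng = np.random.default_rng(44)
        exceed = 0
        n_perm = 20
        for _ in range(n_perm):
            res = scan_single_marker(g, rng.permutation(y))
            top = res.top_marker()
            exceed += res.table.loc[top, "minus_log10_p"] > thr.minus_log10
        assert exceed <= 1


class TestIntervalsAndManhattan:
    def test_interval_spans_significant_markers(self):
        codes = np.tile([0.0, 0.0, 2.0, 2.0, 1.0, 1.0], (3, 1))
        g = _matrix(codes, positions=[279_200_000, 290_000_000, 301_400_000],
                    length=302_000_000)
        y = np.array([0.0, 0.1, 10.0, 10.1, 5.0, 5.2])
        res = scan_single_marker(g, y)
        thr = Threshold.from_per_test_p(1e-3)
        assert significant_interval(res, thr, 1) == (279_200_000, 301_400_000)

    def test_no_significant_markers_empty(self, population):
        g, _ = population
        y = np.random.default_rng(1).normal(size=g.n_samples)
        res = scan_single_marker(g, y)
        thr = Threshold.from_per_test_p(1e-12)
        assert significant_interval(res, thr, 1) is None

    def test_single_marker_zero_width(self):
        g = _matrix([[0.0, 0.0, 2.0, 2.0]], positions=[500_000])
        y = np.array([0.0, 0.1, 10.0, 10.1])
        res = scan_single_marker(g, y)
        thr = Threshold.from_per_test_p(1e-2)
        assert significant_interval(res, thr, 1) == (500_000, 500_000)

    def test_manhattan_has_all_markers(self, population):
        g, ph = population
        thr = bonferroni(0.05, g.n_markers)
        res = scan_single_marker(g, ph.table.acylation_pct.to_numpy())
        man = manhattan_export(res, thr)
        assert len(man) == g.n_markers
        assert man.attrs["threshold_minus_log10"] == pytest.approx(thr.minus_log10)
        # cumulative coordinate strictly increasing in map order
        assert (np.diff(man["cum_pos"].to_numpy()) > 0).all()

    def test_peak_on_causal_chromosome(self, population):
        g, ph = population
        thr = bonferroni(0.05, g.n_markers)
        res = scan_single_marker(g, ph.table.acylation_pct.to_numpy())
        man = manhattan_export(res, thr)
        assert man.loc[man["minus_log10_p"].idxmax(), "chrom"] == 1

    def test_all_p_one_gives_zero_heights(self):
        g = _matrix([[1.0, 1.0, 1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = scan_single_marker(g, y)
        man = manhattan_export(res, bonferroni(0.05, 1))
        assert (man["minus_log10_p"] == 0.0).all()
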