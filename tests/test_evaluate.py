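import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blink import (bin_markers, bin_pvalues, enrichment_null, overlap_count,
                   power_fdr_curve, power_type1_curve, scan_markers,
                   simulate_genotypes)


def make_scan(chroms, positions, pvals):
    from blink.fem import ScanResult
    m = len(pvals)
    return ScanResult(
        marker_id=np.array([f"m{i}" for i in range(m)]),
        chromosome=np.asarray(chroms),
        position=np.asarray(positions),
        effect=np.zeros(m), standard_error=np.ones(m),
        test_statistic=np.zeros(m), p_value=np.asarray(pvals, float),
        n_used=np.full(m, 10),
    )


class TestBinning:
    def test_one_bp_bins_are_single_markers(self):
        gmap = pd.DataFrame({"chromosome": ["1"] * 4,
                             "position": [10, 20, 30, 40]})
        bins = bin_markers(gmap, [1, 3], 1)
        assert bins["is_qtn_bin"].tolist() == [False, True, False, True]
        assert bins.groupby(["bin_chrom", "bin_index"]).ngroups == 4

    def test_cobinning_within_1kb(self):
        gmap = pd.DataFrame({"chromosome": ["1", "1"],
                             "position": [100, 900]})
        bins = bin_markers(gmap, [0], 1000)
        assert bins["bin_index"].nunique() == 1
        assert bins["is_qtn_bin"].all()

    def test_matches_bruteforce_rebinning(self):
        rng = np.random.default_rng(60)
        gmap = pd.DataFrame({
            "chromosome": rng.choice(["1", "2", "3"], size=200),
            "position": rng.integers(1, 1_000_000, size=200),
        })
        qtn = rng.choice(200, size=12, replace=False)
        for bs in (1, 1000, 100_000):
            bins = bin_markers(gmap, qtn, bs)
            for i in range(200):
                expected_bin = (gmap.position[i] - 1) // bs
                assert bins.bin_index[i] == expected_bin
                same = [j for j in range(200)
                        if gmap.chromosome[j] == gmap.chromosome[i]
                        and (gmap.position[j] - 1) // bs == expected_bin]
                assert bins.is_qtn_bin[i] == any(j in set(qtn) for j in same)

    def test_bin_pvalue_is_group_min(self):
        gmap = pd.DataFrame({"chromosome": ["1", "1", "1"],
                             "position": [5, 7, 2000]})
        scan = make_scan(["1", "1", "1"], [5, 7, 2000], [0.3, 1e-9, 0.5])
        bins = bin_markers(gmap, [0], 1000)
        bp, qb = bin_pvalues(scan, bins)
        assert sorted(bp) == [1e-9, 0.5]
        assert bp[qb][0] == 1e-9

    def test_undefined_only_bins_excluded(self):
        gmap = pd.DataFrame({"chromosome": ["1", "2"], "position": [1, 1]})
        scan = make_scan(["1", "2"], [1, 1], [np.nan, 0.2])
        bins = bin_markers(gmap, [0], 1)
        bp, qb = bin_pvalues(scan, bins)
        assert len(bp) == 1 and bp[0] == 0.2


class TestCurves:
    def test_perfect_separation_auc_one(self):
        bin_p = np.array([1e-8, 1e-7, 0.2, 0.5, 0.9])
        qtn = np.array([True, True, False, False, False])
        assert power_fdr_curve(bin_p, qtn).auc == pytest.approx(1.0)
        assert power_type1_curve(bin_p, qtn).auc == pytest.approx(1.0)

    def test_half_power_point(self):
        bin_p = np.array([1e-8, 0.4, 0.05, 0.9])
        qtn = np.array([True, True, False, False])
        curve = power_fdr_curve(bin_p, qtn)
        assert 0.5 in curve.points[:, 1]

    def test_fdr_fraction(self):
        # 3 QTN bins + 1 non-QTN bin positive at the loosest threshold
        bin_p = np.array([1e-9, 1e-8, 1e-7, 1e-6, 0.9, 0.95])
        qtn = np.array([True, True, True, False, False, False])
        curve = power_fdr_curve(bin_p, qtn)
        assert any(np.isclose(c, 0.25) for c in curve.points[:, 0])

    def test_type1_reaches_one(self):
        bin_p = np.array([0.01, 0.2, 0.6])
        qtn = np.array([True, False, False])
        curve = power_type1_curve(bin_p, qtn)
        assert curve.points[-1, 0] == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(61)
        bin_p = rng.random(5000)
        qtn = np.zeros(5000, bool)
        qtn[rng.choice(5000, 500, replace=False)] = True
        assert power_type1_curve(bin_p, qtn).auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_and_closed(self):
        rng = np.random.default_rng(62)
        bin_p = rng.random(100) ** 2
        qtn = rng.random(100) < 0.3
        for fn in (power_fdr_curve, power_type1_curve):
            c = fn(bin_p, qtn)
            assert np.all(np.diff(c.points[:, 0]) >= 0)
            assert np.all(np.diff(c.points[:, 1]) >= 0)
            assert c.points[0, 0] == 0 and c.points[0, 1] == 0
            assert c.points[-1, 0] == 1.0
            assert 0.0 <= c.auc <= 1.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(63)
        bin_p = rng.random(300)
        qtn = rng.random(300) < 0.2
        for fn in (power_fdr_curve, power_type1_curve):
            a = fn(bin_p, qtn)
            b = fn(np.sqrt(bin_p), qtn)  # strictly monotone transform
            np.testing.assert_allclose(a.points, b.points)
            assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_no_qtn_bins_rejected(self):
        with pytest.raises(ValueError):
            power_fdr_curve(np.array([0.1, 0.2]), np.array([False, False]))


class TestEnrichment:
    def test_certain_event(self):
        assert enrichment_null(10, 0.03, 0) == 1.0

    def test_closed_form_matches_explicit_binomial_sum(self):
        from math import comb
        f = 0.03
        expected = sum(comb(9, k) * f**k * (1 - f) ** (9 - k)
                       for k in range(4, 10))
        got = enrichment_null(9, f, 4, mode="binomial")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0.01  # 4+ of 9 loci in 3% of the genome is < 1%

    def test_forty_loci_bound(self):
        assert enrichment_null(40, 0.03, 8, mode="binomial") < 0.05

    def test_monte_carlo_agrees_with_binomial(self):
        p = enrichment_null(9, 0.05, 2, mode="binomial")
        mc = enrichment_null(9, 0.05, 2, mode="monte_carlo",
                             n_samples=100_000, seed=64)
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(mc - p) <= 3 * se + 1e-4

    def test_contracts(self):
        with pytest.raises(ValueError):
            enrichment_null(5, 1.5, 1)
        with pytest.raises(ValueError):
            enrichment_null(5, 0.03, 6)


class TestOverlap:
    def test_inclusive_boundary(self):
        genes = pd.DataFrame({"chromosome": ["1"], "position": [100_000]})
        at = pd.DataFrame({"chromosome": ["1"], "position": [150_000]})
        beyond = pd.DataFrame({"chromosome": ["1"], "position": [150_001]})
        assert overlap_count(at, genes, 50_000) == 1
        assert overlap_count(beyond, genes, 50_000) == 0

    def test_chromosome_must_match(self):
        genes = pd.DataFrame({"chromosome": ["2"], "position": [100]})
        loci = pd.DataFrame({"chromosome": ["1"], "position": [100]})
        assert overlap_count(loci, genes, 50_000) == 0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(65)
        genes = pd.DataFrame({
            "chromosome": rng.choice(["1", "2"], 50),
            "position": rng.integers(1, 5_000_000, 50),
        })
        loci = pd.DataFrame({
            "chromosome": rng.choice(["1", "2"], 30),
            "position": rng.integers(1, 5_000_000, 30),
        })
        expected = 0
        for _, l in loci.iterrows():
            hit = any(l.chromosome == g.chromosome
                      and abs(int(l.position) - int(g.position)) <= 50_000
                      for _, g in genes.iterrows())
            expected += hit
        assert overlap_count(loci, genes, 50_000) == expected


def test_signal_beats_permuted_phenotype_auc():
    """AUC under a real signal exceeds the AUC after permuting the trait."""
    from blink import sample_qtns, simulate_phenotype
    g = simulate_genotypes(250, 1200, seed=66)
    q = sample_qtns(g, 10, seed=66)
    tr = simulate_phenotype(g, q, h2=0.75, seed=66)
    rng = np.random.default_rng(67)
    scan_sig = scan_markers(g, tr.phenotype)
    scan_null = scan_markers(g, rng.permutation(tr.phenotype))
    bins = bin_markers(g.map, q, 10_000)
    bp_s, qb = bin_pvalues(scan_sig, bins)
    bp_n, _ = bin_pvalues(scan_null, bins)
    auc_s = power_fdr_curve(bp_s, qb).auc
    auc_n = power_fdr_curve(bp_n, qb).auc
    assert auc_s > auc_n + 0.2
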