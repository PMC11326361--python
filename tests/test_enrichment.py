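"""Odds ratios, MAF-matched baseline enrichment, GWAS filtering/clumping helpers."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from rhyqtl import enrichment as en
from rhyqtl import synthetic_data as sd
from rhyqtl.enrichment import ContingencyTable
from rhyqtl.io_formats import IntervalSet


class TestOddsRatio:
    def test_symmetry_and_degenerate_cells(self):
        assert en.odds_ratio(ContingencyTable(5, 5, 5, 5))[0] == 1.0
        assert en.odds_ratio(ContingencyTable(0, 3, 4, 5))[0] == 0.0
        assert en.odds_ratio(ContingencyTable(3, 0, 4, 5))[0] == np.inf
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_formula_arithmetic(self):
        orr, p = en.odds_ratio(ContingencyTable(10, 90, 10, 890))
        assert orr == pytest.approx(8900 / 900)
        # two-sided exact p = 5.12e-6; the one-sided upper tail is below 1e-6
        assert p < 1e-5
        _, p_greater = en.odds_ratio(ContingencyTable(10, 90, 10, 890),
                                     alternative="greater")
        assert p_greater < 1e-5
        orr, _ = en.odds_ratio(ContingencyTable(40, 160, 960, 8840))
        assert orr == pytest.approx(40 * 8840 / (160 * 960))

    def test_inversion_invariant(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, 4))
            orr1, _ = en.odds_ratio(ContingencyTable(a, b, c, d))
            orr2, _ = en.odds_ratio(ContingencyTable(b, a, d, c))
            assert orr1 == pytest.approx(1.0 / orr2)

    def test_fisher_p_matches_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher p equals direct enumeration for small tables."""
        for _ in range(15):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            n = a + b + c + d
            row1, col1 = a + b, a + c
            denom = comb(n, col1)
            probs = {}
            for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
                probs[x] = comb(row1, x) * comb(n - row1, col1 - x) / denom
            p_manual = sum(p for p in probs.values()
                           if p <= probs[a] * (1 + 1e-7))
            _, p = en.odds_ratio(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(min(1.0, p_manual), rel=1e-8)


class TestMafMatchedSample:
    def test_histograms_match_exactly(self, rng):
        target = rng.uniform(0.01, 0.5, 200)
        pool_maf = rng.uniform(0.01, 0.5, 5000)
        pool_ids = np.arange(5000)
        draw = en.maf_matched_sample(target, pool_ids, pool_maf, rng)
        assert len(draw) == len(target)
        assert len(set(draw)) == len(draw)  # without replacement
        tbin = en._maf_bins(target)
        dbin = en._maf_bins(pool_maf[draw])
        np.testing.assert_array_equal(np.bincount(tbin, minlength=49),
                                      np.bincount(dbin, minlength=49))

    def test_single_bin_target(self, rng):
        target = np.full(10, 0.105)
        pool_maf = np.concatenate([np.full(50, 0.105), np.full(50, 0.4)])
        draw = en.maf_matched_sample(target, np.arange(100), pool_maf, rng)
        assert len(draw) == 10 and np.all(draw < 50)

    def test_insufficient_bin_named(self, rng):
        with pytest.raises(ValueError, match=r"0\.10"):
            en.maf_matched_sample(np.full(10, 0.105), np.arange(5),
                                  np.full(5, 0.105), rng)


class TestBaselineEnrichment:
    def test_category_equal_baseline_gives_exactly_one(self, rng):
        snps, cats, base = sd.simulate_enrichment_tables(20_000, 1, 2.0,
                                                         seed=4,
                                                         qtl_fraction=0.1)
        res = en.baseline_enrichment(snps, snps["is_qtl"], base, base,
                                     n_iter=5, seed=4)
        assert res.per_iteration == pytest.approx([1.0] * 5)

    def test_disjoint_category_gives_zero(self):
        snps, _, base = sd.simulate_enrichment_tables(20_000, 1, 1.0, seed=5,
                                                      qtl_fraction=0.1)
        # category holds only non-QTL SNPs, so observed QTL overlap is zero
        # while the MAF-matched expected draws do hit it
        non_qtl_pos = snps.loc[~snps["is_qtl"], "pos"].head(600)
        cat = IntervalSet.from_tuples([("chr1", int(p) - 1, int(p))
                                       for p in non_qtl_pos])
        res = en.baseline_enrichment(snps, snps["is_qtl"], cat, base,
                                     n_iter=5, seed=5)
        assert res.e_obs == 0
        assert len(res.per_iteration) >= 1
        assert all(v == 0 for v in res.per_iteration)

    def test_planted_odds_ratio_recovered(self):
        snps, cats, base = sd.simulate_enrichment_tables(50_000, 1, 3.0, seed=6)
        res = en.baseline_enrichment(snps, snps["is_qtl"], cats[0], base,
                                     n_iter=30, seed=6)
        assert len(res.per_iteration) == 30
        assert 2.5 <= res.median <= 3.5


class TestMotifEnrichment:
    def test_independent_flags_near_unit_odds(self, rng):
        n = 10_000
        ids = pd.Index([f"s{i}" for i in range(n)])
        qtl = pd.Series(rng.random(n) < 0.2, index=ids)
        in_motif = rng.random(n) < 0.1
        hits = pd.DataFrame({"snp_id": ids[in_motif], "motif_id": "M1"})
        out = en.motif_enrichment(qtl, hits)
        assert 0.8 < out.loc["M1", "odds_ratio"] < 1.25
        assert out.loc["M1", "fisher_p"] > 0.01

    def test_planted_table_and_degenerate_motifs(self):
        ids = pd.Index([f"s{i}" for i in range(10)])
        qtl = pd.Series([True] * 4 + [False] * 6, index=ids)
        hits = pd.DataFrame({
            "snp_id": ["s0", "s1", "s2", "s3"],  # all QTLs, nothing else
            "motif_id": ["Mall"] * 4,
        })
        out = en.motif_enrichment(qtl, hits)
        assert out.loc["Mall", "odds_ratio"] == np.inf
        zero = pd.DataFrame({"snp_id": ["unknown"], "motif_id": ["M0"]})
        out = en.motif_enrichment(qtl, zero)
        assert np.isnan(out.loc["M0", "odds_ratio"])


class TestGwasFilters:
    def _assoc(self):
        return pd.DataFrame({
            "snp_id": ["a", "b", "c", "d"],
            "chrom": ["chr1", "chr1", "chr6", "chr2"],
            "pos": [100, 200, 30_000_000, 300],
            "trait": ["t"] * 4,
            "category": ["c"] * 4,
            "p": [1e-9, 1e-7, 1e-9, 1e-9],
            "ancestry": ["European", "European", "European", "East Asian"],
        })

    def test_each_filter_applies(self):
        out = en.filter_gwas_catalog(self._assoc())
        assert list(out["snp_id"]) == ["a"]  # b: p, c: HLA, d: ancestry

    def test_filters_configurable(self):
        out = en.filter_gwas_catalog(self._assoc(), european_only=False)
        assert list(out["snp_id"]) == ["a", "d"]


class TestLdExtend:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["snp1", "snp2", "r2"])

    def test_perfect_ld_extends_symmetrically(self):
        pairs = self._pairs([("S1", "S2", 1.0), ("S9", "S1", 1.0)])
        assert en.ld_extend({"S1"}, pairs) == {"S1", "S2", "S9"}

    def test_sub_perfect_ld_ignored(self):
        pairs = self._pairs([("S1", "S2", 0.99)])
        assert en.ld_extend({"S1"}, pairs) == {"S1"}

    def test_no_pairs_identity(self):
        assert en.ld_extend({"S1"}, self._pairs([])) == {"S1"}


class TestClumping:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p"])

    def test_window_suppresses_nearby_snps(self):
        stats = self._stats([("a", "chr1", 1_000, 1e-10),
                             ("b", "chr1", 501_000, 1e-9)])
        leads = en.clump_lead_snps(stats)
        assert list(leads["snp_id"]) == ["a"]

    def test_different_chromosomes_both_lead(self):
        stats = self._stats([("a", "chr1", 1_000, 1e-10),
                             ("b", "chr2", 1_000, 1e-9)])
        assert len(en.clump_lead_snps(stats)) == 2

    def test_greedy_trace(self):
        stats = self._stats([("a", "chr1", 1, 1e-10),
                             ("b", "chr1", 2_000_002, 1e-9),
                             ("c", "chr1", 900_000, 1e-12)])
        leads = en.clump_lead_snps(stats)
        assert list(leads["snp_id"]) == ["c", "b"]

    def test_order_invariance(self, rng):
        rows = [(f"s{i}", "chr1", int(rng.integers(1, 5_000_000)),
                 float(10.0 ** -rng.uniform(8.5, 20))) for i in range(30)]
        base = en.clump_lead_snps(self._stats(rows))
        for _ in range(5):
            perm = [rows[j] for j in rng.permutation(30)]
            again = en.clump_lead_snps(self._stats(perm))
            pd.testing.assert_frame_equal(base, again)

    def test_ld_clumping_rule(self):
        stats = self._stats([("a", "chr1", 1, 1e-12),
                             ("b", "chr9", 1, 1e-9)])
        ld = pd.DataFrame({"snp1": ["a"], "snp2": ["b"], "r2": [0.5]})
        leads = en.clump_lead_snps(stats, ld_pairs=ld)
        assert list(leads["snp_id"]) == ["a"]


class TestLeadRegion:
    def _qtls(self, positions, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_contribution_and_exclusivity(self):
        lead = ("chr1", 5_000_000)
        rhy = self._qtls([4_500_000 + i for i in range(6)])
        out = en.classify_lead_region(lead, rhy, self._qtls([]))
        assert out == {"rhy_count": 6, "eqtl_count": 0,
                       "rhy_contributed": True, "rhy_exclusive": True}

    def test_below_threshold_or_with_eqtls(self):
        lead = ("chr1", 5_000_000)
        rhy4 = self._qtls([5_000_000 + i for i in range(4)])
        out = en.classify_lead_region(lead, rhy4, self._qtls([]))
        assert not out["rhy_contributed"]
        rhy6 = self._qtls([5_000_000 + i for i in range(6)])
        out = en.classify_lead_region(lead, rhy6, self._qtls([5_100_000, 5_200_000]))
        assert out["rhy_contributed"] and not out["rhy_exclusive"]

    def test_window_boundary(self):
        lead = ("chr1", 5_000_000)
        rhy = self._qtls([4_000_000, 6_000_000, 6_000_001])
        out = en.classify_lead_region(lead, rhy, self._qtls([]), min_rhy=2)
        assert out["rhy_count"] == 2


class TestBonferroni:
    def test_reported_threshold_reproduced(self):
        thr = en.bonferroni_threshold(644_251)
        assert thr == pytest.approx(0.05 / 644_251)
        assert en.truncate_2sig(thr) == pytest.approx(7.7e-8, rel=1e-12)

    def test_simple_cases(self):
        assert en.bonferroni_threshold(1) == 0.05
        assert en.bonferroni_threshold(1000) == pytest.approx(5e-5)
        with pytest.raises(ValueError):
            en.bonferroni_threshold(0)
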