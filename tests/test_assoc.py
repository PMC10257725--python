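"""Association engine: OLS burden tests, scans, multiple testing, offsets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gripvar as gv
from gripvar.assoc import round_sig


@pytest.fixture(scope="module")
def ptv_burden(small_cohort):
    bm = gv.gene_burden(small_cohort.genotypes, small_cohort.variants, "ptv",
                        genes=small_cohort.genes)
    bm, _ = gv.carrier_filter(bm, 10)
    return bm


class TestDesign:
    def test_column_count_and_intercept(self, small_cohort):
        design = gv.build_design(small_cohort.covariates)
        assert design.shape[1] == 30  # intercept + 20 PCs + 9 anthropometric terms
        assert (design["intercept"] == 1.0).all()

    def test_constant_column_rejected(self, small_cohort):
        cov = small_cohort.covariates.copy()
        cov["sex"] = 1
        with pytest.raises(ValueError, match="constant"):
            gv.build_design(cov)


class TestFitBurdenLm:
    def test_matches_statsmodels_ols(self, small_cohort, small_design, ptv_burden):
        """Beta, SE and two-sided t-test p agree with statsmodels to 1e-10."""
        import statsmodels.api as sm

        y = small_cohort.phenotypes["hgs"]
        col = ptv_burden.column(ptv_burden.units[0])
        res = gv.fit_burden_lm(col, y, small_design)
        X = np.column_stack([small_design.to_numpy(), col.to_numpy()])
        ols = sm.OLS(y.to_numpy(), X).fit()
        assert res.beta == pytest.approx(ols.params[-1], abs=1e-10)
        assert res.se == pytest.approx(ols.bse[-1], abs=1e-10)
        assert res.p == pytest.approx(ols.pvalues[-1], abs=1e-10)

    def test_zero_variance_burden_is_an_error(self, small_cohort, small_design):
        col = pd.Series(0, index=small_cohort.samples, name="empty")
        with pytest.raises(ValueError, match="zero-variance"):
            gv.fit_burden_lm(col, small_cohort.phenotypes["hgs"], small_design)

    def test_exact_offset_cancels_polygenic_signal(self):
        """Offsetting the exact polygenic component reproduces the polygenic-free fit."""
        spec = gv.SimSpec(n_samples=3000, n_genes=20, seed=31, variants_per_gene=6.0,
                          class_proportions={"ptv": 1.0, "missense": 0.0, "synonymous": 0.0},
                          rare_maf_range=(2e-4, 9.9e-4), polygenic_h2=0.5)
        c = gv.simulate_cohort(spec)
        design = gv.build_design(c.covariates)
        bm = gv.gene_burden(c.genotypes, c.variants, "ptv", genes=c.genes)
        col = bm.column(bm.units[0])
        poly = pd.Series(c.truth["polygenic_component"], index=c.samples)
        y = pd.Series(c.truth["latent"], index=c.samples)
        res_with = gv.fit_burden_lm(col, y, design, offset=poly)
        res_clean = gv.fit_burden_lm(col, y - poly, design)
        assert res_with.beta == pytest.approx(res_clean.beta, abs=1e-10)
        assert res_with.se == pytest.approx(res_clean.se, abs=1e-10)

    def test_constant_offset_shift_absorbed_by_intercept(self, small_cohort, small_design, ptv_burden):
        y = small_cohort.phenotypes["hgs"]
        col = ptv_burden.column(ptv_burden.units[0])
        base = gv.fit_burden_lm(col, y, small_design)
        shifted = gv.fit_burden_lm(col, y, small_design,
                                   offset=pd.Series(3.7, index=y.index))
        assert shifted.beta == pytest.approx(base.beta, abs=1e-10)
        assert shifted.se == pytest.approx(base.se, abs=1e-10)


class TestBurdenScanFWL:
    def test_scan_identical_to_per_gene_ols(self, small_cohort, small_design, ptv_burden):
        """The residualized fast path equals per-gene full OLS exactly."""
        y = small_cohort.phenotypes["hgs"]
        scan = gv.burden_scan(ptv_burden, y, small_design)
        for unit in list(ptv_burden.units)[:10]:
            single = gv.fit_burden_lm(ptv_burden.column(unit), y, small_design)
            assert scan.loc[unit, "beta"] == pytest.approx(single.beta, abs=1e-9)
            assert scan.loc[unit, "se"] == pytest.approx(single.se, abs=1e-9)
            assert scan.loc[unit, "p"] == pytest.approx(single.p, abs=1e-9)

    def test_zero_variance_column_flagged_untestable(self, small_cohort, small_design, ptv_burden):
        counts = ptv_burden.counts.copy()
        counts["dead"] = 0
        scan = gv.burden_scan(gv.BurdenMatrix(counts), small_cohort.phenotypes["hgs"], small_design)
        assert bool(scan.loc["dead", "untestable"])
        assert np.isnan(scan.loc["dead", "beta"])


class TestMultipleTesting:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [
            (0.05, 15, 0.0033),
            (0.05, 15786, 3.2e-6),
            (0.05, 17557, 2.8e-6),
            (0.05, 11370, 4.4e-6),
            (0.05, 3892, 1.3e-5),
            (0.05, 1, 0.05),
        ],
    )
    def test_bonferroni_reproduces_printed_thresholds(self, alpha, m, expected):
        assert gv.bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_errors(self):
        with pytest.raises(ValueError):
            gv.bonferroni_threshold(0.05, 0)

    def test_bh_hand_example(self):
        q = gv.bh_fdr([0.01, 0.02, 0.03, 0.8])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.8], atol=1e-12)

    def test_bh_trivial_cases(self):
        assert gv.bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(gv.bh_fdr([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            gv.bh_fdr([])

    def test_bh_matches_brute_force_and_statsmodels(self, rng):
        """Exact agreement with a brute-force step-up and with statsmodels."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(25):
            m = int(rng.integers(1, 400))
            p = rng.uniform(1e-12, 1.0, m)
            q = gv.bh_fdr(p)
            # brute force: q_(i) = min_{j >= i} p_(j) m / j
            order = np.argsort(p)
            ps = p[order]
            brute = np.array([min(ps[j] * m / (j + 1) for j in range(i, m)) for i in range(m)])
            brute = np.minimum(brute, 1.0)
            np.testing.assert_array_equal(q[order], brute)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestScans:
    def test_exome_scan_has_15_categories(self, small_cohort, small_design):
        scan = gv.run_exome_scan(small_cohort.genotypes, small_cohort.variants,
                                 small_cohort.genes, small_cohort.phenotypes["hgs"], small_design)
        assert len(scan) == 15
        assert scan.attrs["threshold"] == 0.0033
        assert set(scan["category"]) == set(gv.burden.VARIANT_CLASSES)

    def test_empty_category_flagged_untestable_not_dropped(self, small_design):
        spec = gv.SimSpec(n_samples=3000, n_genes=30, seed=2, variants_per_gene=5.0,
                          rare_maf_range=(2e-4, 9.9e-4),
                          class_proportions={"ptv": 0.0, "missense": 0.0, "synonymous": 1.0})
        c = gv.simulate_cohort(spec)
        design = gv.build_design(c.covariates)
        scan = gv.run_exome_scan(c.genotypes, c.variants, c.genes, c.phenotypes["hgs"], design)
        assert len(scan) == 15
        ptv_rows = scan[scan["category"] == "ptv"]
        assert ptv_rows["untestable"].all()

    def test_gene_scan_recovers_injected_gene_as_top_hit(self):
        spec = gv.SimSpec(n_samples=12_000, n_genes=80, seed=41, variants_per_gene=6.0,
                          rare_maf_range=(2e-4, 9.9e-4),
                          class_proportions={"ptv": 1.0, "missense": 0.0, "synonymous": 0.0},
                          ptv_high_confidence_frac=1.0,
                          effect_table={"G00007": -4.0}, noise_sd=5.0)
        c = gv.simulate_cohort(spec)
        design = gv.build_design(c.covariates)
        bm = gv.gene_burden(c.genotypes, c.variants, "ptv", genes=c.genes)
        bm, _ = gv.carrier_filter(bm, 10)
        res = gv.run_gene_scan(bm, c.phenotypes["hgs"], design)
        assert res["p"].idxmin() == "G00007"
        assert res.loc["G00007", "beta"] < 0

    def test_sex_stratified_equal_effects_consistent(self, small_cohort, ptv_burden):
        res = gv.sex_stratified_scan(ptv_burden, small_cohort.phenotypes["hgs"],
                                     small_cohort.covariates)
        ok = ~(res["untestable_m"] | res["untestable_f"])
        assert ok.any()
        # equal true effects (here: null) -> heterogeneity p roughly uniform
        p = res.loc[ok, "het_p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_sex_stratified_single_sex_flagged(self, small_cohort, ptv_burden):
        cov = small_cohort.covariates.copy()
        males = cov.index[cov["sex"] == 1]
        res = gv.sex_stratified_scan(
            gv.BurdenMatrix(ptv_burden.counts.loc[males]),
            small_cohort.phenotypes.loc[males, "hgs"], cov.loc[males],
        )
        assert res["untestable_f"].all()
        assert not res["untestable_m"].any()


class TestXChromScan:
    def test_aneuploid_removed_and_autosomes_rejected(self, small_cohort):
        x_genes = {g: a for g, a in small_cohort.genes.items() if a.chromosome_class == "X"}
        bm = gv.gene_burden(small_cohort.genotypes, small_cohort.variants, "ptv",
                            genes=small_cohort.genes)
        x_units = [u for u in bm.units if u in x_genes]
        assert x_units, "fixture must contain X genes with PTVs"
        x_bm = gv.BurdenMatrix(bm.counts[x_units])
        ph = small_cohort.phenotypes
        res = gv.xchrom_scan(x_bm, small_cohort.genes, ph["hgs"], small_cohort.covariates,
                             aneuploidy=ph["sex_aneuploidy"])
        n_aneuploid = int(ph["sex_aneuploidy"].sum())
        assert (res.loc[~res["untestable"], "n"] == len(ph) - n_aneuploid).all()
        with pytest.raises(ValueError, match="autosomal"):
            gv.xchrom_scan(bm, small_cohort.genes, ph["hgs"], small_cohort.covariates,
                           aneuploidy=ph["sex_aneuploidy"])

    def test_male_dosage_coding_doubles_male_burden(self, small_cohort):
        x_genes = [g for g, a in small_cohort.genes.items() if a.chromosome_class == "X"]
        bm = gv.gene_burden(small_cohort.genotypes, small_cohort.variants, "ptv",
                            genes=small_cohort.genes)
        x_units = [u for u in bm.units if u in x_genes]
        x_bm = gv.BurdenMatrix(bm.counts[x_units])
        ph = small_cohort.phenotypes
        res2 = gv.xchrom_scan(x_bm, small_cohort.genes, ph["hgs"], small_cohort.covariates,
                              aneuploidy=ph["sex_aneuploidy"], male_dosage="0/2")
        res1 = gv.xchrom_scan(x_bm, small_cohort.genes, ph["hgs"], small_cohort.covariates,
                              aneuploidy=ph["sex_aneuploidy"], male_dosage="0/1")
        # same carriers either way; betas differ because male alleles count double
        ok = ~(res1["untestable"] | res2["untestable"])
        assert (res1.loc[ok, "n_carriers"] == res2.loc[ok, "n_carriers"]).all()


class TestGwasAndLoco:
    def test_gwas_excludes_low_maf_and_recovers_effect(self, rng):
        n, m = 4000, 30
        mafs = pd.Series(np.r_[np.full(5, 0.005), rng.uniform(0.05, 0.4, m - 5)],
                         index=[f"v{i}" for i in range(m)])
        G = pd.DataFrame(rng.binomial(2, mafs.to_numpy(), size=(n, m)),
                         columns=mafs.index)
        beta_true = 0.8
        y = pd.Series(beta_true * G["v10"] + rng.normal(0, 2, n))
        design = pd.DataFrame({"intercept": np.ones(n)})
        res = gv.single_variant_gwas(G, mafs, y, design)
        assert not any(f"v{i}" in res.index for i in range(5))  # MAF <= 0.01 out
        ci = 1.96 * res.loc["v10", "se"]
        assert abs(res.loc["v10", "beta"] - beta_true) < ci + 0.05

    def test_gwas_null_uniform_p(self, rng):
        n, m = 3000, 40
        mafs = pd.Series(rng.uniform(0.05, 0.5, m), index=[f"v{i}" for i in range(m)])
        G = pd.DataFrame(rng.binomial(2, mafs.to_numpy(), size=(n, m)), columns=mafs.index)
        y = pd.Series(rng.normal(0, 1, n))
        res = gv.single_variant_gwas(G, mafs, y, pd.DataFrame({"intercept": np.ones(n)}))
        assert stats.kstest(res["p"], "uniform").pvalue > 0.001

    def test_loco_offset_structure_and_null_shrinkage(self):
        spec = gv.SimSpec(n_samples=3000, n_genes=10, seed=3, n_common_variants=120,
                          rare_maf_range=(2e-4, 9.9e-4), polygenic_h2=0.0)
        c = gv.simulate_cohort(spec)
        design = gv.build_design(c.covariates)
        off = gv.loco_offset(c.common_genotypes, c.common_variants["chrom"],
                             c.phenotypes["hgs"], design, seed=0)
        assert off.shape == (3000, 22)
        # no polygenic signal: offsets shrink toward zero
        y_sd = c.phenotypes["hgs"].std()
        assert off.abs().mean().mean() < 0.05 * y_sd

    def test_loco_offset_excludes_own_chromosome(self):
        """Zeroing a chromosome's dosages must not change that chromosome's offset."""
        spec = gv.SimSpec(n_samples=1500, n_genes=10, seed=13, n_common_variants=66,
                          rare_maf_range=(2e-4, 9.9e-4), polygenic_h2=0.4)
        c = gv.simulate_cohort(spec)
        design = gv.build_design(c.covariates)
        off = gv.loco_offset(c.common_genotypes, c.common_variants["chrom"],
                             c.phenotypes["hgs"], design, seed=0)
        geno2 = c.common_genotypes.copy()
        chr1_vars = c.common_variants.index[c.common_variants["chrom"] == "1"]
        # replace chr-1 dosages with fresh noise-free constants: offsets for chr 1
        # are built only from the other chromosomes, so column '1' is unchanged
        geno2[chr1_vars] = 0
        geno2[chr1_vars[0]] = np.arange(1500) % 3  # keep matrix non-degenerate
        off2 = gv.loco_offset(geno2, c.common_variants["chrom"],
                              c.phenotypes["hgs"], design, seed=0)
        np.testing.assert_allclose(off["1"], off2["1"], atol=1e-8)

    def test_loco_single_chromosome_rejected(self, rng):
        G = pd.DataFrame(rng.binomial(2, 0.3, size=(200, 10)),
                         columns=[f"v{i}" for i in range(10)])
        chroms = pd.Series("1", index=G.columns)
        with pytest.raises(ValueError, match="2 chromosomes"):
            gv.loco_offset(G, chroms, pd.Series(rng.normal(size=200)),
                           pd.DataFrame({"intercept": np.ones(200)}))


class TestOverlap:
    def toy_inputs(self):
        genes = {
            "GA": gv.GeneAnnotation(gene="GA", chrom="1", start=1_000_000, end=1_050_000, pli=0.5),
            "GB": gv.GeneAnnotation(gene="GB", chrom="1", start=1_600_000, end=1_700_000, pli=0.5),
            "GC": gv.GeneAnnotation(gene="GC", chrom="2", start=500_000, end=600_000, pli=0.5),
            "GD": gv.GeneAnnotation(gene="GD", chrom="1", start=2_200_001, end=2_300_000, pli=0.5),
            "GE": gv.GeneAnnotation(gene="GE", chrom="2", start=5_000_000, end=5_100_000, pli=0.5),
        }
        leads = pd.DataFrame(
            {"rsid": ["r1", "r2", "r3"], "chrom": ["1", "2", "1"],
             "pos": [1_100_000, 550_000, 1_700_001], "maf": [0.2, 0.3, 0.005]}
        )
        results = pd.DataFrame(
            {"beta": 0.0, "se": 1.0, "p": [0.5, 0.01, 0.2, 0.9, 0.7]},
            index=pd.Index(genes, name="unit"),
        )
        return genes, leads, results

    def test_membership_matches_brute_force_closed_interval(self):
        genes, leads, results = self.toy_inputs()
        table, summary = gv.overlap_analysis(leads, genes, results, window=500_000)
        kept_leads = leads[leads["maf"] > 0.01]
        expected = set()
        for gid, g in genes.items():
            for _, l in kept_leads.iterrows():
                if str(l["chrom"]) == g.chrom and l["pos"] - 500_000 <= g.end and l["pos"] + 500_000 >= g.start:
                    expected.add(gid)
        assert set(table.index) == expected
        assert summary["n_leads_kept"] == 2  # r3 fails the MAF filter
        assert "GE" not in table.index

    def test_exact_500kb_boundary_included(self):
        genes = {"GX": gv.GeneAnnotation(gene="GX", chrom="1", start=1_500_000, end=1_600_000, pli=0.5)}
        results = pd.DataFrame({"beta": [0.0], "se": [1.0], "p": [0.5]},
                               index=pd.Index(["GX"], name="unit"))
        at = pd.DataFrame({"rsid": ["r"], "chrom": ["1"], "pos": [1_000_000], "maf": [0.2]})
        table, _ = gv.overlap_analysis(at, genes, results)  # gene start exactly 500 kb away
        assert "GX" in table.index
        beyond = pd.DataFrame({"rsid": ["r"], "chrom": ["1"], "pos": [999_999], "maf": [0.2]})
        table2, _ = gv.overlap_analysis(beyond, genes, results)  # 500,001 bases: out
        assert "GX" not in table2.index

    def test_chromosome_mismatch_error(self):
        genes, leads, results = self.toy_inputs()
        bad = leads.assign(chrom=["7", "2", "1"])
        with pytest.raises(ValueError, match="chromosomes absent"):
            gv.overlap_analysis(bad, genes, results)


def test_round_sig():
    assert round_sig(0.0033333, 2) == 0.0033
    assert round_sig(3.1674e-6, 2) == 3.2e-6
    assert round_sig(0.0, 2) == 0.0
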