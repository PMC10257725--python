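"""Exome-wide (15-category) and gene-level burden scans of grip strength.

Simulates a PTV-rich cohort with one causal gene, runs the 15-category
exome-wide scan and the carrier-filtered gene scan with Bonferroni and FDR
correction, and prints the top associations.
"""

import gripvar as gv

spec = gv.SimSpec(
    n_samples=15_000,
    n_genes=150,
    seed=7,
    variants_per_gene=6.0,
    rare_maf_range=(2e-4, 9.9e-4),
    class_proportions={"ptv": 0.5, "missense": 0.3, "synonymous": 0.2},
    effect_table={"G00010": -2.5},
)
cohort = gv.simulate_cohort(spec)
design = gv.build_design(cohort.covariates)
hgs = cohort.phenotypes["hgs"]

exome = gv.run_exome_scan(cohort.genotypes, cohort.variants, cohort.genes, hgs, design)
print("15-category exome-wide scan (significance threshold "
      f"p < {exome.attrs['threshold']}):")
print(exome[["category", "stratum", "n_genes", "beta", "p", "significant"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))

bm = gv.gene_burden(cohort.genotypes, cohort.variants, "ptv", genes=cohort.genes)
bm, n_removed = gv.carrier_filter(bm, min_carriers=10)
genes = gv.run_gene_scan(bm, hgs, design, category="ptv")
top = genes.sort_values("p").head(3)
print(f"\ngene-level PTV scan: {genes.attrs['n_tested']} genes tested "
      f"({n_removed} dropped at <10 carriers), Bonferroni threshold "
      f"p < {genes.attrs['bonferroni_threshold']:.2g}")
print(top[["n_carriers", "beta", "se", "p", "q_bh", "sig_bonf"]]
      .to_string(float_format=lambda v: f"{v:.4g}"))
print("\nThe injected gene G00010 should top the scan with beta near -2.5 kg per "
      "rare allele; every other gene is null.")
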