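"""Polygenic score vs rare-carrier additivity on grip strength.

Splits a cohort into PRS-training and evaluation halves (all Mendelian-gene
PTV carriers plus matched non-carriers are held out), builds p-threshold PRS
weights from a training-set GWAS, scores the evaluation set, and fits the
additivity model:

    HGS ~ PRS_std + dom_carrier + rec_carrier + interactions + covariates
"""

import gripvar as gv

spec = gv.SimSpec(
    n_samples=12_000, n_genes=20, seed=21, variants_per_gene=8.0,
    rare_maf_range=(3e-4, 9.9e-4),
    class_proportions={"ptv": 1.0, "missense": 0.0, "synonymous": 0.0},
    ptv_high_confidence_frac=1.0,
    n_common_variants=300, polygenic_h2=0.4,
    effect_table={"G00001": -0.4, "G00002": -0.4},
)
cohort = gv.simulate_cohort(spec)
bm = gv.gene_burden(cohort.genotypes, cohort.variants, "ptv", genes=cohort.genes)

dominant_genes, recessive_genes = ["G00001", "G00002"], ["G00003", "G00004"]
mendelian = gv.carrier_status(bm, dominant_genes + recessive_genes)
train, evaluation = gv.holdout_split(cohort.samples, mendelian, seed=5)
print(f"training {len(train)} samples; evaluation {len(evaluation)} "
      f"({int(mendelian.sum())} carriers + matched non-carriers)")

design_train = gv.build_design(cohort.covariates.loc[train])
gwas = gv.single_variant_gwas(
    cohort.common_genotypes.loc[train], cohort.common_variants["maf"],
    cohort.phenotypes.loc[train, "hgs"], design_train,
)
weights = gv.build_weights(gwas, cohort.common_variants, p_threshold=0.05)
prs = gv.score(cohort.common_genotypes.loc[evaluation], weights, cohort.common_variants)
print(f"{len(weights)} weighted variants; per-chromosome partials sum to the total score")

fit = gv.fit_additivity(
    cohort.phenotypes.loc[evaluation, "hgs"],
    prs["total"],
    gv.carrier_status(bm, dominant_genes).loc[evaluation],
    gv.carrier_status(bm, recessive_genes).loc[evaluation],
    gv.build_design(cohort.covariates.loc[evaluation]),
)
print(fit.table.to_string(float_format=lambda v: f"{v:.4g}"))
print(f"additive (no interaction at alpha=0.05): {fit.additive}")
print("\nThe PRS coefficient is kg of grip strength per SD of polygenic score; "
      "dominant carriers (two -0.4 kg genes) sit below non-carriers, and with no "
      "injected interaction the PRS effect is the same in carriers and "
      "non-carriers — additive architecture.")
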