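"""Generate a synthetic exome cohort with a known injected gene effect.

Builds a 5,000-sample cohort with rare variants (MAF < 0.1%) across 200
genes, injects a -0.61 kg/allele protein-truncating burden effect into one
gene, and writes the cohort to disk as VCF + TSV tables.
"""

from pathlib import Path

import gripvar as gv

spec = gv.SimSpec(
    n_samples=5_000,
    n_genes=200,
    seed=42,
    variants_per_gene=8.0,
    class_proportions={"ptv": 0.4, "missense": 0.4, "synonymous": 0.2},
    effect_table={"G00001": -0.61},
    polygenic_h2=0.2,
)
cohort = gv.simulate_cohort(spec)

out = Path("scratch/example_cohort")
gv.write_cohort(cohort, out)

n_ptv = sum(1 for v in cohort.variants if gv.classify_variant(v) == "ptv")
bm = gv.gene_burden(cohort.genotypes, cohort.variants, "ptv", genes=cohort.genes)
carriers = int((bm.column("G00001") >= 1).sum()) if "G00001" in bm.units else 0

print(f"cohort: {len(cohort.samples)} samples, {len(cohort.variants)} rare variants, "
      f"{len(cohort.genes)} genes -> written to {out}/")
print(f"qualifying PTVs: {n_ptv}; carriers of the -0.61 kg gene G00001: {carriers}")
print(f"grip strength mean {cohort.phenotypes['hgs'].mean():.1f} kg, "
      f"SD {cohort.phenotypes['hgs'].std():.1f} kg")
print("Carriers of G00001 PTVs have grip strength lowered by 0.61 kg per rare allele "
      "before noise; downstream scans should recover that effect.")
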