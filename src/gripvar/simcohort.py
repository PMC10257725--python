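"""Synthetic cohort generator for rare-variant burden analyses of grip strength.

Generates genotypes, variant and gene annotations, covariates, grip-strength
phenotypes with known injected effects, binary PheWAS traits, and mouse
grip-strength tables, so that every downstream stage runs at desk scale with
a known ground truth.

Rare variants are simulated independently under Hardy-Weinberg equilibrium
(no LD); common variants optionally carry blockwise autoregressive LD via a
Gaussian copula on haplotypes.  Grip strength (kg) is a polynomial in age,
sex and height, plus injected per-gene burden effects, an optional polygenic
component from the common variants, and Gaussian noise; left- and right-hand
values are the latent value plus independent hand-specific jitter, so the
analysis maximum inherits the latent signal.  Site-frequency spectra,
demography and sequencing error are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import GeneAnnotation, VariantRecord, gene_burden

__all__ = [
    "SimSpec",
    "SimCohort",
    "simulate_cohort",
    "simulate_binary_traits",
    "simulate_mouse_cohort",
    "write_cohort",
    "write_vcf",
]

_PTV_CONSEQ = ("stop_gained", "splice_disruptive", "frameshift")

#: default variant-class mix, proportional to the study's qualifying-variant
#: counts (0.71M PTV : 6.68M missense : 3.88M synonymous)
DEFAULT_CLASS_PROPORTIONS = {"ptv": 0.063, "missense": 0.593, "synonymous": 0.344}

#: grip strength (kg) as a polynomial in age (centered at 55 y), sex (1=male)
#: and height (centered at 169 cm); chosen so means land near 40 kg for adult
#: males and 24 kg for females with decline after midlife
DEFAULT_COVARIATE_EFFECTS = {
    "intercept": 30.5,
    "age": -0.12,
    "age2": -0.003,
    "sex": 11.0,
    "age_sex": -0.05,
    "age2_sex": -0.001,
    "height": 0.25,
    "height2": 0.001,
    "height_sex": 0.05,
    "height2_sex": 0.0,
}

#: exclusion-flag rates, matching the source study's removal counts relative
#: to its 409,559 starting samples (COPD 2616, brachial plexus 50, arm injury
#: 7608, sex-chromosome aneuploidy 417)
DEFAULT_FLAG_RATES = {
    "copd": 0.0064,
    "brachial_plexus": 0.00012,
    "arm_injury": 0.0186,
    "sex_aneuploidy": 0.0012,
}


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")


@dataclass
class SimSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_samples: int
    n_genes: int
    seed: int
    variants_per_gene: float = 6.0  # Poisson mean, min 1 per gene
    rare_maf_range: tuple[float, float] = (5e-5, 9.9e-4)
    n_common_variants: int = 200
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    pli_mixture: float = 0.18  # fraction of genes with pLI >= 0.9
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    cadd_distribution: dict = field(
        default_factory=lambda: {"missense": (0.0, 40.0), "synonymous": (0.0, 10.0)}
    )
    ptv_high_confidence_frac: float = 0.9  # LOFTEE high-confidence share of PTV-eligible
    effect_table: dict = field(default_factory=dict)  # gene -> kg per qualifying allele
    effect_class: str = "ptv"  # variant class the injected effects act through
    polygenic_h2: float = 0.0  # share of non-covariate variance from common variants
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    noise_sd: float = 5.0  # kg
    hand_jitter_frac: float = 0.05  # hand jitter SD as a fraction of phenotype SD
    missing_rate: float = 0.0
    prevalence_table: dict = field(default_factory=dict)
    flag_rates: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_RATES))
    x_gene_fraction: float = 0.0
    ld_rho: float = 0.0  # AR(1) haplotype correlation within common-variant blocks
    ld_block_size: int = 20

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        lo, hi = self.rare_maf_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"rare_maf_range must satisfy 0 < lo <= hi, got {self.rare_maf_range}")
        if hi >= 1e-3:
            raise ValueError(f"rare_maf_range upper bound must be < 0.001 (rare), got {hi}")
        clo, chi = self.common_maf_range
        if not (clo <= chi <= 0.5):
            raise ValueError(f"common_maf_range must satisfy lo <= hi <= 0.5, got {self.common_maf_range}")
        if clo <= 0.01:
            raise ValueError(f"common_maf_range lower bound must be > 0.01, got {clo}")
        _check_fraction("pli_mixture", self.pli_mixture)
        _check_fraction("polygenic_h2", self.polygenic_h2)
        _check_fraction("hand_jitter_frac", self.hand_jitter_frac)
        _check_fraction("missing_rate", self.missing_rate)
        _check_fraction("x_gene_fraction", self.x_gene_fraction)
        _check_fraction("ptv_high_confidence_frac", self.ptv_high_confidence_frac)
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        for cls, p in self.class_proportions.items():
            if cls not in ("ptv", "missense", "synonymous"):
                raise ValueError(f"class_proportions has unknown class {cls!r}")
            _check_fraction(f"class_proportions[{cls}]", p)
        for trait, prev in self.prevalence_table.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence_table[{trait}] must be in (0, 1), got {prev}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.effect_class not in ("ptv", "missense_gt30", "missense_20_30", "missense_0_20", "synonymous"):
            raise ValueError(f"effect_class {self.effect_class!r} is not a variant class")


@dataclass
class SimCohort:
    """A generated cohort with its ground truth."""

    genotypes: pd.DataFrame  # samples x rare variants, int8 dosage; -1 = missing
    variants: list  # list[VariantRecord]
    genes: dict  # gene id -> GeneAnnotation
    common_genotypes: pd.DataFrame  # samples x common variants, int8
    common_variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt, maf
    phenotypes: pd.DataFrame  # covariates, flags, hgs_left/right, hgs
    truth: dict
    spec: SimSpec

    @property
    def samples(self) -> pd.Index:
        return self.phenotypes.index

    @property
    def covariates(self) -> pd.DataFrame:
        cols = ["age", "sex", "height"] + [f"pc{i}" for i in range(1, 21)]
        return self.phenotypes[cols]


def _simulate_genes(spec: SimSpec, rng: np.random.Generator) -> dict[str, GeneAnnotation]:
    n = spec.n_genes
    ids = [f"G{i:05d}" for i in range(1, n + 1)]
    intolerant = rng.random(n) < spec.pli_mixture
    pli = np.where(intolerant, rng.uniform(0.9, 1.0, n), rng.uniform(0.0, 0.9, n))
    n_x = int(round(spec.x_gene_fraction * n))
    chroms = [str(c) for c in (np.arange(n - n_x) % 22 + 1)] + ["X"] * n_x
    genes = {}
    per_chrom_counter: dict[str, int] = {}
    for gid, chrom, p in zip(ids, chroms, pli):
        k = per_chrom_counter.get(chrom, 0)
        per_chrom_counter[chrom] = k + 1
        start = 1_000_000 + k * 1_000_000
        length = int(rng.integers(5_000, 200_000))
        genes[gid] = GeneAnnotation(
            gene=gid, chrom=chrom, start=start, end=start + length, pli=float(p),
            chromosome_class="X" if chrom == "X" else "autosome",
        )
    return genes


def _simulate_variants(
    spec: SimSpec, genes: dict[str, GeneAnnotation], rng: np.random.Generator
) -> list[VariantRecord]:
    classes = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes])
    bases = np.array(["A", "C", "G", "T"])
    variants: list[VariantRecord] = []
    log_lo, log_hi = np.log(spec.rare_maf_range[0]), np.log(spec.rare_maf_range[1])
    for gid, g in genes.items():
        k = max(1, int(rng.poisson(spec.variants_per_gene)))
        pos = np.sort(rng.integers(g.start, g.end + 1, size=k))
        mafs = np.exp(rng.uniform(log_lo, log_hi, size=k))  # log-uniform over the rare range
        cls = rng.choice(classes, size=k, p=probs)
        for j in range(k):
            ref, alt = rng.choice(bases, size=2, replace=False)
            if cls[j] == "ptv":
                conseq = _PTV_CONSEQ[rng.integers(0, 3)]
                loftee = (
                    "high_confidence"
                    if rng.random() < spec.ptv_high_confidence_frac
                    else "low_confidence"
                )
                cadd = None
            else:
                conseq = cls[j]
                loftee = "not_applicable"
                lo, hi = spec.cadd_distribution.get(cls[j], (0.0, 40.0))
                cadd = float(rng.uniform(lo, hi))
            variants.append(
                VariantRecord(
                    chrom=g.chrom, pos=int(pos[j]), ref=str(ref), alt=str(alt),
                    maf=float(mafs[j]), consequence=str(conseq), loftee=loftee,
                    cadd=cadd, gene=gid, variant_id=f"v{len(variants):06d}",
                )
            )
    return variants


def _hwe_dosages(
    mafs: np.ndarray, n_samples: int, rng: np.random.Generator, male: np.ndarray | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """Independent Hardy-Weinberg dosages, int8, generated in column chunks.

    When ``male`` is given the variants are X-chromosomal: males are haploid
    and coded 0/1.
    """
    m = len(mafs)
    out = np.empty((n_samples, m), dtype=np.int8)
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        block = rng.binomial(2, mafs[j0:j1], size=(n_samples, j1 - j0)).astype(np.int8)
        if male is not None:
            hap = rng.binomial(1, mafs[j0:j1], size=(n_samples, j1 - j0)).astype(np.int8)
            block[male, :] = hap[male, :]
        out[:, j0:j1] = block
    return out


def _ld_common_dosages(
    mafs: np.ndarray, n_samples: int, rho: float, block_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Common-variant dosages with AR(1) haplotype LD via a Gaussian copula."""
    m = len(mafs)
    thresh = _norm_ppf(mafs)
    out = np.zeros((n_samples, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n_samples, m))
        for b0 in range(0, m, block_size):
            b1 = min(b0 + block_size, m)
            z[:, b0] = rng.standard_normal(n_samples)
            for j in range(b0 + 1, b1):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_samples)
        out += (z < thresh).astype(np.int8)
    return out


def _norm_ppf(p: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(p)


def _simulate_covariates(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    idx = pd.Index([f"S{i:06d}" for i in range(1, n + 1)], name="sample")
    sex = rng.integers(0, 2, n)  # 1 = male
    age = rng.uniform(40, 70, n)
    height = np.where(sex == 1, rng.normal(175.6, 6.9, n), rng.normal(162.5, 6.2, n))
    weight = np.clip(np.where(sex == 1, rng.normal(85, 14, n), rng.normal(72, 14, n)), 1.0, None)
    df = pd.DataFrame({"age": age, "sex": sex, "height": height, "weight": weight}, index=idx)
    pcs = rng.standard_normal((n, 20))
    for i in range(20):
        df[f"pc{i+1}"] = pcs[:, i]
    for flag, rate in spec.flag_rates.items():
        df[flag] = (rng.random(n) < rate).astype(int)
    return df


def _covariate_part(cov: pd.DataFrame, effects: dict) -> np.ndarray:
    a = cov["age"].to_numpy() - 55.0
    s = cov["sex"].to_numpy().astype(float)
    h = cov["height"].to_numpy() - 169.0
    e = {k: effects.get(k, 0.0) for k in DEFAULT_COVARIATE_EFFECTS}
    return (
        e["intercept"]
        + e["age"] * a + e["age2"] * a**2 + e["sex"] * s
        + e["age_sex"] * a * s + e["age2_sex"] * a**2 * s
        + e["height"] * h + e["height2"] * h**2
        + e["height_sex"] * h * s + e["height2_sex"] * h**2 * s
    )


def simulate_cohort(spec: SimSpec) -> SimCohort:
    """Generate a full synthetic cohort from a validated :class:`SimSpec`.

    Reproducible given the seed.  Grip strength is built as covariate
    polynomial + sum_g effect_g x burden_g + polygenic component + Gaussian
    noise; both hands are the latent value plus independent jitter so their
    maximum tracks the latent phenotype.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = _simulate_genes(spec, rng)
    variants = _simulate_variants(spec, genes, rng)
    unknown_effects = sorted(set(spec.effect_table) - set(genes))
    if unknown_effects:
        raise ValueError(f"effect_table names genes not in the cohort: {unknown_effects}")

    cov = _simulate_covariates(spec, rng)
    male = (cov["sex"].to_numpy() == 1)

    mafs = np.array([v.maf for v in variants])
    is_x = np.array([v.chrom == "X" for v in variants])
    geno = _hwe_dosages(mafs, spec.n_samples, rng)
    if is_x.any():
        geno[:, is_x] = _hwe_dosages(mafs[is_x], spec.n_samples, rng, male=male)
    geno_df = pd.DataFrame(geno, index=cov.index, columns=[v.variant_id for v in variants])

    # common variants on chromosomes 1..22 for PRS / LOCO offsets
    m_c = spec.n_common_variants
    c_mafs = rng.uniform(*spec.common_maf_range, m_c)
    c_chroms = (np.arange(m_c) % 22 + 1).astype(str)
    if spec.ld_rho > 0:
        c_geno = _ld_common_dosages(c_mafs, spec.n_samples, spec.ld_rho, spec.ld_block_size, rng)
    else:
        c_geno = _hwe_dosages(c_mafs, spec.n_samples, rng)
    c_ids = [f"rs{100000 + i}" for i in range(m_c)]
    common_variants = pd.DataFrame(
        {
            "variant_id": c_ids,
            "chrom": c_chroms,
            "pos": 500_000 + 10_000 * np.arange(m_c),
            "ref": "A",
            "alt": "G",
            "maf": c_mafs,
        }
    ).set_index("variant_id")
    c_geno_df = pd.DataFrame(c_geno, index=cov.index, columns=c_ids)

    # phenotype assembly
    cov_part = _covariate_part(cov, spec.covariate_effects)
    burden_part = np.zeros(spec.n_samples)
    effect_burdens = {}
    if spec.effect_table:
        import warnings

        bm = gene_burden(geno_df, variants, spec.effect_class, genes=genes)
        for gid, eff in spec.effect_table.items():
            if gid in bm.units:
                col = bm.column(gid).to_numpy()
                burden_part += eff * col
                effect_burdens[gid] = col
            else:
                warnings.warn(
                    f"effect_table gene {gid} has no qualifying {spec.effect_class} "
                    "variants in this cohort; its effect is inert"
                )

    poly_part = np.zeros(spec.n_samples)
    poly_weights = np.zeros(m_c)
    if spec.polygenic_h2 > 0:
        w = rng.standard_normal(m_c)
        g_std = (c_geno.astype(float) - 2 * c_mafs) / np.sqrt(2 * c_mafs * (1 - c_mafs))
        raw = g_std @ w
        target_var = spec.polygenic_h2 / (1 - spec.polygenic_h2) * spec.noise_sd**2
        scale = np.sqrt(target_var) / max(raw.std(), 1e-12)
        poly_part = raw * scale
        poly_weights = w * scale

    noise = rng.normal(0.0, spec.noise_sd, spec.n_samples)
    latent = cov_part + burden_part + poly_part + noise
    jitter_sd = spec.hand_jitter_frac * max(latent.std(), 1e-12)
    left = np.clip(latent + rng.normal(0, jitter_sd, spec.n_samples), 0, None)
    right = np.clip(latent + rng.normal(0, jitter_sd, spec.n_samples), 0, None)

    pheno = cov.copy()
    pheno["hgs_left"] = left
    pheno["hgs_right"] = right
    pheno["hgs"] = np.maximum(left, right)

    if spec.missing_rate > 0:
        mask = rng.random(geno_df.shape) < spec.missing_rate
        arr = geno_df.to_numpy()
        arr[mask] = -1
        geno_df = pd.DataFrame(arr, index=geno_df.index, columns=geno_df.columns)

    truth = {
        "effect_table": dict(spec.effect_table),
        "effect_burdens": effect_burdens,
        "polygenic_component": poly_part,
        "polygenic_weights_std": poly_weights,
        "covariate_part": cov_part,
        "latent": latent,
        "noise_sd": spec.noise_sd,
    }
    return SimCohort(
        genotypes=geno_df, variants=variants, genes=genes,
        common_genotypes=c_geno_df, common_variants=common_variants,
        phenotypes=pheno, truth=truth, spec=spec,
    )


def simulate_binary_traits(
    cohort: SimCohort,
    prevalence_table: dict[str, float],
    linked: dict[str, tuple[str, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binary traits with given prevalences; optionally genotype-linked.

    ``linked`` maps a trait name to ``(gene, log_odds)``: carriers of a
    qualifying allele in that gene get the stated log-odds added on top of the
    baseline logit, producing enrichment of cases among carriers.
    """
    for trait, prev in prevalence_table.items():
        if not 0.0 < prev < 1.0:
            raise ValueError(f"prevalence for {trait!r} must be in (0, 1), got {prev}")
    rng = np.random.default_rng(cohort.spec.seed + 104729 if seed is None else seed)
    n = len(cohort.samples)
    out = {}
    linked = linked or {}
    for trait, prev in prevalence_table.items():
        logit = np.full(n, np.log(prev / (1 - prev)))
        if trait in linked:
            gene, log_or = linked[trait]
            bm = gene_burden(cohort.genotypes, cohort.variants, cohort.spec.effect_class,
                             genes=cohort.genes)
            if gene not in bm.units:
                raise KeyError(f"linked gene {gene} has no qualifying variants")
            carrier = (bm.column(gene).to_numpy() >= 1).astype(float)
            logit = logit + log_or * carrier
        p = 1.0 / (1.0 + np.exp(-logit))
        out[trait] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(out, index=cohort.samples)


def simulate_mouse_cohort(
    n_per_genotype: tuple[int, int, int] = (24, 18, 13),
    cohort_effects: tuple[float, ...] = (0.0, 8.0),
    genotype_effects: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    baseline: float = 120.0,
    animal_sd: float = 10.0,
    trial_sd: float = 6.0,
    femur_mean: float = 15.5,
    femur_sd: float = 0.4,
) -> pd.DataFrame:
    """Mouse forelimb grip-strength table: 3 trials per animal plus femur length.

    ``n_per_genotype`` gives the WT/HET/HOM counts (default 24/18/13, the
    study's 55 animals in two cohorts); ``genotype_effects`` are the (HET,
    HOM) shifts in grams of peak pull force — a negative, increasing-magnitude
    pair produces the dose-ordered WT > HET > HOM pattern.  Animals are split
    across ``len(cohort_effects)`` cohorts with the stated additive shifts.
    """
    if any(n < 1 for n in n_per_genotype):
        raise ValueError(f"n_per_genotype must all be >= 1, got {n_per_genotype}")
    if len(cohort_effects) < 2:
        raise ValueError("at least 2 cohorts are required")
    rng = np.random.default_rng(seed)
    shifts = {"WT": 0.0, "HET": genotype_effects[0], "HOM": genotype_effects[1]}
    rows = []
    i = 0
    for gt, n in zip(("WT", "HET", "HOM"), n_per_genotype):
        for _ in range(n):
            cohort_ix = i % len(cohort_effects)
            mu = baseline + shifts[gt] + cohort_effects[cohort_ix] + rng.normal(0, animal_sd)
            trials = np.clip(mu + rng.normal(0, trial_sd, 3), 1.0, None)
            femur = max(rng.normal(femur_mean, femur_sd), 0.1)
            rows.append(
                {
                    "animal": f"M{i:03d}", "genotype": gt, "cohort": f"C{cohort_ix + 1}",
                    "trial1": trials[0], "trial2": trials[1], "trial3": trials[2],
                    "femur": femur,
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("animal")


# ---------------------------------------------------------------------------
# writers (plain-text formats)


def write_vcf(genotypes: pd.DataFrame, variants: list[VariantRecord], path) -> None:
    """Write biallelic GT dosages as a VCFv4.2 text file (one column per sample)."""
    samples = list(genotypes.index)
    chrom_order = {}
    for v in variants:
        chrom_order.setdefault(v.chrom, len(chrom_order))
    recs = sorted(variants, key=lambda v: (chrom_order[v.chrom], v.pos))
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in recs:
            dos = genotypes[v.variant_id].to_numpy()
            cells = "\t".join(gt_codes[int(d)] for d in dos)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{cells}\n")


def write_annotations(variants: list[VariantRecord], path) -> None:
    df = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "gene": [v.gene for v in variants],
            "consequence": [v.consequence for v in variants],
            "loftee": [v.loftee for v in variants],
            "cadd": [v.cadd if v.cadd is not None else np.nan for v in variants],
            "maf": [v.maf for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_genes(genes: dict[str, GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "gene": list(genes),
            "chrom": [g.chrom for g in genes.values()],
            "start": [g.start for g in genes.values()],
            "end": [g.end for g in genes.values()],
            "pli": [g.pli for g in genes.values()],
            "chromosome_class": [g.chromosome_class for g in genes.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: SimCohort, outdir) -> None:
    """Write the cohort as VCF + TSVs (dosages, annotations, genes, phenotypes)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort.genotypes, cohort.variants, outdir / "rare.vcf")
    dos = cohort.genotypes.astype(float).replace(-1, np.nan)
    dos.to_csv(outdir / "rare_dosages.tsv", sep="\t")
    write_annotations(cohort.variants, outdir / "annotations.tsv")
    write_genes(cohort.genes, outdir / "genes.tsv")
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
    cohort.common_genotypes.to_csv(outdir / "common_dosages.tsv", sep="\t")
    cohort.common_variants.to_csv(outdir / "common_variants.tsv", sep="\t")
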