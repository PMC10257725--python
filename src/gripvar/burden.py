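"""Qualifying-variant classification and rare-allele burden construction.

Rare coding variants (MAF < 0.1%) are classified into five functional
categories — protein-truncating (PTV), three missense tiers split on CADD
phred score, and synonymous — and aggregated per sample into gene-level,
gene-set, or exome-wide allele-count burdens.  Genes are stratified by pLI
into loss-of-function intolerant (pLI >= 0.9) and tolerant (pLI < 0.9) sets;
the five classes crossed with {intolerant, tolerant, all} give the fifteen
exome-wide burden categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: consequences eligible for PTV status (before the LOFTEE confidence filter)
PTV_CONSEQUENCES = frozenset({"stop_gained", "splice_disruptive", "frameshift"})

#: the five qualifying-variant classes
VARIANT_CLASSES = ("ptv", "missense_gt30", "missense_20_30", "missense_0_20", "synonymous")

#: pLI strata; crossed with VARIANT_CLASSES these yield the 15 exome-wide categories
STRATA = ("all", "pli_ge_0.9", "pli_lt_0.9")

#: qualifying-variant MAF ceiling ("rare" means MAF < 0.1%)
RARE_MAF_THRESHOLD = 1e-3

_LOFTEE_ALIASES = {
    "HC": "high_confidence",
    "LC": "low_confidence",
    "high_confidence": "high_confidence",
    "low_confidence": "low_confidence",
    "not_applicable": "not_applicable",
    "NA": "not_applicable",
    "": "not_applicable",
}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic variant on its canonical transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    consequence: str
    loftee: str
    cadd: float | None
    gene: str
    variant_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf} at {self.chrom}:{self.pos}")
        if not self.variant_id:
            object.__setattr__(self, "variant_id", f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}")
        loftee = _LOFTEE_ALIASES.get(self.loftee)
        if loftee is None:
            raise ValueError(f"unknown LOFTEE label {self.loftee!r}")
        object.__setattr__(self, "loftee", loftee)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates and loss-of-function intolerance (pLI)."""

    gene: str
    chrom: str
    start: int
    end: int
    pli: float | None
    chromosome_class: str = "autosome"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start {self.start} > end {self.end}")
        if self.pli is not None and not np.isnan(self.pli) and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"gene {self.gene}: pli {self.pli} outside [0, 1]")
        if self.chromosome_class not in ("autosome", "X"):
            raise ValueError(f"gene {self.gene}: chromosome_class must be 'autosome' or 'X'")


class BurdenMatrix:
    """Sample x unit matrix of non-negative integer rare-allele counts.

    Units are genes, gene-set names, or a single exome-wide column.  Backed by
    a pandas DataFrame (``.counts``) with sample ids on the index.
    """

    def __init__(self, counts: pd.DataFrame):
        arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("burden counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def units(self) -> pd.Index:
        return self.counts.columns

    def carriers(self) -> pd.Series:
        """Number of samples with at least one qualifying rare allele, per unit."""
        return (self.counts >= 1).sum(axis=0)

    def column(self, unit: str) -> pd.Series:
        return self.counts[unit]

    def __repr__(self) -> str:
        return f"BurdenMatrix({self.counts.shape[0]} samples x {self.counts.shape[1]} units)"


def classify_variant(v: VariantRecord, maf_threshold: float = RARE_MAF_THRESHOLD) -> str | None:
    """Assign a variant to one of the five qualifying classes, or exclude it.

    Rules:

    * MAF >= ``maf_threshold`` (default 0.1%): not rare, excluded.
    * PTV iff consequence is stop-gained / splice-disruptive / frameshift AND
      LOFTEE calls it high-confidence; low-confidence calls are excluded.
    * Missense binned literally on CADD phred: > 30, (20, 30], (0, 20].
      A missense with CADD exactly 30 therefore lands in the (20, 30] bin,
      and CADD <= 0 qualifies for no bin (excluded).
    * Synonymous passes through; every other consequence is excluded.

    Returns the class name or ``None`` for excluded variants.  A missense
    variant with a missing CADD score raises rather than silently binning.
    """
    if v.maf >= maf_threshold:
        return None
    if v.consequence in PTV_CONSEQUENCES:
        return "ptv" if v.loftee == "high_confidence" else None
    if v.consequence == "missense":
        if v.cadd is None or (isinstance(v.cadd, float) and np.isnan(v.cadd)):
            raise ValueError(f"missense variant {v.variant_id} has no CADD score; cannot bin")
        if v.cadd > 30:
            return "missense_gt30"
        if v.cadd > 20:
            return "missense_20_30"
        if v.cadd > 0:
            return "missense_0_20"
        return None
    if v.consequence == "synonymous":
        return "synonymous"
    return None


def assign_stratum(g: GeneAnnotation) -> str | None:
    """pLI >= 0.9 -> ``pli_ge_0.9`` (LoF intolerant); else ``pli_lt_0.9``.

    Genes with missing pLI cannot be stratified and return ``None`` with a
    warning; callers report how many were excluded.
    """
    if g.pli is None or np.isnan(g.pli):
        warnings.warn(f"gene {g.gene} has missing pLI; excluded from stratification")
        return None
    return "pli_ge_0.9" if g.pli >= 0.9 else "pli_lt_0.9"


def _qualifying_mask(
    variants: list[VariantRecord],
    vclass: str,
    genes: dict[str, GeneAnnotation] | None,
    stratum: str,
    maf_threshold: float,
) -> list[VariantRecord]:
    if vclass not in VARIANT_CLASSES:
        raise ValueError(f"unknown variant class {vclass!r}; expected one of {VARIANT_CLASSES}")
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    kept = []
    for v in variants:
        if classify_variant(v, maf_threshold) != vclass:
            continue
        if stratum != "all":
            if genes is None:
                raise ValueError("gene annotations required for pLI-stratified burden")
            g = genes.get(v.gene)
            if g is None:
                raise KeyError(f"variant {v.variant_id} references unknown gene {v.gene}")
            if assign_stratum(g) != stratum:
                continue
        kept.append(v)
    return kept


def gene_burden(
    genotypes: pd.DataFrame,
    variants: list[VariantRecord],
    vclass: str,
    genes: dict[str, GeneAnnotation] | None = None,
    stratum: str = "all",
    maf_threshold: float = RARE_MAF_THRESHOLD,
    carrier_indicator: bool = False,
) -> BurdenMatrix:
    """Aggregate qualifying rare alleles of one class into per-gene burdens.

    ``genotypes`` holds alt-allele dosages (0/1/2; negative or NaN = missing)
    with samples on the index and variant ids on the columns.  Rare alleles of
    the same category on each gene are summed; missing dosages contribute 0.
    With ``carrier_indicator`` the per-gene burden is clipped to 0/1.
    """
    unknown = sorted({v.gene for v in variants if genes is not None and v.gene not in genes})
    if unknown:
        raise KeyError(f"variants reference unknown genes: {', '.join(unknown)}")
    qualifying = _qualifying_mask(variants, vclass, genes, stratum, maf_threshold)
    by_gene: dict[str, list[str]] = {}
    for v in qualifying:
        by_gene.setdefault(v.gene, []).append(v.variant_id)

    out = {}
    for gene_id, vids in by_gene.items():
        present = [vid for vid in vids if vid in genotypes.columns]
        if len(present) < len(vids):
            missing = set(vids) - set(present)
            raise KeyError(f"variants absent from genotype matrix: {sorted(missing)}")
        dos = genotypes[present].to_numpy(dtype=np.float64)
        dos = np.where(np.isnan(dos) | (dos < 0), 0.0, dos)  # missing -> 0
        out[gene_id] = dos.sum(axis=1).astype(np.int64)
    counts = pd.DataFrame(out, index=genotypes.index)
    if carrier_indicator:
        counts = (counts >= 1).astype(np.int64)
    return BurdenMatrix(counts)


def set_burden(burden: BurdenMatrix, gene_set: list[str]) -> pd.Series:
    """Per-sample burden of a gene set: the exact column sum over member genes.

    The exome-wide burden is the special case where ``gene_set`` is every gene
    in the stratum.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in burden.units]
    if missing:
        raise KeyError(f"gene set members absent from burden matrix: {missing}")
    return burden.counts[list(gene_set)].sum(axis=1)


def exome_burden(burden: BurdenMatrix) -> pd.Series:
    """Whole-exome burden: sum over every gene column."""
    return set_burden(burden, list(burden.units))


def carrier_filter(burden: BurdenMatrix, min_carriers: int = 10) -> tuple[BurdenMatrix, int]:
    """Drop units carried by fewer than ``min_carriers`` samples.

    A carrier is a sample with burden >= 1.  "Fewer than 10 carriers" is read
    literally: a unit with exactly 10 carriers is retained.  Returns the
    filtered matrix and the number of units removed.
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    carriers = burden.carriers()
    keep = carriers[carriers >= min_carriers].index
    n_removed = burden.counts.shape[1] - len(keep)
    if n_removed:
        logger.info("carrier_filter: removed %d units with < %d carriers", n_removed, min_carriers)
    return BurdenMatrix(burden.counts[keep]), n_removed


# ---------------------------------------------------------------------------
# readers


def read_annotations(path) -> list[VariantRecord]:
    """Read a variant annotation TSV (chrom, pos, ref, alt, gene, class, loftee, cadd, maf)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        cadd = getattr(row, "cadd", None)
        records.append(
            VariantRecord(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
                maf=float(row.maf), consequence=getattr(row, "consequence", getattr(row, "_5", None)),
                loftee=row.loftee if isinstance(row.loftee, str) else "not_applicable",
                cadd=None if cadd is None or (isinstance(cadd, float) and np.isnan(cadd)) else float(cadd),
                gene=row.gene,
            )
        )
    return records


def read_gene_table(path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV (gene, chrom, start, end, pli, chromosome_class)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        pli = float(row.pli) if not pd.isna(row.pli) else None
        out[row.gene] = GeneAnnotation(
            gene=row.gene, chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            pli=pli, chromosome_class=getattr(row, "chromosome_class", "autosome"),
        )
    return out


def read_vcf(path) -> pd.DataFrame:
    """Read biallelic GT dosages from a VCF into a samples x variants DataFrame.

    Multi-allelic records must be pre-split; an unsplit record is rejected with
    a message naming the site.  Missing genotypes are coded -1.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        cols: dict[str, np.ndarray] = {}
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split to biallelic first"
                )
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            dos = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    dos[i] = -1
                else:
                    dos[i] = sum(1 for a in gt if a == 1)
            cols[vid] = dos
    return pd.DataFrame(cols, index=pd.Index(samples, name="sample"))


def read_dosage_tsv(path) -> pd.DataFrame:
    """Read a dosage TSV (samples on rows, variant ids on columns; NA = missing -> -1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.fillna(-1).astype(np.int8)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: set name, description, then member gene ids."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
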