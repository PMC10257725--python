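"""Polygenic score construction, carrier stratification, and the additivity model.

The additivity model asks whether common-variant polygenic background and
rare protein-truncating variants act additively on grip strength:

    HGS ~ PRS_std + PTV_carrier_dom + PTV_carrier_rec
          + PRS_std x PTV_carrier_dom + PRS_std x PTV_carrier_rec  (+ covariates)

fit on a held-out evaluation set (all carriers of PTVs in Mendelian
neuromuscular disease genes plus an equal number of random non-carriers);
PRS weights are built on the remaining training samples only.  Additivity
holds when the interaction terms are null.

Posterior-shrinkage weighting (PRS-CS-style) is out of scope: weights come
from p-value thresholding of the training GWAS, and externally produced
weight files can be dropped in unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import BurdenMatrix
from .assoc import _ols_t

logger = logging.getLogger(__name__)


@dataclass
class AdditivityFit:
    """Coefficients of the additivity model with an interaction-based verdict."""

    table: pd.DataFrame  # term -> beta, se, p
    n: int
    n_dom_carriers: int
    n_rec_carriers: int
    dropped_terms: list
    additive: bool  # True when no interaction p falls below alpha

    @property
    def interaction_p(self) -> dict:
        return {
            t: float(self.table.loc[t, "p"])
            for t in ("prs_x_dom", "prs_x_rec")
            if t in self.table.index
        }


def carrier_status(burden: BurdenMatrix, gene_list: list[str]) -> pd.Series:
    """Carrier indicator: burden >= 1 in any listed gene (missing genes ignored)."""
    present = [g for g in gene_list if g in burden.units]
    if not present:
        return pd.Series(False, index=burden.samples)
    return burden.counts[present].sum(axis=1) >= 1


def holdout_split(
    sample_ids: pd.Index, carrier: pd.Series, seed: int
) -> tuple[pd.Index, pd.Index]:
    """Split samples into PRS-training and additivity-evaluation sets.

    The evaluation set is every carrier of a qualifying PTV in the Mendelian
    gene list plus an equal-size random draw of non-carriers; the training
    set is everyone else.  Deterministic given the seed; the two sets are
    disjoint by construction.
    """
    carrier = carrier.loc[sample_ids]
    carriers = sample_ids[carrier]
    non_carriers = sample_ids[~carrier]
    if len(non_carriers) < len(carriers):
        raise ValueError(
            f"cannot match {len(carriers)} carriers: only {len(non_carriers)} non-carriers"
        )
    rng = np.random.default_rng(seed)
    matched = pd.Index(rng.choice(non_carriers, size=len(carriers), replace=False))
    eval_ids = carriers.append(matched)
    train_ids = sample_ids.difference(eval_ids, sort=False)
    return train_ids, eval_ids


def build_weights(
    gwas_summary: pd.DataFrame,
    variant_info: pd.DataFrame,
    p_threshold: float,
) -> pd.DataFrame:
    """P-value-threshold PRS weights from training GWAS summary statistics.

    Keeps variants with p < ``p_threshold``; the weight is the GWAS beta (kg
    per effect allele) and the effect allele is the GWAS dosage allele (alt).
    ``variant_info`` supplies chrom/ref/alt per variant id.
    """
    sel = gwas_summary[gwas_summary["p"] < p_threshold]
    if sel.empty:
        raise ValueError(
            f"no variants pass p < {p_threshold}; smallest p is {gwas_summary['p'].min():.3g} "
            "— try a larger threshold"
        )
    info = variant_info.loc[sel.index]
    return pd.DataFrame(
        {
            "chrom": info["chrom"].astype(str),
            "effect_allele": info["alt"],
            "weight": sel["beta"],
        },
        index=sel.index,
    )


def score(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    variant_info: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample PRS: weighted sum of effect-allele dosages, by chromosome.

    Per-chromosome partial scores are retained in the output and the
    ``total`` column is their exact sum (chromosomes 1-22 convention).  When
    the weight's effect allele is the *reference* allele the dosage is
    reflected (2 - d).  Weighted variants absent from the genotype matrix are
    skipped and counted in ``.attrs['n_skipped']``.
    """
    present = weights.index.intersection(genotypes.columns)
    n_skipped = len(weights) - len(present)
    if n_skipped:
        logger.info("score: %d weighted variants absent from genotypes; skipped", n_skipped)
    partials: dict[str, np.ndarray] = {}
    for vid in present:
        w = float(weights.loc[vid, "weight"])
        eff = weights.loc[vid, "effect_allele"]
        info = variant_info.loc[vid]
        d = genotypes[vid].to_numpy(dtype=float)
        if eff == info["alt"]:
            pass
        elif eff == info["ref"]:
            d = 2.0 - d
        else:
            raise ValueError(f"effect allele {eff!r} matches neither allele of {vid}")
        chrom = str(weights.loc[vid, "chrom"])
        partials[chrom] = partials.get(chrom, np.zeros(len(genotypes))) + w * d
    out = pd.DataFrame(partials, index=genotypes.index)
    out = out.reindex(sorted(out.columns, key=lambda c: (len(c), c)), axis=1)
    out["total"] = out.sum(axis=1)
    out.attrs["n_skipped"] = n_skipped
    return out


def standardize(prs: pd.Series) -> pd.Series:
    """Mean-0, SD-1 standardization on the analysis sample."""
    sd = prs.std(ddof=0)
    if sd == 0:
        raise ValueError("PRS has zero variance; cannot standardize")
    return (prs - prs.mean()) / sd


def fit_additivity(
    hgs: pd.Series,
    prs: pd.Series,
    dom_carrier: pd.Series,
    rec_carrier: pd.Series,
    design: pd.DataFrame,
    alpha: float = 0.05,
) -> AdditivityFit:
    """Fit the additivity model on the evaluation set.

    The PRS is standardized within the fitted sample, so the PRS coefficient
    reads as kg per SD of polygenic score.  Carrier categories without any
    carriers are dropped (with their interaction) and reported.  The verdict
    ``additive`` is True when every retained interaction p exceeds ``alpha``.
    """
    prs_std = standardize(prs)
    dom = dom_carrier.astype(float)
    rec = rec_carrier.astype(float)
    terms: dict[str, pd.Series] = {"prs_std": prs_std}
    dropped = []
    if dom.sum() > 0:
        terms["dom_carrier"] = dom
        terms["prs_x_dom"] = prs_std * dom
    else:
        dropped += ["dom_carrier", "prs_x_dom"]
    if rec.sum() > 0:
        terms["rec_carrier"] = rec
        terms["prs_x_rec"] = prs_std * rec
    else:
        dropped += ["rec_carrier", "prs_x_rec"]
    if dropped:
        logger.warning("fit_additivity: no carriers for %s; terms dropped", dropped)

    names = list(design.columns) + list(terms)
    X = np.column_stack([design.to_numpy(dtype=float)] + [t.to_numpy(dtype=float) for t in terms.values()])
    beta, se, p, _ = _ols_t(X, hgs.to_numpy(dtype=float))
    table = pd.DataFrame({"beta": beta, "se": se, "p": p}, index=pd.Index(names, name="term"))
    table = table.loc[list(terms)]
    inter = [t for t in ("prs_x_dom", "prs_x_rec") if t in table.index]
    additive = bool(all(table.loc[t, "p"] > alpha for t in inter))
    return AdditivityFit(
        table=table, n=len(hgs),
        n_dom_carriers=int(dom.sum()), n_rec_carriers=int(rec.sum()),
        dropped_terms=dropped, additive=additive,
    )


def read_gene_inheritance(path) -> tuple[list[str], list[str]]:
    """Read a gene-list TSV (gene, inheritance in {dominant, recessive})."""
    df = pd.read_csv(path, sep="\t")
    dom = df.loc[df["inheritance"].str.lower().str.startswith("dom"), "gene"].tolist()
    rec = df.loc[df["inheritance"].str.lower().str.startswith("rec"), "gene"].tolist()
    return dom, rec


def read_weights(path) -> pd.DataFrame:
    """Read a PRS weight TSV (variant_id/rsid, chrom, effect_allele, weight)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    id_col = "variant_id" if "variant_id" in df.columns else "rsid"
    return df.set_index(id_col)[["chrom", "effect_allele", "weight"]]
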