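"""Selection of candidate protein-changing variants (PCVs).

A PCV is a biallelic variant that (1) has a HIGH or MODERATE predicted
impact on the encoded protein (or creates an upstream ORF), (2) is
alt-homozygous in at least one but no more than five cohort members, and
(3) has an external reference minor allele frequency below 0.05 (strict).
Variants absent from the external reference are retained: absence from a
catalog of >100k genomes is stronger evidence of rarity than any cutoff.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io import GenotypeDataset, read_annotation_table, read_vcf

logger = logging.getLogger(__name__)

PCV_IMPACTS = ("HIGH", "MODERATE", "UORF")


def load_annotated_variants(
    vcf_path: str,
    annotation_path: str,
    max_mismatch_fraction: float = 0.5,
) -> GenotypeDataset:
    """Join a biallelic VCF with its side-car annotation table.

    Variants lacking an annotation row are dropped (logged count).  The join
    requires an exact (chrom, pos, ref, alt) match — the input contract is a
    pre-normalized, pre-split VCF.  A mismatch fraction above
    ``max_mismatch_fraction`` aborts with an integrity error.
    """
    ds = read_vcf(vcf_path)
    annot = read_annotation_table(annotation_path)
    matched = ds.variants.index.isin(annot.index)
    n_dropped = int((~matched).sum())
    if n_dropped:
        logger.warning(
            "%d of %d VCF variants have no annotation row and were dropped",
            n_dropped, ds.n_variants,
        )
    if ds.n_variants and n_dropped / ds.n_variants > max_mismatch_fraction:
        raise IntegrityError(
            f"{n_dropped}/{ds.n_variants} variants missing from the annotation "
            f"table exceeds the allowed fraction {max_mismatch_fraction}"
        )
    variants = ds.variants[matched]
    extra = annot.loc[variants.index].drop(columns=["chrom", "pos", "ref", "alt"])
    variants = variants.join(extra)
    return GenotypeDataset(
        variants=variants,
        genotypes=ds.genotypes[matched],
        samples=ds.samples,
    )


def select_pcvs(
    ds: GenotypeDataset,
    min_hom: int = 1,
    max_hom: int = 5,
    maf_cutoff: float = 0.05,
    impacts=PCV_IMPACTS,
) -> pd.DataFrame:
    """Apply the three PCV filters and return one row per retained variant.

    Homozygote counting uses non-missing genotypes only.  The returned frame
    is indexed by variant id and carries the carrier sample ids per variant.
    """
    V = ds.variants
    G = ds.genotypes
    hom_counts = (G == 2).sum(axis=1)
    impact_ok = V["impact"].isin(impacts).to_numpy()
    hom_ok = (hom_counts >= min_hom) & (hom_counts <= max_hom)
    maf = V["external_maf"].to_numpy(dtype=float) if "external_maf" in V else np.full(len(V), np.nan)
    maf_ok = np.isnan(maf) | (maf < maf_cutoff)
    keep = impact_ok & hom_ok & maf_ok

    sample_arr = np.array(ds.samples)
    rows = []
    for vi in np.nonzero(keep)[0]:
        carriers = sample_arr[G[vi] == 2].tolist()
        rows.append(
            {
                "variant_id": V.index[vi],
                "chrom": V["chrom"].iloc[vi],
                "pos": V["pos"].iloc[vi],
                "gene": V["gene"].iloc[vi] if "gene" in V else None,
                "consequence": V["consequence"].iloc[vi] if "consequence" in V else None,
                "impact_class": V["impact"].iloc[vi],
                "external_maf": maf[vi],
                "n_hom": len(carriers),
                "homozygote_ids": carriers,
            }
        )
    pcvs = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "gene", "consequence",
                 "impact_class", "external_maf", "n_hom", "homozygote_ids"],
    )
    return pcvs.set_index("variant_id")


def summarize_pcvs(pcvs: pd.DataFrame, ds: GenotypeDataset | None = None) -> dict:
    """Summary tables: consequence-class counts, impact counts, PCVs-per-gene
    histogram, single-PCV gene count, and (when the full dataset is supplied)
    the filter-funnel intermediates in both filter orders: impact+homozygote
    count before the MAF cut, and impact+MAF before the homozygote cut."""
    if len(pcvs):
        by_consequence = pcvs["consequence"].value_counts().sort_index()
        by_impact = pcvs["impact_class"].value_counts().sort_index()
        per_gene = pcvs.groupby("gene").size()
        histogram = per_gene.value_counts().sort_index()
        single = int((per_gene == 1).sum())
    else:
        by_consequence = pd.Series(dtype=int)
        by_impact = pd.Series(dtype=int)
        histogram = pd.Series(dtype=int)
        single = 0
    summary = {
        "n_pcvs": len(pcvs),
        "n_genes": int(pcvs["gene"].nunique()) if len(pcvs) else 0,
        "by_consequence": by_consequence,
        "by_impact": by_impact,
        "pcvs_per_gene_histogram": histogram,
        "genes_with_single_pcv": single,
    }
    if ds is not None:
        variants = ds.variants
        impact_ok = variants["impact"].isin(PCV_IMPACTS).to_numpy()
        maf = variants["external_maf"].to_numpy(dtype=float)
        maf_ok = np.isnan(maf) | (maf < 0.05)
        hom_counts = (ds.genotypes == 2).sum(axis=1)
        hom_ok = (hom_counts >= 1) & (hom_counts <= 5)
        summary["funnel"] = {
            "n_variants": len(variants),
            "n_impact_pass": int(impact_ok.sum()),
            "n_impact_and_hom": int((impact_ok & hom_ok).sum()),
            "n_impact_and_maf": int((impact_ok & maf_ok).sum()),
            "n_final": len(pcvs),
        }
    return summary
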