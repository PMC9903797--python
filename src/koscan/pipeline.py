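"""End-to-end orchestration: filter -> homozygosity -> EHF -> scan -> stats.

The report is a machine-readable funnel: variant counts at every filter
stage, ROH/PGROH/F summaries, association counts before and after the
relevance filters, FDR estimates and the significant hit list.  Every
stage's output is also written standalone so stages can be rerun
independently.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .ehf import classic_caf, design_curve, ehf_table
from .errors import ConfigurationError, FormatError
from .pcv import load_annotated_variants, select_pcvs, summarize_pcvs
from .roh import RohHmmParams, detect_roh, inbreeding_f, pcv_roh_overlap, pg_roh
from .scan import PhenotypeMatrix, RelevanceMaps, apply_relevance, scan
from .stats import annotate_associations, permutation_fdr, qq_data
from .io import (
    read_bed,
    read_gene_metabolite_pairs,
    read_phenotype_table,
    read_protein_gene_map,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    annotation: str = ""
    regions: str = ""
    phenotypes: dict = field(default_factory=dict)  # platform -> TSV path
    protein_genes: str = ""
    gene_metabolite: str = ""
    outdir: str = "koscan_out"
    # PCV filter
    min_hom: int = 1
    max_hom: int = 5
    maf_cutoff: float = 0.05
    # scan
    k: int = 20
    min_nonmissing: int = 1000
    min_nonmissing_protein: int = 0
    same_tail: bool = True
    missing_homozygote_policy: str = "skip"
    # stats
    b_permutations: int = 100
    seed: int = 0
    alpha: float = 0.05
    two_sided_halving: bool = False
    # ROH
    roh_min_length: int = 10_000
    roh_az_to_hw_rate: float = 1e-8
    roh_hw_to_az_rate: float = 1e-8
    roh_genotype_error: float = 1e-4
    # EHF
    ehf_a: float = 0.058
    design_cohort_sizes: tuple = (2935, 60000, 5_000_000)

    def __post_init__(self):
        self.design_cohort_sizes = tuple(self.design_cohort_sizes)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.b_permutations < 1:
            raise ConfigurationError("b_permutations must be at least 1")
        if not 1 <= self.min_hom <= self.max_hom:
            raise ConfigurationError("need 1 <= min_hom <= max_hom")
        if not 0 < self.maf_cutoff <= 1:
            raise ConfigurationError("maf_cutoff must lie in (0, 1]")
        if self.missing_homozygote_policy not in ("skip", "available"):
            raise ConfigurationError("missing_homozygote_policy must be skip|available")
        for name in ("vcf", "annotation", "regions"):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise ConfigurationError(f"{name} file not found: {path}")

    def roh_params(self) -> RohHmmParams:
        return RohHmmParams(
            az_to_hw_rate=self.roh_az_to_hw_rate,
            hw_to_az_rate=self.roh_hw_to_az_rate,
            genotype_error=self.roh_genotype_error,
            min_length=self.roh_min_length,
        )


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Schema and consistency diagnostics without running any stage.

    Returns a list of {level, message} dicts; errors do not raise.
    """
    diags: list[dict] = []

    def err(msg):
        diags.append({"level": "error", "message": msg})

    def warn(msg):
        diags.append({"level": "warning", "message": msg})

    vcf_samples: list[str] = []
    if not os.path.exists(config.vcf):
        err(f"VCF not found: {config.vcf}")
    else:
        with open(config.vcf) as fh:
            n_cols = None
            for lineno, line in enumerate(fh, 1):
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    if len(fields) < 10:
                        err(f"VCF line {lineno}: header has no sample columns")
                    n_cols = len(fields)
                    vcf_samples = fields[9:]
                    continue
                if n_cols is None:
                    err(f"VCF line {lineno}: data before #CHROM header")
                    break
                if len(fields) != n_cols:
                    err(f"VCF line {lineno}: {len(fields)} columns, expected {n_cols}")
                    break
                try:
                    int(fields[1])
                except ValueError:
                    err(f"VCF line {lineno}: POS {fields[1]!r} is not an integer")
                    break

    if not os.path.exists(config.annotation):
        err(f"annotation table not found: {config.annotation}")
    else:
        try:
            from .io import read_annotation_table
            read_annotation_table(config.annotation)
        except FormatError as exc:
            err(str(exc))

    if config.regions:
        if not os.path.exists(config.regions):
            err(f"regions BED not found: {config.regions}")
        else:
            try:
                read_bed(config.regions)
            except FormatError as exc:
                err(str(exc))

    for platform, path in config.phenotypes.items():
        if not os.path.exists(path):
            err(f"{platform} phenotype table not found: {path}")
            continue
        try:
            mat = read_phenotype_table(path)
        except Exception as exc:
            err(f"{platform} phenotype table unreadable: {exc}")
            continue
        if vcf_samples:
            extra = [s for s in mat.index if s not in set(vcf_samples)]
            for s in extra[:10]:
                warn(f"{platform} sample {s} is absent from the VCF")
    return diags


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on the configured inputs and write the report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)

    # --- stage 1: load + PCV filter -------------------------------------
    ds = load_annotated_variants(config.vcf, config.annotation)
    pcvs = select_pcvs(
        ds, min_hom=config.min_hom, max_hom=config.max_hom, maf_cutoff=config.maf_cutoff
    )
    summary = summarize_pcvs(pcvs, ds)
    pcv_out = pcvs.copy()
    pcv_out["homozygote_ids"] = [",".join(ids) for ids in pcv_out["homozygote_ids"]]
    pcv_out.to_csv(out("pcvs.tsv"), sep="\t")

    # --- stage 2: homozygosity ------------------------------------------
    regions = read_bed(config.regions) if config.regions else None
    freqs = ds.allele_frequencies()
    f_series = inbreeding_f(ds, freqs)
    segments = detect_roh(ds, config.roh_params(), regions=regions, allele_freqs=freqs)
    if regions is not None:
        pg = pg_roh(segments, regions, samples=ds.samples)
    else:
        pg = pd.Series(np.nan, index=ds.samples, name="pg_roh")
    profile, in_roh_fraction, corr = pcv_roh_overlap(pcvs, segments, ds.samples, pg)
    profile["f_coefficient"] = f_series
    profile.to_csv(out("homozygosity_profiles.tsv"), sep="\t", float_format="%.8g")
    segments.to_csv(out("roh_segments.tsv"), sep="\t", index=False, float_format="%.6g")

    # --- stage 3: EHF ----------------------------------------------------
    lof = ds.variants[ds.variants["impact"] == "HIGH"].copy()
    lof["af"] = freqs[ds.variants["impact"].to_numpy() == "HIGH"]
    caf = classic_caf(lof, maf_cutoff=config.maf_cutoff, lof_only=False)
    a = float(pg.mean()) if pg.notna().any() else config.ehf_a
    ehf_records = ehf_table(caf, a)
    ehf_records.to_csv(out("ehf.tsv"), sep="\t", float_format="%.8g")
    curve = design_curve(ehf_records["ehf"], config.design_cohort_sizes)
    curve.to_csv(out("design_curve.tsv"), sep="\t", index=False)

    # --- stage 4: scan ---------------------------------------------------
    maps = RelevanceMaps(
        protein_to_genes=read_protein_gene_map(config.protein_genes)
        if config.protein_genes else {},
        gene_metabolite_pairs=read_gene_metabolite_pairs(config.gene_metabolite)
        if config.gene_metabolite else set(),
    )
    matrices = {
        platform: PhenotypeMatrix(
            values=read_phenotype_table(path), platform=platform
        )
        for platform, path in config.phenotypes.items()
    }
    m_phenotypes = sum(len(m.values.columns) for m in matrices.values())
    all_assoc, fdr_reports = [], {}
    for platform, matrix in matrices.items():
        min_nn = (
            config.min_nonmissing_protein if platform == "protein"
            else config.min_nonmissing
        )
        assoc = scan(
            pcvs, matrix, k=config.k, min_nonmissing=min_nn,
            same_tail=config.same_tail,
            missing_homozygote_policy=config.missing_homozygote_policy,
        )
        assoc, _, _ = apply_relevance(assoc, maps)
        all_assoc.append(assoc)
        fdr_all = permutation_fdr(
            pcvs, matrix, k=config.k, min_nonmissing=min_nn,
            B=config.b_permutations, seed=config.seed,
        )
        fdr_rel = permutation_fdr(
            pcvs, matrix, k=config.k, min_nonmissing=min_nn,
            B=config.b_permutations, seed=config.seed, maps=maps,
        )
        fdr_reports[platform] = {
            "unfiltered": fdr_all.to_dict(),
            "relevance_filtered": fdr_rel.to_dict(),
        }

    associations = (
        pd.concat(all_assoc, ignore_index=True) if all_assoc else pd.DataFrame()
    )
    if len(associations) and m_phenotypes:
        associations = annotate_associations(
            associations, m_phenotypes, alpha=config.alpha,
            two_sided_halving=config.two_sided_halving,
        )
        qq, inflation = qq_data(associations["approx_p"])
        qq.to_csv(out("qq.tsv"), sep="\t", index=False, float_format="%.6g")
    else:
        inflation = float("nan")
    assoc_out = associations.copy()
    if len(assoc_out):
        assoc_out["ranks"] = [",".join(map(str, r)) for r in assoc_out["ranks"]]
    assoc_out.to_csv(out("associations.tsv"), sep="\t", index=False, float_format="%.8g")

    with open(out("fdr.json"), "w") as fh:
        json.dump(fdr_reports, fh, indent=1, sort_keys=True)

    relevant = (
        associations[associations["relevance"] != "none"]
        if len(associations) else associations
    )
    n_sig = (
        int((relevant["significant"]).sum())
        if len(relevant) and "significant" in relevant else 0
    )
    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "funnel": summary["funnel"],
        "pcv_summary": {
            "n_pcvs": summary["n_pcvs"],
            "n_genes": summary["n_genes"],
            "genes_with_single_pcv": summary["genes_with_single_pcv"],
            "by_impact": {str(k): int(v) for k, v in summary["by_impact"].items()},
        },
        "homozygosity": {
            "mean_f": float(f_series.mean()),
            "mean_pg_roh": float(pg.mean()) if pg.notna().any() else None,
            "hom_pcv_in_roh_fraction": in_roh_fraction,
            "pg_roh_vs_n_hom_pcvs_pearson_r": None if np.isnan(corr[0]) else corr[0],
        },
        "ehf": {
            "a_roh": a,
            "median_ehf": float(ehf_records["ehf"].median()) if len(ehf_records) else None,
        },
        "associations": {
            "m_phenotypes": m_phenotypes,
            "n_total": int(len(associations)),
            "n_ppcv": int((associations["relevance"] == "in_cis").sum())
            if len(associations) else 0,
            "n_mpcv": int(associations["relevance"].isin(["mqtl", "hmdb"]).sum())
            if len(associations) else 0,
            "n_relevant_significant": n_sig,
            "qq_inflation": None if np.isnan(inflation) else inflation,
        },
        "fdr": fdr_reports,
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out("summary.txt"), "w") as fh:
        fh.write(_human_summary(report))
    logger.info("resolved config: %s", report["config"])
    return report


def _human_summary(report: dict) -> str:
    fn = report["funnel"]
    hz = report["homozygosity"]
    asc = report["associations"]
    lines = [
        "koscan pipeline summary",
        "=======================",
        f"variants in VCF:                {fn['n_variants']}",
        f"  with qualifying impact:       {fn['n_impact_pass']}",
        f"  + 1-5 homozygotes:            {fn['n_impact_and_hom']}",
        f"  retained PCVs:                {fn['n_final']}",
        f"mean inbreeding F:              {hz['mean_f']:.4f}",
        f"mean PGROH:                     {hz['mean_pg_roh'] if hz['mean_pg_roh'] is not None else 'n/a'}",
        f"hom. PCVs inside ROH:           {hz['hom_pcv_in_roh_fraction']:.2%}",
        f"extreme-tail associations:      {asc['n_total']}",
        f"  in-cis protein (pPCV):        {asc['n_ppcv']}",
        f"  gene-linked metabolite (mPCV):{asc['n_mpcv']}",
        f"  relevant and significant:     {asc['n_relevant_significant']}",
        "",
    ]
    return "\n".join(lines)
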