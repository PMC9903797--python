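"""Readers and writers for the cohort file formats.

VCF parsing goes through cyvcf2; all tabular inputs (annotation table,
phenotype matrices, relevance maps, BED) are plain TSV read with pandas.

Genotypes are held as an ``int8`` matrix of shape (n_variants, n_samples)
with codes 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: columns the side-car annotation table must provide
ANNOTATION_REQUIRED = ["chrom", "pos", "ref", "alt", "gene", "consequence", "impact", "external_maf"]
ANNOTATION_OPTIONAL = ["cadd", "revel", "lof_confidence"]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeDataset:
    """Biallelic variants with per-sample genotype codes.

    ``variants`` is indexed by ``chrom:pos:ref:alt`` and aligned row-wise with
    the genotype matrix.  Annotation columns (gene, consequence, impact,
    external_maf, ...) are attached after joining the side-car table.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise IntegrityError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def allele_frequencies(self) -> np.ndarray:
        """Cohort alternate-allele frequency per variant over non-missing calls."""
        G = self.genotypes
        called = G >= 0
        alt = np.where(called, G, 0).sum(axis=1)
        denom = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)


def read_vcf(path: str) -> GenotypeDataset:
    """Load a biallelic VCF into a :class:`GenotypeDataset`.

    Multiallelic records (comma in ALT) are dropped with a logged count;
    the input contract is a pre-split, pre-normalized VCF.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required to read VCF input") from exc

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows, gts = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)
    vcf.close()
    if n_multi:
        logger.warning("dropped %d multiallelic records from %s", n_multi, path)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    variants.index = pd.Index(
        [variant_key(*r) for r in rows], name="variant_id"
    )
    G = np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeDataset(variants=variants, genotypes=G, samples=samples)


def write_vcf(path: str, ds: GenotypeDataset) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    chroms = list(dict.fromkeys(ds.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=koscan-synthetic-cohort\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        V = ds.variants
        for i, (vid, row) in enumerate(V.iterrows()):
            cols = [
                str(row["chrom"]), str(int(row["pos"])), str(vid),
                row["ref"], row["alt"], ".", "PASS", ".", "GT",
            ]
            cols.extend(gt_str[int(g)] for g in ds.genotypes[i])
            fh.write("\t".join(cols) + "\n")


def read_annotation_table(path: str) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_REQUIRED if c not in annot.columns]
    if missing:
        raise FormatError(f"annotation table {path} lacks required columns {missing}")
    annot.index = pd.Index(
        [variant_key(c, p, r, a) for c, p, r, a in
         zip(annot["chrom"], annot["pos"], annot["ref"], annot["alt"])],
        name="variant_id",
    )
    return annot


def read_bed(path: str) -> pd.DataFrame:
    """Read 0-based half-open regions; only the first three columns are used."""
    regions = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    if (regions["end"] <= regions["start"]).any():
        raise FormatError(f"BED {path} contains empty or inverted intervals")
    return regions


def write_bed(path: str, regions: pd.DataFrame, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    regions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_phenotype_table(path: str) -> pd.DataFrame:
    """Sample-by-analyte TSV: first column sample id, one column per analyte."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        raise IntegrityError(f"duplicate sample ids in {path}")
    return mat.astype(float)


def read_protein_gene_map(path: str) -> dict[str, frozenset]:
    """analyte -> set of encoding genes; several genes comma-separated."""
    tab = pd.read_csv(path, sep="\t")
    return {
        str(r["analyte"]): frozenset(str(r["genes"]).split(","))
        for _, r in tab.iterrows()
    }


def read_gene_metabolite_pairs(path: str) -> set[tuple]:
    tab = pd.read_csv(path, sep="\t")
    return {(str(r["gene"]), str(r["metabolite"])) for _, r in tab.iterrows()}
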