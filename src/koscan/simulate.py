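"""Synthetic consanguineous cohort with planted gene knockouts.

The generator emulates the statistical structure the downstream analysis
assumes, not the biology that produces it:

* per-sample autozygosity is planted directly as runs of homozygosity (ROH)
  drawn from an alternating renewal process whose stationary occupancy
  equals the requested mean genome fraction in ROH;
* genotypes are Hardy-Weinberg draws outside ROH and forced homozygous
  inside ROH (alt-hom with probability equal to the allele frequency);
* analyte levels are standard normal, shifted for planted knockout
  carriers, and metabolites are left-censored at a limit-of-detection
  quantile (missing-not-at-random, as assay LOD censoring produces).

Defaults mirror the cohort the analysis was designed around: 2,935
participants, 32,868 candidate protein-changing variants, mean genome
fraction in ROH 3.52%, and platform sizes of 1,305 proteins, 1,159
metabolites and 71 laboratory assays.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import GenotypeDataset, variant_key, write_vcf, write_bed
from .scan import PhenotypeMatrix, RelevanceMaps

# consequence class -> (sampling weight, predicted impact); weights give the
# usual exome mix: missense dominates, frameshifts next among the truncating
# classes, with a synonymous (LOW) background the impact filter removes.
CONSEQUENCE_MIX = {
    "missense_variant": (0.42, "MODERATE"),
    "synonymous_variant": (0.30, "LOW"),
    "frameshift_variant": (0.08, "HIGH"),
    "inframe_deletion": (0.05, "MODERATE"),
    "stop_gained": (0.05, "HIGH"),
    "splice_acceptor_variant": (0.02, "HIGH"),
    "splice_donor_variant": (0.02, "HIGH"),
    "start_lost": (0.01, "HIGH"),
    "stop_lost": (0.01, "HIGH"),
    "uORF_created": (0.04, "UORF"),
}

_PLATFORM_PREFIX = {"protein": "PROT", "metabolite": "MET", "lab": "LAB"}

MIN_ROH_LENGTH = 10_000


@dataclass(frozen=True)
class PlantedKnockout:
    """Ground-truth knockout: a forced rare homozygous variant in ``gene``
    that shifts its carriers' levels of ``affected_analytes`` by
    ``effect_size_sd`` standard deviations."""

    gene: str
    n_homozygotes: int
    affected_analytes: tuple[str, ...]
    effect_size_sd: float
    impact: str = "HIGH"

    def __post_init__(self):
        if not 1 <= self.n_homozygotes <= 5:
            raise ConfigurationError(
                f"planted knockout {self.gene}: n_homozygotes must be in 1..5"
            )
        if self.impact not in ("HIGH", "MODERATE"):
            raise ConfigurationError(f"planted knockout impact must be HIGH or MODERATE")


@dataclass
class SimulationConfig:
    n_samples: int = 2935
    n_variants: int = 32868
    n_genes: int = 12466
    target_regions: tuple = (("1", 0, 30_000_000), ("2", 0, 30_000_000))
    roh_fraction_mean: float = 0.0352
    roh_segment_mean_length: float = 1_500_000.0
    planted_knockouts: tuple = ()
    lod_censor_quantile: float = 0.10
    analyte_counts: dict = field(
        default_factory=lambda: {"protein": 1305, "metabolite": 1159, "lab": 71}
    )
    seed: int = 0
    # optional knobs
    missing_genotype_rate: float = 0.0
    mcar_rate: float = 0.0
    analyte_block_corr: float = 0.0
    analyte_block_size: int = 10
    af_range: tuple = (5e-4, 0.5)

    def validate(self) -> None:
        if min(self.n_samples, self.n_variants, self.n_genes) <= 0:
            raise ConfigurationError("all counts must be positive")
        if not 0.0 <= self.roh_fraction_mean <= 1.0:
            raise ConfigurationError("roh_fraction_mean must lie in [0, 1]")
        if not 0.0 <= self.lod_censor_quantile < 1.0:
            raise ConfigurationError("lod_censor_quantile must lie in [0, 1)")
        if any(c <= 0 for c in self.analyte_counts.values()):
            raise ConfigurationError("analyte counts must be positive")
        for ko in self.planted_knockouts:
            if ko.n_homozygotes > self.n_samples:
                raise ConfigurationError(
                    f"knockout {ko.gene} needs {ko.n_homozygotes} homozygotes "
                    f"but the cohort has only {self.n_samples} samples"
                )
            for analyte in ko.affected_analytes:
                if self._platform_of(analyte) is None:
                    raise ConfigurationError(
                        f"knockout {ko.gene} references unknown analyte {analyte}"
                    )

    def _platform_of(self, analyte: str) -> str | None:
        for platform, prefix in _PLATFORM_PREFIX.items():
            n = self.analyte_counts.get(platform, 0)
            if analyte.startswith(prefix):
                try:
                    idx = int(analyte[len(prefix):])
                except ValueError:
                    return None
                if 0 <= idx < n:
                    return platform
        return None

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:05d}" for i in range(self.n_genes)]

    def analyte_ids(self, platform: str) -> list[str]:
        prefix = _PLATFORM_PREFIX[platform]
        return [f"{prefix}{i:04d}" for i in range(self.analyte_counts.get(platform, 0))]


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    dataset: GenotypeDataset
    phenotypes: dict  # platform -> PhenotypeMatrix
    maps: RelevanceMaps
    truth: dict


def _sample_roh_segments(rng, regions, fraction, mean_length):
    """Alternating gap/ROH renewal walk across each region.

    Segment lengths are Exp(mean_length) floored at 10 kb; the gap mean is
    chosen so the stationary ROH occupancy equals ``fraction`` (using the
    analytic mean of the floored-exponential, c + m*exp(-c/m))."""
    if fraction <= 0:
        return []
    if fraction >= 1:
        return [(c, s, e) for c, s, e in regions]
    c = MIN_ROH_LENGTH
    eff_mean = c + mean_length * math.exp(-c / mean_length)
    gap_mean = eff_mean * (1.0 - fraction) / fraction
    segments = []
    for chrom, start, end in regions:
        pos = float(start)
        in_roh = rng.random() < fraction
        while pos < end:
            if in_roh:
                length = max(c, rng.exponential(mean_length))
                seg_end = min(pos + length, end)
                if seg_end - pos >= c:
                    segments.append((chrom, int(pos), int(seg_end)))
                pos += length
            else:
                pos += rng.exponential(gap_mean)
            in_roh = not in_roh
    return segments


def _draw_variant_table(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Positions, alleles, gene assignment, consequence/impact, allele
    frequencies and an external-reference MAF for every variant."""
    regions = list(cfg.target_regions)
    lengths = np.array([e - s for _, s, e in regions], dtype=float)
    n_per = rng.multinomial(cfg.n_variants, lengths / lengths.sum())
    chroms, positions = [], []
    for (chrom, start, end), k in zip(regions, n_per):
        span = end - start
        k = min(k, span)  # positions must be distinct within the region
        pos = np.sort(rng.choice(span, size=k, replace=False)) + start + 1  # 1-based
        chroms.extend([chrom] * k)
        positions.extend(pos.tolist())
    n = len(positions)

    classes = list(CONSEQUENCE_MIX)
    weights = np.array([CONSEQUENCE_MIX[c][0] for c in classes])
    consequence = rng.choice(classes, size=n, p=weights / weights.sum())
    impact = np.array([CONSEQUENCE_MIX[c][1] for c in consequence])

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=n)) % 4]
    # indel-style alleles for the indel consequence classes
    indel = np.isin(consequence, ["frameshift_variant", "inframe_deletion"])
    ref = np.where(indel, np.char.add(ref, alt), ref)

    lo, hi = cfg.af_range
    af = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    # external reference MAF tracks the cohort AF with multiplicative noise;
    # ~10% of variants are absent from the reference (NaN)
    external = np.clip(af * np.exp(rng.normal(0.0, 0.4, size=n)), 0.0, 0.5)
    external[rng.random(n) < 0.10] = np.nan

    # genes are contiguous positional blocks, n_genes of them genome-wide
    gene_of = np.sort(rng.integers(0, cfg.n_genes, size=n))
    gene_names = np.array(cfg.gene_ids())[gene_of]

    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "gene": gene_names,
            "consequence": consequence,
            "impact": impact,
            "external_maf": external,
            "af": af,
        }
    )
    variants.index = pd.Index(
        [variant_key(c, p, r, a) for c, p, r, a in
         zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])],
        name="variant_id",
    )
    if variants.index.duplicated().any():
        variants = variants[~variants.index.duplicated()]
    return variants


def simulate_genotypes(cfg: SimulationConfig):
    """Draw ROH truth and the genotype matrix; returns (dataset, truth).

    ``truth`` carries the planted ROH intervals, per-sample true PGROH
    (autozygous genome fraction, which is also the expected inbreeding F),
    and one record per planted knockout with its forced carriers."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:05d}" for i in range(cfg.n_samples)]
    variants = _draw_variant_table(cfg, rng)
    n_var = len(variants)
    positions0 = variants["pos"].to_numpy() - 1  # 0-based for interval tests
    chrom_arr = variants["chrom"].to_numpy()
    af = variants["af"].to_numpy()

    regions = list(cfg.target_regions)
    total_len = float(sum(e - s for _, s, e in regions))

    G = np.empty((n_var, cfg.n_samples), dtype=np.int8)
    roh_rows = []
    pg_truth = np.zeros(cfg.n_samples)
    for j, sample in enumerate(samples):
        segs = _sample_roh_segments(
            rng, regions, cfg.roh_fraction_mean, cfg.roh_segment_mean_length
        )
        in_roh = np.zeros(n_var, dtype=bool)
        for chrom, s, e in segs:
            roh_rows.append((sample, chrom, s, e))
            in_roh |= (chrom_arr == chrom) & (positions0 >= s) & (positions0 < e)
        pg_truth[j] = sum(e - s for _, s, e in segs) / total_len
        u = rng.random(n_var)
        hwe = (u < af).astype(np.int8) + (rng.random(n_var) < af).astype(np.int8)
        autozygous = np.where(u < af, np.int8(2), np.int8(0))
        G[:, j] = np.where(in_roh, autozygous, hwe)

    truth_roh = pd.DataFrame(roh_rows, columns=["sample", "chrom", "start", "end"])

    # force planted knockouts: one variant per knocked-out gene
    ko_records = []
    gene_index = variants.groupby("gene").indices
    variants = variants.copy()
    sample_arr = np.array(samples)
    for ko in cfg.planted_knockouts:
        if ko.gene not in gene_index:
            raise ConfigurationError(f"planted gene {ko.gene} received no variants")
        vi = int(gene_index[ko.gene][0])
        vid = variants.index[vi]
        conseq = "stop_gained" if ko.impact == "HIGH" else "missense_variant"
        variants.iloc[vi, variants.columns.get_loc("consequence")] = conseq
        variants.iloc[vi, variants.columns.get_loc("impact")] = ko.impact
        variants.iloc[vi, variants.columns.get_loc("external_maf")] = 0.001
        carriers = rng.choice(cfg.n_samples, size=ko.n_homozygotes, replace=False)
        row = np.minimum(G[vi], 1)  # demote accidental homozygotes
        row[carriers] = 2
        G[vi] = row
        ko_records.append(
            {
                "gene": ko.gene,
                "variant_id": vid,
                "carriers": sorted(sample_arr[carriers].tolist()),
                "affected_analytes": list(ko.affected_analytes),
                "effect_size_sd": ko.effect_size_sd,
                "impact": ko.impact,
            }
        )

    if cfg.missing_genotype_rate > 0:
        mask = rng.random(G.shape) < cfg.missing_genotype_rate
        # keep forced carriers callable
        for rec in ko_records:
            vi = variants.index.get_loc(rec["variant_id"])
            mask[vi, :] = False
        G[mask] = -1

    ds = GenotypeDataset(variants=variants, genotypes=G, samples=samples)
    truth = {
        "roh": truth_roh,
        "pg_roh": pd.Series(pg_truth, index=samples, name="pg_roh_true"),
        "knockouts": ko_records,
    }
    return ds, truth


def simulate_phenotypes(cfg: SimulationConfig, ds: GenotypeDataset, truth: dict):
    """Baseline-normal analyte matrices with knockout shifts and metabolite
    left-censoring; also builds the protein->gene and gene<->metabolite
    relevance maps (planted pairs plus decoys)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    samples = ds.samples
    carriers_by_analyte: dict[str, list] = {}
    gene_by_protein_analyte: dict[str, str] = {}
    planted_pairs = set()
    for rec in truth["knockouts"]:
        for analyte in rec["affected_analytes"]:
            carriers_by_analyte.setdefault(analyte, []).append(
                (rec["carriers"], rec["effect_size_sd"])
            )
            platform = cfg._platform_of(analyte)
            if platform == "protein":
                gene_by_protein_analyte[analyte] = rec["gene"]
            elif platform == "metabolite":
                planted_pairs.add((rec["gene"], analyte))

    sample_pos = {s: i for i, s in enumerate(samples)}
    matrices = {}
    for platform in ("protein", "metabolite", "lab"):
        analytes = cfg.analyte_ids(platform)
        if not analytes:
            continue
        X = rng.standard_normal((len(samples), len(analytes)))
        rho = cfg.analyte_block_corr
        if rho > 0:
            b = cfg.analyte_block_size
            n_blocks = math.ceil(len(analytes) / b)
            factors = rng.standard_normal((len(samples), n_blocks))
            block_of = np.arange(len(analytes)) // b
            X = math.sqrt(1 - rho) * X + math.sqrt(rho) * factors[:, block_of]
        for ai, analyte in enumerate(analytes):
            for carriers, delta in carriers_by_analyte.get(analyte, []):
                idx = [sample_pos[s] for s in carriers]
                X[idx, ai] += delta
        if platform == "metabolite" and cfg.lod_censor_quantile > 0:
            lod = np.quantile(X, cfg.lod_censor_quantile, axis=0)
            X = np.where(X < lod[None, :], np.nan, X)
        if cfg.mcar_rate > 0 and platform != "protein":
            X = np.where(rng.random(X.shape) < cfg.mcar_rate, np.nan, X)
        values = pd.DataFrame(X, index=pd.Index(samples, name="sample"), columns=analytes)
        matrices[platform] = PhenotypeMatrix(values=values, platform=platform)

    genes = cfg.gene_ids()
    # protein -> encoding gene: planted analytes map to their knockout gene,
    # the rest to arbitrary genes; ~4% of aptamers map to two genes
    protein_to_genes = {}
    for analyte in cfg.analyte_ids("protein"):
        if analyte in gene_by_protein_analyte:
            mapped = {gene_by_protein_analyte[analyte]}
        else:
            mapped = {genes[int(rng.integers(0, len(genes)))]}
        if rng.random() < 0.04:
            mapped.add(genes[int(rng.integers(0, len(genes)))])
        protein_to_genes[analyte] = frozenset(mapped)

    # gene <-> metabolite pairs: every planted pair plus random decoys
    met_ids = cfg.analyte_ids("metabolite")
    pairs = {(g, m, "mGWAS") for g, m in planted_pairs}
    n_decoys = 3 * len(met_ids)
    sources = ("mGWAS", "HMDB-enzyme", "HMDB-transporter")
    for _ in range(n_decoys):
        g = genes[int(rng.integers(0, len(genes)))]
        m = met_ids[int(rng.integers(0, len(met_ids)))] if met_ids else None
        if m is not None and (g, m) not in planted_pairs:
            pairs.add((g, m, sources[int(rng.integers(0, 3))]))
    maps = RelevanceMaps(
        protein_to_genes=protein_to_genes,
        gene_metabolite_pairs={(g, m) for g, m, _ in pairs},
        pair_sources={(g, m): src for g, m, src in pairs},
    )
    return matrices, maps


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    ds, truth = simulate_genotypes(cfg)
    phenotypes, maps = simulate_phenotypes(cfg, ds, truth)
    return SyntheticCohort(config=cfg, dataset=ds, phenotypes=phenotypes, maps=maps, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str) -> dict:
    """Serialize the cohort; returns the path of every file written."""
    os.makedirs(outdir, exist_ok=True)
    cfg = cohort.config
    paths = {}

    paths["vcf"] = os.path.join(outdir, "cohort.vcf")
    write_vcf(paths["vcf"], cohort.dataset)

    paths["annotation"] = os.path.join(outdir, "annotation.tsv")
    annot = cohort.dataset.variants[
        ["chrom", "pos", "ref", "alt", "gene", "consequence", "impact", "external_maf"]
    ]
    annot.to_csv(paths["annotation"], sep="\t", index=False, float_format="%.8g")

    for platform, matrix in cohort.phenotypes.items():
        p = os.path.join(outdir, f"phenotypes_{platform}.tsv")
        matrix.values.to_csv(p, sep="\t", float_format="%.8g")
        paths[f"phenotypes_{platform}"] = p

    paths["protein_genes"] = os.path.join(outdir, "protein_genes.tsv")
    pd.DataFrame(
        {
            "analyte": list(cohort.maps.protein_to_genes),
            "genes": [",".join(sorted(g)) for g in cohort.maps.protein_to_genes.values()],
        }
    ).to_csv(paths["protein_genes"], sep="\t", index=False)

    paths["gene_metabolite"] = os.path.join(outdir, "gene_metabolite.tsv")
    pairs = sorted(cohort.maps.gene_metabolite_pairs)
    pd.DataFrame(
        {
            "gene": [g for g, _ in pairs],
            "metabolite": [m for _, m in pairs],
            "source": [cohort.maps.pair_sources.get((g, m), "mGWAS") for g, m in pairs],
        }
    ).to_csv(paths["gene_metabolite"], sep="\t", index=False)

    paths["regions"] = os.path.join(outdir, "regions.bed")
    regions = pd.DataFrame(list(cfg.target_regions), columns=["chrom", "start", "end"])
    write_bed(paths["regions"], regions)

    paths["truth"] = os.path.join(outdir, "truth.json")
    truth_json = {
        "knockouts": cohort.truth["knockouts"],
        "roh": cohort.truth["roh"].to_dict(orient="records"),
        "pg_roh": cohort.truth["pg_roh"].round(10).to_dict(),
        "f_expected": cohort.truth["pg_roh"].round(10).to_dict(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)

    paths["config"] = os.path.join(outdir, "config.json")
    cfg_dict = asdict(cfg)
    cfg_dict["planted_knockouts"] = [asdict(k) for k in cfg.planted_knockouts]
    with open(paths["config"], "w") as fh:
        json.dump(cfg_dict, fh, indent=1, sort_keys=True, default=list)
    return paths
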