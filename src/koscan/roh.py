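"""Consanguinity quantification: inbreeding coefficient F, run-of-homozygosity
(ROH) detection with a two-state HMM, and the proportion of the assessed
genome covered by ROH (PGROH).

The HMM has states AZ (autozygous) and HW (Hardy-Weinberg equilibrium).
Emissions at a site with alternate allele frequency p and genotype-error
rate e:

    HW: (1-e) * [(1-p)^2, 2p(1-p), p^2] + e/3
    AZ: (1-e) * [1-p,     0,       p  ] + e/3

so a heterozygote in the AZ state can only arise through genotyping error.
The switch probability between consecutive sites a distance d apart is
1 - exp(-rate * d) with separate AZ->HW and HW->AZ per-bp rates (default
1e-8 each, the conventional setting for exome-restricted ROH calling).
Decoding is Viterbi; contiguous AZ runs become segments and runs shorter
than 10 kb are discarded, so reported ROH are "long" ROH produced by recent
parental relatedness rather than background LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, IntegrityError
from .io import GenotypeDataset

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_sites", "mean_quality"]


@dataclass(frozen=True)
class RohHmmParams:
    az_to_hw_rate: float = 1e-8
    hw_to_az_rate: float = 1e-8
    genotype_error: float = 1e-4
    min_length: int = 10_000

    def __post_init__(self):
        for r in (self.az_to_hw_rate, self.hw_to_az_rate, self.genotype_error):
            if not 0.0 < r < 1.0:
                raise ConfigurationError("HMM rates must lie in (0, 1)")
        if self.min_length <= 0:
            raise ConfigurationError("min_length must be positive")


def inbreeding_f(ds: GenotypeDataset, allele_freqs: np.ndarray | None = None) -> pd.Series:
    """Method-of-moments inbreeding coefficient per sample.

    F = (O - E) / (L - E) with L the non-missing site count for the sample,
    O its observed homozygous count and E = sum_i (1 - 2 p_i (1 - p_i)) the
    homozygosity expected under Hardy-Weinberg at the supplied (or
    cohort-estimated) allele frequencies.  Samples for which every included
    site is monomorphic (L == E) get NaN.
    """
    p = ds.allele_frequencies() if allele_freqs is None else np.asarray(allele_freqs, float)
    G = ds.genotypes
    called = G >= 0
    hom = called & (G != 1)
    e_site = 1.0 - 2.0 * p * (1.0 - p)
    L = called.sum(axis=0).astype(float)
    O = hom.sum(axis=0).astype(float)
    E = np.where(called, e_site[:, None], 0.0).sum(axis=0)
    denom = L - E
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    return pd.Series(f, index=ds.samples, name="f_coefficient")


def _emission_logs(genotypes, freqs, error):
    """(log_e_hw, log_e_az) per site; missing genotypes are uninformative."""
    p = np.clip(freqs, 1e-9, 1 - 1e-9)
    hw = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)
    az = np.stack([1 - p, np.zeros_like(p), p], axis=1)
    hw = (1 - error) * hw + error / 3.0
    az = (1 - error) * az + error / 3.0
    g = np.asarray(genotypes)
    ok = g >= 0
    idx = np.where(ok, g, 0)
    e_hw = np.where(ok, hw[np.arange(len(g)), idx], 1.0)
    e_az = np.where(ok, az[np.arange(len(g)), idx], 1.0)
    return np.log(e_hw), np.log(e_az)


def viterbi_roh(positions, genotypes, freqs, params: RohHmmParams):
    """Viterbi-decode one sample on one chromosome.

    Returns (state_path, segments) where state 1 = AZ, and segments are
    (start0, end0, n_sites, mean_quality) tuples covering contiguous AZ
    runs; ``mean_quality`` is the mean per-site log10 likelihood ratio
    AZ vs HW.  The minimum-length filter is NOT applied here.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise IntegrityError("sites must be sorted by position")
    n = len(pos)
    le_hw, le_az = _emission_logs(genotypes, freqs, params.genotype_error)
    d = np.diff(pos).astype(float)
    t_hw_az = -np.expm1(-params.hw_to_az_rate * d)  # switch prob HW->AZ
    t_az_hw = -np.expm1(-params.az_to_hw_rate * d)
    tiny = 1e-300
    log_stay_hw = np.log(np.maximum(1 - t_hw_az, tiny))
    log_sw_hw_az = np.log(np.maximum(t_hw_az, tiny))
    log_stay_az = np.log(np.maximum(1 - t_az_hw, tiny))
    log_sw_az_hw = np.log(np.maximum(t_az_hw, tiny))

    # states: 0 = HW, 1 = AZ
    V = np.empty((n, 2))
    ptr = np.zeros((n, 2), dtype=np.int8)
    V[0, 0] = np.log(0.5) + le_hw[0]
    V[0, 1] = np.log(0.5) + le_az[0]
    for i in range(1, n):
        from_hw = V[i - 1, 0] + log_stay_hw[i - 1]
        from_az = V[i - 1, 1] + log_sw_az_hw[i - 1]
        if from_hw >= from_az:
            V[i, 0], ptr[i, 0] = from_hw + le_hw[i], 0
        else:
            V[i, 0], ptr[i, 0] = from_az + le_hw[i], 1
        from_hw = V[i - 1, 0] + log_sw_hw_az[i - 1]
        from_az = V[i - 1, 1] + log_stay_az[i - 1]
        if from_az >= from_hw:
            V[i, 1], ptr[i, 1] = from_az + le_az[i], 1
        else:
            V[i, 1], ptr[i, 1] = from_hw + le_az[i], 0
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(V[-1, 1] > V[-1, 0])
    for i in range(n - 2, -1, -1):
        path[i] = ptr[i + 1, path[i + 1]]

    segments = []
    quality = (le_az - le_hw) / np.log(10)
    i = 0
    while i < n:
        if path[i] == 1:
            j = i
            while j + 1 < n and path[j + 1] == 1:
                j += 1
            segments.append(
                (int(pos[i] - 1), int(pos[j]), j - i + 1, float(quality[i:j + 1].mean()))
            )
            i = j + 1
        else:
            i += 1
    return path, segments


def detect_roh(
    ds: GenotypeDataset,
    params: RohHmmParams | None = None,
    regions: pd.DataFrame | None = None,
    allele_freqs: np.ndarray | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Detect ROH segments for every (sample, chromosome).

    Sites are restricted to ``regions`` (0-based half-open BED frame) when
    supplied.  Segments shorter than ``params.min_length`` are discarded
    after decoding.  Returns a frame with SEGMENT_COLUMNS.
    """
    params = params or RohHmmParams()
    freqs = ds.allele_frequencies() if allele_freqs is None else np.asarray(allele_freqs, float)
    V = ds.variants
    keep = np.ones(len(V), dtype=bool)
    if regions is not None:
        keep = np.zeros(len(V), dtype=bool)
        pos0 = V["pos"].to_numpy() - 1
        for _, reg in regions.iterrows():
            keep |= (
                (V["chrom"].to_numpy() == reg["chrom"])
                & (pos0 >= reg["start"]) & (pos0 < reg["end"])
            )
    which_samples = samples if samples is not None else ds.samples
    sample_idx = [ds.samples.index(s) for s in which_samples]
    rows = []
    for chrom in dict.fromkeys(V["chrom"][keep]):
        m = keep & (V["chrom"] == chrom).to_numpy()
        order = np.argsort(V["pos"].to_numpy()[m], kind="stable")
        pos = V["pos"].to_numpy()[m][order]
        p = freqs[m][order]
        for s, si in zip(which_samples, sample_idx):
            g = ds.genotypes[m, si][order]
            _, segs = viterbi_roh(pos, g, p, params)
            for start, end, n_sites, q in segs:
                if end - start >= params.min_length:
                    rows.append((s, chrom, start, end, n_sites, q))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _clip_total(segments: pd.DataFrame, regions: pd.DataFrame) -> float:
    """Total base pairs of segments after clipping to regions."""
    total = 0.0
    for _, seg in segments.iterrows():
        for _, reg in regions.iterrows():
            if seg["chrom"] != reg["chrom"]:
                continue
            lo = max(seg["start"], reg["start"])
            hi = min(seg["end"], reg["end"])
            if hi > lo:
                total += hi - lo
    return total


def pg_roh(
    segments: pd.DataFrame,
    regions: pd.DataFrame,
    samples: list[str] | None = None,
) -> pd.Series:
    """Per-sample proportion of the assessed genome in ROH.

    Segments are clipped to the target regions before the ratio; the
    denominator is the total target-region length (the regions the ROH
    caller assessed), not the whole genome.
    """
    region_total = float((regions["end"] - regions["start"]).sum())
    if region_total <= 0:
        raise ConfigurationError("target regions have zero total length")
    index = samples if samples is not None else sorted(segments["sample"].unique())
    out = pd.Series(0.0, index=pd.Index(index, name="sample"), name="pg_roh")
    for s, group in segments.groupby("sample"):
        if s in out.index:
            out[s] = _clip_total(group, regions) / region_total
    return out


def pcv_roh_overlap(
    pcvs: pd.DataFrame,
    segments: pd.DataFrame,
    samples: list[str],
    pg: pd.Series | None = None,
):
    """Overlap of homozygous PCV positions with each carrier's ROH.

    Returns (profile frame, overall in-ROH fraction, (pearson_r, p_value)).
    The correlation relates PGROH to the per-sample homozygous PCV count
    and needs ``pg`` and at least 3 samples; otherwise (nan, nan).
    """
    seg_by_sample: dict[str, dict] = {}
    for s, group in segments.groupby("sample"):
        by_chrom = {}
        for chrom, g2 in group.groupby("chrom"):
            starts = g2["start"].to_numpy()
            ends = g2["end"].to_numpy()
            order = np.argsort(starts)
            by_chrom[chrom] = (starts[order], ends[order])
        seg_by_sample[s] = by_chrom

    n_hom = dict.fromkeys(samples, 0)
    n_in = dict.fromkeys(samples, 0)
    for vid, row in pcvs.iterrows():
        pos0 = int(row["pos"]) - 1
        chrom = row["chrom"]
        for s in row["homozygote_ids"]:
            if s not in n_hom:
                continue
            n_hom[s] += 1
            starts_ends = seg_by_sample.get(s, {}).get(chrom)
            if starts_ends is None:
                continue
            starts, ends = starts_ends
            j = np.searchsorted(starts, pos0, side="right") - 1
            if j >= 0 and pos0 < ends[j]:
                n_in[s] += 1
    profile = pd.DataFrame(
        {
            "sample": samples,
            "n_hom_pcvs": [n_hom[s] for s in samples],
            "n_hom_pcvs_in_roh": [n_in[s] for s in samples],
        }
    ).set_index("sample")
    total = profile["n_hom_pcvs"].sum()
    fraction = profile["n_hom_pcvs_in_roh"].sum() / total if total else 0.0
    corr = (np.nan, np.nan)
    if pg is not None and len(samples) >= 3:
        aligned = pg.reindex(samples)
        if aligned.notna().all() and profile["n_hom_pcvs"].std() > 0 and aligned.std() > 0:
            r, pval = stats.pearsonr(aligned, profile["n_hom_pcvs"])
            corr = (float(r), float(pval))
        profile["pg_roh"] = aligned
    return profile, float(fraction), corr
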