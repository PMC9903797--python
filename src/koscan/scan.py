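"""Extreme-tail phenotype scan.

A candidate protein-changing variant (PCV) is flagged for an analyte when
every one of its alt-homozygous carriers ranks inside the extreme top-k or
bottom-k of the analyte's cohort distribution (default k=20, both tails
tested, all carriers required in the same tail).  Relevance filters then
retain in-cis protein hits (pPCVs: the variant sits in the gene encoding
the measured protein) and gene-linked metabolite hits (mPCVs: the
(gene, metabolite) pair is a reported mQTL or HMDB enzyme/transporter
association).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

SENSITIVITY_RULES = ("top20", "top10", "top5", "sd3")


@dataclass
class PhenotypeMatrix:
    """Samples x analytes with missing entries allowed.

    ``values``: DataFrame indexed by sample id, one float column per analyte
    (NaN = missing).  ``platform`` is one of protein / metabolite / lab.
    """

    values: pd.DataFrame
    platform: str
    analyte_meta: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def n_nonmissing(self) -> pd.Series:
        return self.values.notna().sum(axis=0)


@dataclass
class RelevanceMaps:
    """protein analyte -> encoding gene set, and reported gene<->metabolite pairs."""

    protein_to_genes: dict = field(default_factory=dict)
    gene_metabolite_pairs: set = field(default_factory=set)
    pair_sources: dict = field(default_factory=dict)


def rank_analyte(values: pd.Series, tail: str) -> pd.Series:
    """Extreme ordinal ranks over the non-missing samples of one analyte.

    tail="high": rank 1 = largest value; tail="low": rank 1 = smallest.
    Ties are broken deterministically by ascending sample id.  Missing
    samples get NaN (an all-missing analyte returns all-NaN: skip signal).
    """
    if tail not in ("high", "low"):
        raise ConfigurationError(f"tail must be 'high' or 'low', got {tail!r}")
    v = values.dropna()
    if v.empty:
        return pd.Series(np.nan, index=values.index)
    frame = v.sort_index()
    key = -frame.to_numpy() if tail == "high" else frame.to_numpy()
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(frame), dtype=float)
    ranks[order] = np.arange(1, len(frame) + 1)
    return pd.Series(ranks, index=frame.index).reindex(values.index)


def _rank_matrices(values: pd.DataFrame):
    """(rank_high, rank_low) float arrays aligned to values; NaN where missing."""
    vs = values.sort_index()
    V = vs.to_numpy(float)
    n, A = V.shape
    RH = np.full((n, A), np.nan)
    RL = np.full((n, A), np.nan)
    for a in range(A):
        col = V[:, a]
        ok = ~np.isnan(col)
        m = int(ok.sum())
        if m == 0:
            continue
        sub = col[ok]
        order = np.argsort(-sub, kind="stable")
        r = np.empty(m, dtype=float)
        r[order] = np.arange(1, m + 1)
        RH[ok, a] = r
        order = np.argsort(sub, kind="stable")
        r = np.empty(m, dtype=float)
        r[order] = np.arange(1, m + 1)
        RL[ok, a] = r
    # back to the original row order
    back = vs.index.get_indexer(values.index)
    return RH[back], RL[back]


def _prepare(pcvs: pd.DataFrame, matrix: PhenotypeMatrix, min_nonmissing: int):
    """Shared scan precomputation: analyte filter, rank matrices, carrier rows."""
    nn = matrix.n_nonmissing()
    keep = nn[nn > min_nonmissing].index
    values = matrix.values[keep]
    RH, RL = _rank_matrices(values)
    miss = np.isnan(values.to_numpy(float))
    sample_pos = {s: i for i, s in enumerate(values.index)}
    hom_rows = [
        np.array([sample_pos[s] for s in ids if s in sample_pos], dtype=int)
        for ids in pcvs["homozygote_ids"]
    ]
    n_absent = [
        len(ids) - len(rows) for ids, rows in zip(pcvs["homozygote_ids"], hom_rows)
    ]
    return values, RH, RL, miss, nn[keep], hom_rows, n_absent


def scan(
    pcvs: pd.DataFrame,
    matrix: PhenotypeMatrix,
    k: int = 20,
    min_nonmissing: int = 1000,
    same_tail: bool = True,
    missing_homozygote_policy: str = "skip",
    return_skipped: bool = False,
):
    """Emit (variant, analyte) pairs whose carriers all rank in one extreme tail.

    Analytes with at most ``min_nonmissing`` non-missing values are dropped
    first.  A pair in which any carrier lacks a measurement is skipped
    entirely under the default policy ("skip"; those pairs are routed to the
    missingness Fisher test) or evaluated on the measured carriers under
    policy "available".
    """
    if missing_homozygote_policy not in ("skip", "available"):
        raise ConfigurationError(
            f"unknown missing_homozygote_policy {missing_homozygote_policy!r}"
        )
    values, RH, RL, miss, nn, hom_rows, n_absent = _prepare(pcvs, matrix, min_nonmissing)
    analytes = np.array(values.columns)
    records, skipped = [], []
    for (vid, row), rows, absent in zip(pcvs.iterrows(), hom_rows, n_absent):
        if len(rows) == 0:
            continue
        sub_miss = miss[rows]
        any_missing = sub_miss.any(axis=0) | (absent > 0)
        measured_any = (~sub_miss).any(axis=0)
        if missing_homozygote_policy == "skip":
            eligible = ~any_missing
        else:
            eligible = measured_any
        with np.errstate(invalid="ignore"):
            in_high = np.where(sub_miss, True, RH[rows] <= k)
            in_low = np.where(sub_miss, True, RL[rows] <= k)
        hit_high = in_high.all(axis=0) & eligible & measured_any
        hit_low = in_low.all(axis=0) & eligible & measured_any
        if same_tail:
            hit_mixed = np.zeros(len(analytes), dtype=bool)
        else:
            either = np.where(sub_miss, True, np.minimum(RH[rows], RL[rows]) <= k)
            hit_mixed = either.all(axis=0) & eligible & measured_any & ~hit_high & ~hit_low
        for a in np.nonzero(hit_high | hit_low | hit_mixed)[0]:
            if hit_high[a]:
                tail = "high"
            elif hit_low[a]:
                tail = "low"
            else:
                tail = "mixed"
            R = RH if tail == "high" else RL
            ranks = [int(r) for r in R[rows, a] if not np.isnan(r)]
            records.append(
                (vid, row.get("gene"), analytes[a], matrix.platform, tail,
                 ranks, int(nn.iloc[a]))
            )
        if return_skipped:
            for a in np.nonzero(any_missing)[0]:
                skipped.append((vid, row.get("gene"), analytes[a], matrix.platform))
    assoc = pd.DataFrame(
        records,
        columns=["variant_id", "gene", "analyte", "platform", "tail", "ranks", "n_nonmissing"],
    )
    assoc["relevance"] = "none"
    if return_skipped:
        skipped_df = pd.DataFrame(
            skipped, columns=["variant_id", "gene", "analyte", "platform"]
        )
        return assoc, skipped_df
    return assoc


def count_hits(
    pcvs: pd.DataFrame,
    matrix: PhenotypeMatrix,
    k: int = 20,
    min_nonmissing: int = 1000,
    relevance_mask: np.ndarray | None = None,
) -> int:
    """Count emitted (variant, analyte) pairs under the default scan policy.

    Equivalent to ``len(scan(...))`` but without materializing ranks; used by
    the permutation FDR where only the count matters.  ``relevance_mask`` is
    an optional (n_pcv, n_analyte) boolean restricting which pairs count
    (analytes ordered as they survive the min_nonmissing filter).
    """
    values, RH, RL, miss, nn, hom_rows, n_absent = _prepare(pcvs, matrix, min_nonmissing)
    total = 0
    for vi, (rows, absent) in enumerate(zip(hom_rows, n_absent)):
        if len(rows) == 0:
            continue
        sub_miss = miss[rows]
        eligible = ~(sub_miss.any(axis=0) | (absent > 0))
        with np.errstate(invalid="ignore"):
            hit = (
                (np.where(sub_miss, True, RH[rows] <= k).all(axis=0)
                 | np.where(sub_miss, True, RL[rows] <= k).all(axis=0))
                & eligible
            )
        if relevance_mask is not None:
            hit &= relevance_mask[vi]
        total += int(hit.sum())
    return total


def relevance_mask(
    pcvs: pd.DataFrame, matrix: PhenotypeMatrix, maps: RelevanceMaps,
    min_nonmissing: int = 1000,
) -> np.ndarray:
    """(n_pcv, n_analyte) boolean: which pairs pass the in-cis / mQTL filter.

    Depends only on variant genes and analyte identity, so it is invariant
    under sample permutation and can be precomputed once for the FDR."""
    nn = matrix.n_nonmissing()
    analytes = [a for a in matrix.analytes if nn[a] > min_nonmissing]
    mask = np.zeros((len(pcvs), len(analytes)), dtype=bool)
    genes = pcvs["gene"].to_numpy()
    for ai, analyte in enumerate(analytes):
        if matrix.platform == "protein":
            linked = maps.protein_to_genes.get(analyte, frozenset())
            mask[:, ai] = [g in linked for g in genes]
        elif matrix.platform == "metabolite":
            mask[:, ai] = [(g, analyte) in maps.gene_metabolite_pairs for g in genes]
    return mask


def apply_relevance(associations: pd.DataFrame, maps: RelevanceMaps):
    """Tag each association as in_cis / mqtl / hmdb / none and split subsets.

    Returns (annotated, ppcvs, mpcvs).  A protein association is in-cis when
    the variant's gene is among the analyte's encoding genes (any match for
    multi-gene aptamers); a metabolite association is relevant when the
    (gene, metabolite) pair is in the curated table.
    """
    tags = []
    for _, row in associations.iterrows():
        tag = "none"
        if row["platform"] == "protein":
            if row["gene"] in maps.protein_to_genes.get(row["analyte"], frozenset()):
                tag = "in_cis"
        elif row["platform"] == "metabolite":
            pair = (row["gene"], row["analyte"])
            if pair in maps.gene_metabolite_pairs:
                src = maps.pair_sources.get(pair, "mGWAS")
                tag = "mqtl" if src == "mGWAS" else "hmdb"
        tags.append(tag)
    annotated = associations.copy()
    annotated["relevance"] = tags
    ppcvs = annotated[annotated["relevance"] == "in_cis"]
    mpcvs = annotated[annotated["relevance"].isin(["mqtl", "hmdb"])]
    return annotated, ppcvs, mpcvs


def sensitivity_scan(
    pcvs: pd.DataFrame,
    matrix: PhenotypeMatrix,
    rules=SENSITIVITY_RULES,
    min_nonmissing: int = 1000,
    maps: RelevanceMaps | None = None,
):
    """Re-run the scan under stricter thresholds: top-20/10/5 ranks or
    mean +/- 3 SD (population SD over non-missing values; SD=0 analytes
    emit nothing).  Returns (per-rule association dict, summary table)."""
    results = {}
    for rule in rules:
        if rule.startswith("top"):
            k = int(rule[3:])
            assoc = scan(pcvs, matrix, k=k, min_nonmissing=min_nonmissing)
        elif rule == "sd3":
            assoc = _sd_scan(pcvs, matrix, n_sd=3.0, min_nonmissing=min_nonmissing)
        else:
            raise ConfigurationError(f"unknown sensitivity rule {rule!r}")
        if maps is not None:
            assoc, _, _ = apply_relevance(assoc, maps)
        results[rule] = assoc
    rows = []
    for rule, assoc in results.items():
        n = len(assoc)
        n_p = int((assoc["relevance"] == "in_cis").sum()) if n else 0
        n_m = int(assoc["relevance"].isin(["mqtl", "hmdb"]).sum()) if n else 0
        rows.append((rule, n, n_p, n_m,
                     n_p / n if n else np.nan, n_m / n if n else np.nan))
    summary = pd.DataFrame(
        rows, columns=["rule", "n_associations", "n_ppcv", "n_mpcv",
                       "ppcv_fraction", "mpcv_fraction"],
    )
    return results, summary


def _sd_scan(pcvs, matrix, n_sd, min_nonmissing):
    nn = matrix.n_nonmissing()
    keep = nn[nn > min_nonmissing].index
    values = matrix.values[keep]
    V = values.to_numpy(float)
    mean = np.nanmean(V, axis=0)
    sd = np.nanstd(V, axis=0)  # population SD (divisor n)
    miss = np.isnan(V)
    RH, RL = _rank_matrices(values)
    sample_pos = {s: i for i, s in enumerate(values.index)}
    analytes = np.array(values.columns)
    records = []
    for vid, row in pcvs.iterrows():
        rows = np.array([sample_pos[s] for s in row["homozygote_ids"] if s in sample_pos])
        absent = len(row["homozygote_ids"]) - len(rows)
        if len(rows) == 0:
            continue
        sub = V[rows]
        sub_miss = miss[rows]
        eligible = ~(sub_miss.any(axis=0) | (absent > 0)) & (sd > 0)
        with np.errstate(invalid="ignore"):
            hit_high = np.where(sub_miss, True, sub > mean + n_sd * sd).all(axis=0) & eligible
            hit_low = np.where(sub_miss, True, sub < mean - n_sd * sd).all(axis=0) & eligible
        for a in np.nonzero(hit_high | hit_low)[0]:
            tail = "high" if hit_high[a] else "low"
            R = RH if tail == "high" else RL
            ranks = [int(r) for r in R[rows, a]]
            records.append(
                (vid, row.get("gene"), analytes[a], matrix.platform, tail,
                 ranks, int(nn[analytes[a]]))
            )
    assoc = pd.DataFrame(
        records,
        columns=["variant_id", "gene", "analyte", "platform", "tail", "ranks", "n_nonmissing"],
    )
    assoc["relevance"] = "none"
    return assoc
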