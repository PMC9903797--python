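"""Expected homozygote frequency (EHF) under consanguinity.

For a gene with cumulative loss-of-function allele frequency p in a
population whose genomes are autozygous over a fraction a on average,

    EHF = (1 - a) * p**2 + a * p

i.e. Hardy-Weinberg homozygosity outside autozygous tracts plus
identity-by-descent homozygosity inside them.  Because p >= p**2, EHF
grows linearly with a, which is why consanguineous cohorts reach complete
gene knockouts at far smaller sample sizes.

Two routes to p are provided: the "classic" cumulative allele frequency
(sum of rare high-confidence LoF allele frequencies per gene) and the
genotype-based p = 1 - sqrt(q) where q is the fraction of reference
individuals carrying no LoF allele.  The two routes differ on real
catalogs (the classic sum ignores haplotype sharing between variants);
both are exposed and neither is corrected toward the other.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def classic_caf(
    variants: pd.DataFrame,
    maf_cutoff: float = 0.05,
    lof_only: bool = True,
) -> pd.Series:
    """Per-gene cumulative allele frequency: sum of AF over rare qualifying
    variants (AF < maf_cutoff), capped at 1.

    ``variants`` needs columns gene and af, plus lof_confidence when
    ``lof_only`` (only rows tagged "HC" — high confidence — are summed;
    the tag is an input, never computed here).
    """
    v = variants
    mask = v["af"].to_numpy(float) < maf_cutoff
    if lof_only:
        if "lof_confidence" not in v.columns:
            raise ConfigurationError("lof_only requires a lof_confidence column")
        mask &= (v["lof_confidence"] == "HC").to_numpy()
    caf = v.loc[mask].groupby("gene")["af"].sum()
    over = caf > 1.0
    if over.any():
        logger.warning("CAF exceeded 1 for %d genes; capped", int(over.sum()))
        caf = caf.clip(upper=1.0)
    return caf.rename("caf_classic")


def caf_from_q(q):
    """Cumulative allele frequency from the no-LoF carrier fraction: p = 1 - sqrt(q)."""
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr < 0) | (q_arr > 1)):
        raise ConfigurationError("q must lie in [0, 1]")
    p = 1.0 - np.sqrt(q_arr)
    return float(p) if np.isscalar(q) or q_arr.ndim == 0 else p


def ehf(p, a):
    """Expected homozygote frequency (1-a) p^2 + a p for p, a in [0, 1]."""
    p_arr = np.asarray(p, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)) or np.any((a_arr < 0) | (a_arr > 1)):
        raise ConfigurationError("p and a must lie in [0, 1]")
    out = (1.0 - a_arr) * p_arr**2 + a_arr * p_arr
    scalar = np.isscalar(p) and np.isscalar(a)
    return float(out) if scalar else out


def min_cohort_size(ehf_value: float, probabilistic: bool = False, prob: float = 0.95):
    """Smallest cohort expected to contain at least one homozygote.

    Default rule: smallest N with N * EHF >= 1, i.e. ceil(1/EHF).  With
    ``probabilistic``, smallest N with 1 - (1-EHF)^N >= prob.  EHF = 0 gives
    infinity.
    """
    if ehf_value <= 0:
        return math.inf
    if not probabilistic:
        return math.ceil(1.0 / ehf_value)
    return math.ceil(math.log1p(-prob) / math.log1p(-ehf_value))


def ehf_table(caf: pd.Series, a: float, q: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene EHF records from classic CAF (and optionally the q route)."""
    out = pd.DataFrame({"caf_classic": caf})
    out["a_roh"] = a
    out["ehf"] = ehf(caf.to_numpy(), a)
    out["min_cohort_for_one_hom"] = [min_cohort_size(e) for e in out["ehf"]]
    if q is not None:
        out["q_no_lof"] = q.reindex(out.index)
        out["caf_from_q"] = caf_from_q(out["q_no_lof"].fillna(1.0).to_numpy())
    return out


def design_curve(
    ehf_by_gene: pd.Series,
    cohort_sizes,
    probabilistic: bool = False,
    prob: float = 0.95,
) -> pd.DataFrame:
    """Genes with at least one expected homozygote as a function of cohort size.

    For each N, counts genes whose minimum cohort size (see
    :func:`min_cohort_size`) is <= N.  The curve is non-decreasing in N by
    construction.
    """
    min_n = np.array([
        min_cohort_size(e, probabilistic=probabilistic, prob=prob)
        for e in ehf_by_gene
    ])
    rows = [
        (int(n), int((min_n <= n).sum())) for n in sorted(cohort_sizes)
    ]
    return pd.DataFrame(rows, columns=["cohort_size", "genes_with_expected_homozygote"])
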