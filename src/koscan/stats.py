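"""Significance machinery for the extreme-tail scan.

* Permutation FDR: sample identifiers are permuted as whole records (one
  permutation of the phenotype rows per replicate, preserving cross-analyte
  correlation), the identical scan is re-run, and the FDR is the mean
  permuted hit count divided by the observed hit count.
* Approximate rank-product p-value: for a variant with homozygote extreme
  ranks R_1..R_k over N non-missing measurements, P = prod_i R_i / N,
  capped at 1.  Tail direction never enters the p-value.  A variant is
  significant when P < alpha / M with M the total phenotype count.
* Fisher exact test on the genotype-group x missing/observed contingency
  table, for deciding whether homozygotes' missing analyte values are
  missing by chance (under limit-of-detection censoring they are not).
* QQ data for inflation checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .errors import ConfigurationError
from .scan import PhenotypeMatrix, RelevanceMaps, count_hits, relevance_mask


@dataclass
class PermutationFDRResult:
    observed_count: int
    permuted_counts: list[int]
    seed: int
    b_permutations: int = 100

    @property
    def permuted_mean(self) -> float:
        return float(np.mean(self.permuted_counts))

    @property
    def fdr(self) -> float:
        """mean permuted / observed; NaN (undefined) when nothing was observed."""
        if self.observed_count == 0:
            return math.nan
        return self.permuted_mean / self.observed_count

    def to_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "permuted_mean": self.permuted_mean,
            "fdr": None if math.isnan(self.fdr) else self.fdr,
            "b_permutations": self.b_permutations,
            "seed": self.seed,
            "permuted_counts": list(map(int, self.permuted_counts)),
        }


def permutation_fdr(
    pcvs: pd.DataFrame,
    matrix: PhenotypeMatrix,
    k: int = 20,
    min_nonmissing: int = 1000,
    B: int = 100,
    seed: int = 0,
    maps: RelevanceMaps | None = None,
) -> PermutationFDRResult:
    """Estimate the scan FDR from B whole-matrix sample-label permutations.

    When ``maps`` is given the relevance filter (in-cis / mQTL) is applied
    inside every permutation as well, so the estimate refers to the
    relevance-filtered hit set.
    """
    if B < 1:
        raise ConfigurationError("B must be at least 1")
    mask = None
    if maps is not None:
        mask = relevance_mask(pcvs, matrix, maps, min_nonmissing=min_nonmissing)
    observed = count_hits(pcvs, matrix, k=k, min_nonmissing=min_nonmissing,
                          relevance_mask=mask)
    rng = np.random.default_rng(seed)
    n = len(matrix.values)
    counts = []
    for _ in range(B):
        perm = rng.permutation(n)
        permuted = PhenotypeMatrix(
            values=pd.DataFrame(
                matrix.values.to_numpy()[perm],
                index=matrix.values.index,
                columns=matrix.values.columns,
            ),
            platform=matrix.platform,
        )
        counts.append(
            count_hits(pcvs, permuted, k=k, min_nonmissing=min_nonmissing,
                       relevance_mask=mask)
        )
    return PermutationFDRResult(
        observed_count=observed, permuted_counts=counts, seed=seed, b_permutations=B
    )


def approx_pvalue(ranks, n_nonmissing: int, two_sided_halving: bool = False) -> float:
    """Product-of-extreme-ranks approximate p-value.

    P = prod_i R_i / N with N = n_nonmissing (default) or n_nonmissing / 2
    when ``two_sided_halving`` — the halving accounts for testing both tails
    but the undivided convention is the default because it matches the
    published worked example (1*2*3 / 2935^3).  Capped at 1.
    """
    ranks = list(ranks)
    if not ranks:
        raise ConfigurationError("at least one extreme rank is required")
    if any(r < 1 for r in ranks):
        raise ConfigurationError("extreme ranks start at 1")
    if any(r > n_nonmissing for r in ranks):
        raise ConfigurationError("a rank exceeds the number of non-missing values")
    N = n_nonmissing / 2.0 if two_sided_halving else float(n_nonmissing)
    log_p = sum(math.log(r) - math.log(N) for r in ranks)
    return min(1.0, math.exp(log_p))


def significance_threshold(m_phenotypes: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / M over the phenotype count."""
    if m_phenotypes < 1:
        raise ConfigurationError("m_phenotypes must be at least 1")
    return alpha / m_phenotypes


def gene_based_threshold(n_genes: int, n_phenotypes: int, alpha: float = 0.05) -> float:
    """Exome-wide Bonferroni threshold alpha / (genes x phenotypes)."""
    if n_genes < 1 or n_phenotypes < 1:
        raise ConfigurationError("counts must be at least 1")
    return alpha / (n_genes * n_phenotypes)


def annotate_associations(
    associations: pd.DataFrame,
    m_phenotypes: int,
    alpha: float = 0.05,
    two_sided_halving: bool = False,
) -> pd.DataFrame:
    """Attach approx_p and the Bonferroni significance flag to scan output."""
    out = associations.copy()
    threshold = significance_threshold(m_phenotypes, alpha)
    out["approx_p"] = [
        approx_pvalue(row["ranks"], row["n_nonmissing"], two_sided_halving)
        for _, row in associations.iterrows()
    ]
    out["significant"] = out["approx_p"] < threshold
    return out


def _exact_2xk(table: np.ndarray, tol: float = 1e-9) -> float:
    """Two-sided Fisher exact p for a 2 x K table by enumeration.

    All tables with the observed margins are enumerated (vectorized over a
    grid for K=3); two-sidedness by the point-probability rule: sum the
    probabilities of tables no more probable than the observed one.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2:
        raise ConfigurationError("expected a 2 x K table")
    col_tot = table.sum(axis=0)
    m = int(table[0].sum())
    N = int(table.sum())
    log_denom = gammaln(N + 1) - gammaln(m + 1) - gammaln(N - m + 1)

    def log_binom(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    K = table.shape[1]
    if K == 1:
        return 1.0
    if K == 2:
        x0 = np.arange(max(0, m - col_tot[1]), min(col_tot[0], m) + 1)
        x1 = m - x0
        logp = log_binom(col_tot[0], x0) + log_binom(col_tot[1], x1) - log_denom
    elif K == 3:
        g0 = np.arange(0, min(col_tot[0], m) + 1)
        g1 = np.arange(0, min(col_tot[1], m) + 1)
        X0, X1 = np.meshgrid(g0, g1, indexing="ij")
        X2 = m - X0 - X1
        valid = (X2 >= 0) & (X2 <= col_tot[2])
        logp = np.where(
            valid,
            log_binom(col_tot[0], X0) + log_binom(col_tot[1], X1)
            + log_binom(col_tot[2], np.clip(X2, 0, None)) - log_denom,
            -np.inf,
        )[valid]
    else:
        raise ConfigurationError("enumeration implemented for K <= 3 groups")
    log_obs = sum(log_binom(col_tot[j], table[0, j]) for j in range(K)) - log_denom
    p = float(np.exp(logp[logp <= log_obs + tol]).sum())
    return min(1.0, p)


def missingness_fisher(genotype_groups, missing_flags) -> float:
    """Fisher exact test of missingness across genotype groups.

    ``genotype_groups``: per-sample labels (wt / het / hom, any hashable);
    ``missing_flags``: per-sample booleans.  Empty genotype groups are
    dropped; a single non-empty group leaves the test undefined (NaN).
    2x2 tables go through scipy; 2x3 tables through margin enumeration.
    """
    groups = pd.Series(list(genotype_groups))
    missing = np.asarray(list(missing_flags), dtype=bool)
    if len(groups) != len(missing):
        raise ConfigurationError("groups and flags must align")
    labels = [g for g in pd.unique(groups) if (groups == g).any()]
    cols = []
    for g in labels:
        in_g = (groups == g).to_numpy()
        cols.append((int((in_g & missing).sum()), int((in_g & ~missing).sum())))
    table = np.array(cols).T  # rows: missing, observed
    nonempty = table.sum(axis=0) > 0
    table = table[:, nonempty]
    if table.shape[1] < 2:
        return math.nan
    if not missing.any():
        return 1.0
    if table.shape[1] == 2:
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    return _exact_2xk(table)


def qq_data(p_values) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 p quantiles plus a median-ratio inflation
    summary (1 for a well-calibrated uniform null)."""
    p = np.sort(np.asarray(list(p_values), dtype=float))
    if len(p) == 0:
        raise ConfigurationError("at least one p-value is required")
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(np.clip(p, 1e-300, 1.0))[::-1]
    df = pd.DataFrame({"expected": expected, "observed": observed})
    med_exp = float(np.median(expected))
    inflation = float(np.median(observed) / med_exp) if med_exp > 0 else math.nan
    return df, inflation
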