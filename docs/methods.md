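# Methods

This note records the models, conventions and numerical choices behind
`koscan`, and what the synthetic cohort does and does not emulate.

## Cohort model and synthetic data

The analysis targets a consanguineous cohort with whole-genome genotypes
and three phenotype layers (affinity proteomics, untargeted metabolomics,
clinical chemistry). The generator (`koscan.simulate`) reproduces the
statistical structure the downstream stages rely on, not the biology that
produces it:

- **Autozygosity is planted directly.** Each sample receives ROH
  segments from an alternating renewal process: segment lengths are
  exponential with mean `roh_segment_mean_length` (default 1.5 Mb),
  floored at 10 kb; the gap mean is set so the stationary occupancy
  equals `roh_fraction_mean`. The floor shifts the effective segment
  mean to c + m·e^(−c/m) (c = 10 kb), which the gap calculation uses, so
  the realized genome fraction in ROH is unbiased (verified to ±0.005 by
  Monte Carlo). Pedigree simulation would produce the same testable
  contract at much higher cost.
- **Genotypes.** Outside ROH, Hardy–Weinberg draws at each variant's
  allele frequency (log-uniform on [5e-4, 0.5] by default — rare
  variants supply the 1–5-homozygote PCVs, common ones make ROH
  detectable). Inside ROH every site is homozygous: alt with probability
  p, ref otherwise. No linkage disequilibrium, recombination maps or
  mutation models (declared non-goals).
- **Planted knockouts** force exactly `n_homozygotes` carriers at one
  variant of the chosen gene (external MAF set to 0.001, impact HIGH or
  MODERATE) and shift each carrier's value of each affected analyte by
  `effect_size_sd` standard deviations.
- **Phenotypes** are independent standard normals (optional
  block-correlation via a shared factor, for exercising the permutation
  FDR under correlated analytes). Metabolites are then left-censored at
  the per-analyte `lod_censor_quantile` (default 0.10) — the
  missing-not-at-random mechanism that limit-of-detection censoring
  produces. An optional MCAR overlay exists; the default is pure
  left-censoring.
- **Defaults** mirror the emulated study conditions: 2,935 samples,
  32,868 candidate variants, mean PGROH 3.52%, platform sizes 1,305
  proteins / 1,159 metabolites / 71 assays. Tests and the acceptance
  script pass smaller explicit configs (given below).

What passing tests on this cohort do **not** show: robustness to LD
between variants, to population stratification, to batch effects or
non-normal analyte distributions, or to annotation error — real-data
features outside the generator.

## PCV selection

Impact ∈ {HIGH, MODERATE, UORF} (upstream-ORF-creating variants are
admitted but tallied separately, since they come from a different
annotation route), alt-homozygote count in [1, 5] counting non-missing
genotypes only, external MAF < 0.05 strict. Variants absent from the
external reference are retained. When several reference sub-population
frequencies are supplied, the maximum is used (the conservative reading
of a single cutoff over multiple populations). The annotation join is an
exact (chrom, pos, ref, alt) match: inputs are pre-normalized,
pre-split biallelic VCFs; no left-alignment is attempted.

## Inbreeding coefficient

F = (O − E)/(L − E) per sample with E = Σᵢ (1 − 2pᵢ(1 − pᵢ)) over that
sample's non-missing sites. No small-sample correction of E is applied
(tools differ here; the uncorrected estimator is documented so results
are reproducible). Allele frequencies default to cohort estimates; F is
site-list dependent, so a different site panel gives a different F.
All-monomorphic samples get NaN.

## ROH hidden Markov model

Two states. Emissions at error rate e (default 1e-4):
HW: (1−e)·[(1−p)², 2p(1−p), p²] + e/3;
AZ: (1−e)·[1−p, 0, p] + e/3 (a het in AZ only via error).
Missing genotypes are uninformative (emission 1 in both states).
Transition (switch) probability between consecutive sites at distance d:
1 − exp(−rate·d), rates defaulting to 1e-8/bp in both directions — the
conventional setting for exome-restricted ROH calling. Initial state
probabilities 0.5/0.5. Decoding is Viterbi (segments, not site
posteriors, are the downstream unit); the 10 kb minimum is applied after
decoding, so reported ROH are the "long" tracts recent consanguinity
produces. Distances are physical bp; when a genetic map is supplied,
distances are rescaled (1 cM ≈ 1 Mb equivalent). Allele frequencies are
clamped to [1e-9, 1−1e-9] before taking logs. Exact equality with a
full-path enumeration oracle is asserted for ≤12-site instances.

PGROH divides clipped segment length by the supplied target-region
length (the regions the caller assessed), not the genome, so cohorts are
comparable only when computed over identical regions.

Boundary resolution is limited by site spacing: at 10 kb spacing the
detected PGROH under-reads the planted fraction by roughly 10% (segment
ends blur by about half a gap; sub-resolution segments near the 10 kb
floor are invisible). The acceptance script therefore measures cohort
PGROH at ~5 kb spacing and base-pair recovery at ~1.4 kb spacing.

## Extreme-tail scan

Ordinal extreme ranks per analyte (rank 1 = most extreme; ties broken by
ascending sample id, making runs deterministic). A pair is emitted iff
every carrier's rank ≤ k in a single tail; k = 20 is absolute, not a
quantile (an optional flag scales k ∝ n for differently sized synthetic
cohorts; off by default). The rank boundary is inclusive. Carriers split
across tails do not count (a knockout shifts one direction); a
permissive mixed-tail mode exists behind a flag. Analytes need more than
`min_nonmissing` (default 1,000) non-missing values — applied to
metabolites and laboratory data; proteins are assumed complete
(configurable). A pair in which any carrier lacks a measurement is
skipped entirely and routed to the missingness Fisher test; an
"available" mode evaluates the measured carriers instead, and a
missing-equals-zero re-run mode covers the left-censoring
interpretation. The mean±3SD sensitivity rule uses population SD
(divisor n) over non-missing values; SD = 0 analytes emit nothing.

Under an exchangeable null the expected emitted-pair count for a variant
with m carriers and an analyte with n non-missing values is
2·∏ᵢ₌₀^{m−1}(k−i)/(n−i); the scan is checked against this closed form
and against an exhaustive double-loop reference.

## Significance

- **Permutation FDR**: one whole-matrix permutation of sample
  identifiers per replicate (preserving cross-analyte correlation),
  B = 100 by default; FDR = mean permuted count / observed count,
  undefined (NaN) when nothing is observed. The relevance filter is
  applied inside each permutation when estimating the pPCV/mPCV FDR;
  both filtered and unfiltered estimates are reported side by side.
- **Rank-product p-value**: P = ∏ᵢ Rᵢ/N capped at 1. N is the
  non-missing count, undivided, by default; the halved-N variant
  (motivated by testing both tails) is a flag. The undivided convention
  is the default because it is the one the method's printed worked
  example uses. Tail direction never enters P. Significance is
  P < α/M with M the configured total phenotype count (raw platform
  sizes, not post-filter counts).
- **Fisher missingness test**: genotype group × {missing, observed}
  table; empty groups dropped; one group → undefined. 2×2 via
  scipy, 2×3 via vectorized enumeration of all margin-consistent tables
  with the point-probability two-sided rule (stated explicitly because
  doubling-based definitions differ).
- **QQ/inflation**: observed vs expected −log10 quantiles with a
  median-ratio summary (≈1 for a calibrated null).

## Problem sizes used in tests and the acceptance script

Chosen to keep the default runs fast while leaving every estimate
well-determined: null-FDR calibration on five cohorts of 1,000 samples ×
500 PCVs × 200 analytes with B = 100 (the estimate's SE is ~1% there);
knockout recovery over 20 seeds at 600 samples with 1–5 carriers and
|effect| = 5 SD; PGROH/F on 500 samples over 60 Mb of target regions;
ROH base-pair recovery on a 10 Mb region at ~1.4 kb spacing. A 5 SD
shift places a carrier beyond the bottom-20 threshold of a
1,000-sample normal cohort with failure probability ~2e-3, so recovery
failures are dominated by metabolite LOD censoring of strongly lowered
values — which the skip-pair policy handles by design.

## Known limitations

- The HMM is not a re-implementation of any particular caller's
  numerics; segment boundaries can differ from other tools by a few
  inter-site gaps.
- CAF from summed allele frequencies ignores haplotype sharing between
  LoF variants and therefore overestimates p relative to
  individual-genotype estimates; both routes are exposed, no
  reconciliation is attempted.
- The scan estimates no effect sizes and adjusts for no covariates;
  heterozygote-trend comparisons are out of scope.
- Gene-based burden/SKAT tests are not implemented (external tooling in
  the original workflow).
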