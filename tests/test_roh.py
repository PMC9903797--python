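"""Inbreeding F, ROH Viterbi decoding, PGROH interval arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from koscan.errors import IntegrityError
from koscan.roh import (
    RohHmmParams,
    _emission_logs,
    detect_roh,
    inbreeding_f,
    pcv_roh_overlap,
    pg_roh,
    viterbi_roh,
)
from conftest import make_dataset


# ---------------------------------------------------------------- F -----

def test_f_is_minus_one_for_fully_heterozygous_sample():
    # all sites p=0.5 and the sample het everywhere: O=0, E=L/2, F=-1
    G = np.ones((20, 1), dtype=np.int8)
    ds = make_dataset(G)
    f = inbreeding_f(ds, allele_freqs=np.full(20, 0.5))
    assert f.iloc[0] == pytest.approx(-1.0)


def test_f_is_one_for_fully_homozygous_sample():
    G = np.full((20, 1), 2, dtype=np.int8)
    ds = make_dataset(G)
    f = inbreeding_f(ds, allele_freqs=np.full(20, 0.3))
    assert f.iloc[0] == pytest.approx(1.0)


def test_f_matches_sitewise_brute_force():
    rng = np.random.default_rng(4)
    p = rng.uniform(0.05, 0.95, 20)
    G = rng.integers(0, 3, size=(20, 3)).astype(np.int8)
    G[5, 1] = -1  # one missing call
    ds = make_dataset(G)
    f = inbreeding_f(ds, allele_freqs=p)
    for j in range(3):
        O = E = L = 0.0
        for i in range(20):
            if G[i, j] < 0:
                continue
            L += 1
            O += 1 if G[i, j] != 1 else 0
            E += 1 - 2 * p[i] * (1 - p[i])
        assert f.iloc[j] == pytest.approx((O - E) / (L - E))


def test_f_undefined_when_all_sites_monomorphic():
    G = np.zeros((10, 2), dtype=np.int8)
    ds = make_dataset(G)
    f = inbreeding_f(ds, allele_freqs=np.zeros(10))
    assert f.isna().all()


def test_f_near_zero_on_outbred_hwe_cohort():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.1, 0.5, 400)
    n = 150
    G = (rng.random((400, n)) < p[:, None]).astype(np.int8) + (
        rng.random((400, n)) < p[:, None]
    ).astype(np.int8)
    ds = make_dataset(G)
    f = inbreeding_f(ds, allele_freqs=p)
    se = f.std() / np.sqrt(n)
    assert abs(f.mean()) < 3 * se + 1e-3


def test_f_monotone_in_planted_roh_fraction():
    from scipy.stats import spearmanr

    from koscan.simulate import SimulationConfig, simulate_genotypes

    levels = [0.02, 0.05, 0.1, 0.2, 0.35]
    mean_f = []
    for frac in levels:
        cfg = SimulationConfig(
            n_samples=80, n_variants=1200, n_genes=100,
            target_regions=(("1", 0, 6_000_000),),
            roh_fraction_mean=frac, roh_segment_mean_length=500_000.0,
            analyte_counts={"protein": 2, "metabolite": 2, "lab": 2},
            seed=31,
        )
        ds, _ = simulate_genotypes(cfg)
        mean_f.append(inbreeding_f(ds).mean())
    r, _ = spearmanr(levels, mean_f)
    assert r > 0.9


# ------------------------------------------------------------ Viterbi ----

def _enumerate_best_path(positions, genotypes, freqs, params):
    """Score every 2^n state path explicitly; independent of the Viterbi code."""
    n = len(positions)
    le_hw, le_az = _emission_logs(genotypes, freqs, params.genotype_error)
    d = np.diff(np.asarray(positions, float))
    t_ha = 1 - np.exp(-params.hw_to_az_rate * d)
    t_ah = 1 - np.exp(-params.az_to_hw_rate * d)
    best, best_path = -np.inf, None
    for path in itertools.product([0, 1], repeat=n):
        score = np.log(0.5) + (le_az[0] if path[0] else le_hw[0])
        for i in range(1, n):
            prev, cur = path[i - 1], path[i]
            if prev == 0:
                score += np.log(t_ha[i - 1] if cur == 1 else 1 - t_ha[i - 1])
            else:
                score += np.log(t_ah[i - 1] if cur == 0 else 1 - t_ah[i - 1])
            score += le_az[i] if cur else le_hw[i]
        if score > best:
            best, best_path = score, path
    return np.array(best_path)


@pytest.mark.parametrize("seed", range(6))
def test_viterbi_equals_exhaustive_path_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = 11
    positions = np.cumsum(rng.integers(500, 5000, n))
    freqs = rng.uniform(0.05, 0.95, n)
    genotypes = rng.integers(0, 3, n).astype(np.int8)
    params = RohHmmParams(az_to_hw_rate=1e-5, hw_to_az_rate=1e-5,
                          genotype_error=1e-3)
    path, _ = viterbi_roh(positions, genotypes, freqs, params)
    expected = _enumerate_best_path(positions, genotypes, freqs, params)
    np.testing.assert_array_equal(path, expected)


def test_all_heterozygous_sample_has_no_segments():
    n = 200
    positions = np.arange(1, n + 1) * 1000
    params = RohHmmParams()
    path, segs = viterbi_roh(positions, np.ones(n, np.int8),
                             np.full(n, 0.5), params)
    assert segs == []


def test_homozygous_block_recovered_within_one_gap():
    n = 200
    positions = np.arange(1, n + 1) * 1000
    g = np.ones(n, np.int8)
    g[50:150] = np.where(np.arange(100) % 2 == 0, 0, 2)  # homozygous mix
    path, segs = viterbi_roh(positions, g, np.full(n, 0.5), RohHmmParams())
    assert len(segs) == 1
    start, end, n_sites, _ = segs[0]
    # block spans sites 50..149 (1-based pos 51000..150000) +/- one gap
    assert abs(start - 50_000) <= 1000
    assert abs(end - 150_000) <= 1000
    assert n_sites == pytest.approx(100, abs=1)


def test_unsorted_positions_rejected():
    with pytest.raises(IntegrityError):
        viterbi_roh([3000, 1000], np.zeros(2, np.int8), [0.5, 0.5], RohHmmParams())


def test_min_length_filter_applied_after_decoding():
    # a strong but short homozygous block is decoded yet filtered out
    n = 60
    positions = np.arange(1, n + 1) * 100  # 100 bp spacing: block < 10 kb
    g = np.ones(n, np.int8)
    g[20:40] = 2
    ds = make_dataset(g[:, None], positions=positions)
    segs = detect_roh(ds, RohHmmParams(hw_to_az_rate=1e-4, az_to_hw_rate=1e-4),
                      allele_freqs=np.full(n, 0.5))
    assert len(segs) == 0


def test_detected_roh_matches_planted_truth_on_dense_sites():
    from koscan.simulate import SimulationConfig, simulate_genotypes

    cfg = SimulationConfig(
        n_samples=12, n_variants=5000, n_genes=50,
        target_regions=(("1", 0, 10_000_000),),
        roh_fraction_mean=0.1, roh_segment_mean_length=1_000_000.0,
        analyte_counts={"protein": 2, "metabolite": 2, "lab": 2},
        seed=17,
    )
    ds, truth = simulate_genotypes(cfg)
    segs = detect_roh(ds, RohHmmParams(), allele_freqs=ds.variants["af"].to_numpy())
    inter = union = 0.0
    for s in ds.samples:
        t_iv = [(r["start"], r["end"]) for _, r in
                truth["roh"][truth["roh"]["sample"] == s].iterrows()]
        d_iv = [(r["start"], r["end"]) for _, r in
                segs[segs["sample"] == s].iterrows()]
        grid = np.zeros(10_000_000 // 1000, dtype=np.int8)
        for a, b in t_iv:
            grid[a // 1000:b // 1000] |= 1
        for a, b in d_iv:
            grid[a // 1000:b // 1000] |= 2
        inter += np.sum(grid == 3)
        union += np.sum(grid > 0)
    assert union > 0
    assert inter / union >= 0.85


# ------------------------------------------------------------- PGROH ----

REGIONS = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1_000_000]})


def _segframe(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end"])


def test_pg_roh_trivial_cases():
    assert pg_roh(_segframe([]), REGIONS, samples=["a"]).iloc[0] == 0.0
    full = _segframe([("a", "1", 0, 1_000_000)])
    assert pg_roh(full, REGIONS, samples=["a"]).iloc[0] == 1.0


def test_pg_roh_clips_boundary_overlap():
    segs = _segframe([("a", "1", 900_000, 1_200_000)])
    # only 100 kb of the segment lies inside the region
    assert pg_roh(segs, REGIONS, samples=["a"]).iloc[0] == pytest.approx(0.1)


def test_pg_roh_invariant_to_segment_splitting():
    whole = _segframe([("a", "1", 100_000, 400_000)])
    split = _segframe([("a", "1", 100_000, 250_000), ("a", "1", 250_000, 400_000)])
    assert pg_roh(whole, REGIONS, samples=["a"]).iloc[0] == pytest.approx(
        pg_roh(split, REGIONS, samples=["a"]).iloc[0]
    )


def test_pcv_roh_overlap_counts_and_correlation(small_cohort):
    from koscan.pcv import select_pcvs

    ds = small_cohort.dataset
    pcvs = select_pcvs(ds)
    truth_roh = small_cohort.truth["roh"].copy()
    profile, fraction, (r, pval) = pcv_roh_overlap(
        pcvs, truth_roh, ds.samples, small_cohort.truth["pg_roh"]
    )
    assert (profile["n_hom_pcvs_in_roh"] <= profile["n_hom_pcvs"]).all()
    assert 0 < fraction <= 1
    # autozygosity concentrates homozygous PCVs: positive correlation
    assert r > 0 and pval < 0.01


def test_pcv_roh_overlap_extremes(small_cohort):
    from koscan.pcv import select_pcvs

    ds = small_cohort.dataset
    pcvs = select_pcvs(ds)
    empty = _segframe([])
    _, fraction, _ = pcv_roh_overlap(pcvs, empty, ds.samples)
    assert fraction == 0.0
    everything = _segframe([(s, "1", 0, 10**9) for s in ds.samples])
    _, fraction, _ = pcv_roh_overlap(pcvs, everything, ds.samples)
    assert fraction == 1.0
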