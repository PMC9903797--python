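"""Extreme-tail scan: rank conventions, oracle equivalence, relevance filters."""

import numpy as np
import pandas as pd
import pytest

from koscan.scan import (
    PhenotypeMatrix,
    RelevanceMaps,
    apply_relevance,
    rank_analyte,
    scan,
    sensitivity_scan,
)


def _pcv_frame(rows):
    """rows: list of (variant_id, gene, homozygote_ids)."""
    df = pd.DataFrame(rows, columns=["variant_id", "gene", "homozygote_ids"])
    return df.set_index("variant_id")


def _matrix(values, samples=None, platform="protein"):
    V = np.asarray(values, dtype=float)
    samples = samples or [f"s{i:03d}" for i in range(V.shape[0])]
    cols = [f"A{j}" for j in range(V.shape[1])]
    return PhenotypeMatrix(
        values=pd.DataFrame(V, index=samples, columns=cols), platform=platform
    )


# ------------------------------------------------------------- ranks ----

def test_rank_analyte_directions():
    s = pd.Series([5.0, 3.0, 9.0], index=["a", "b", "c"])
    assert rank_analyte(s, "high").tolist() == [2, 3, 1]
    assert rank_analyte(s, "low").tolist() == [2, 1, 3]


def test_rank_ties_break_by_sample_id():
    s = pd.Series([4.0, 4.0], index=["b", "a"])
    ranks = rank_analyte(s, "high")
    assert ranks["a"] == 1 and ranks["b"] == 2


def test_rank_reversal_identity_on_untied_vectors():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 50))
        s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        total = rank_analyte(s, "high") + rank_analyte(s, "low")
        assert (total == n + 1).all()


def test_rank_skips_missing_values():
    s = pd.Series([1.0, np.nan, 3.0], index=["a", "b", "c"])
    ranks = rank_analyte(s, "high")
    assert np.isnan(ranks["b"]) and ranks["c"] == 1 and ranks["a"] == 2


# -------------------------------------------------------------- scan ----

def test_scan_rank_boundary_is_inclusive():
    rng = np.random.default_rng(1)
    V = rng.normal(size=(100, 1))
    samples = [f"s{i:03d}" for i in range(100)]
    m = _matrix(V, samples)
    order = np.argsort(-V[:, 0])
    at20, at21 = samples[order[19]], samples[order[20]]
    pcvs = _pcv_frame([("v1", "G1", [at20]), ("v2", "G2", [at21]),
                       ("v3", "G3", [at20, at21])])
    assoc = scan(pcvs, m, k=20, min_nonmissing=0)
    emitted = set(assoc["variant_id"])
    assert "v1" in emitted       # rank 20 qualifies
    assert "v2" not in emitted   # rank 21 does not
    assert "v3" not in emitted   # one carrier outside the tail sinks the pair


def _brute_force_scan(pcvs, matrix, k, min_nonmissing):
    """Exhaustive double-loop reference, independent of the vectorized path."""
    hits = set()
    values = matrix.values
    for analyte in values.columns:
        col = values[analyte]
        if col.notna().sum() <= min_nonmissing:
            continue
        rh = rank_analyte(col, "high")
        rl = rank_analyte(col, "low")
        for vid, row in pcvs.iterrows():
            homs = row["homozygote_ids"]
            vals = [col.get(s, np.nan) for s in homs]
            if any(np.isnan(v) for v in vals):
                continue  # skip-pair policy
            if all(rh[s] <= k for s in homs) or all(rl[s] <= k for s in homs):
                hits.add((vid, analyte))
    return hits


def test_scan_equals_brute_force_reference():
    rng = np.random.default_rng(2)
    n, A = 200, 30
    V = rng.normal(size=(n, A))
    V[rng.random((n, A)) < 0.05] = np.nan
    samples = [f"s{i:03d}" for i in range(n)]
    m = _matrix(V, samples, platform="metabolite")
    rows = []
    for i in range(50):
        n_hom = int(rng.integers(1, 6))
        homs = list(rng.choice(samples, size=n_hom, replace=False))
        rows.append((f"v{i}", f"G{i}", homs))
    pcvs = _pcv_frame(rows)
    assoc = scan(pcvs, m, k=20, min_nonmissing=100)
    got = set(zip(assoc["variant_id"], assoc["analyte"]))
    assert got == _brute_force_scan(pcvs, m, k=20, min_nonmissing=100)


def test_scan_invariant_to_row_and_column_order():
    rng = np.random.default_rng(3)
    V = rng.normal(size=(80, 10))
    samples = [f"s{i:03d}" for i in range(80)]
    m = _matrix(V, samples)
    pcvs = _pcv_frame(
        [(f"v{i}", f"G{i}", list(rng.choice(samples, 2, replace=False)))
         for i in range(30)]
    )
    base = scan(pcvs, m, k=20, min_nonmissing=0)
    perm_rows = rng.permutation(80)
    perm_cols = rng.permutation(10)
    shuffled = PhenotypeMatrix(
        values=m.values.iloc[perm_rows, perm_cols], platform="protein"
    )
    again = scan(pcvs, shuffled, k=20, min_nonmissing=0)
    key = lambda df: set(zip(df["variant_id"], df["analyte"], df["tail"]))
    assert key(base) == key(again)


def test_null_hit_count_matches_closed_form():
    # single-homozygote variants on a null matrix: P(pair emitted) = 2k/n
    rng = np.random.default_rng(4)
    n, A, k, n_var = 300, 40, 10, 40
    samples = [f"s{i:03d}" for i in range(n)]
    counts = []
    for rep in range(60):
        V = rng.normal(size=(n, A))
        m = _matrix(V, samples)
        pcvs = _pcv_frame(
            [(f"v{i}", f"G{i}", [samples[rng.integers(0, n)]]) for i in range(n_var)]
        )
        counts.append(len(scan(pcvs, m, k=k, min_nonmissing=0)))
    expected = n_var * A * 2 * k / n
    se = np.sqrt(expected / 60)  # Poisson-scale SE of the mean
    assert abs(np.mean(counts) - expected) < 4 * se


def test_missing_homozygote_policies():
    V = np.random.default_rng(5).normal(size=(50, 1))
    samples = [f"s{i:03d}" for i in range(50)]
    # force the two carriers extreme, then censor one of them
    V[0, 0], V[1, 0] = 9.0, 8.0
    V[1, 0] = np.nan
    m = _matrix(V, samples)
    pcvs = _pcv_frame([("v0", "G0", [samples[0], samples[1]])])
    skip, skipped = scan(pcvs, m, k=20, min_nonmissing=0, return_skipped=True)
    assert len(skip) == 0 and len(skipped) == 1  # routed to the Fisher test
    avail = scan(pcvs, m, k=20, min_nonmissing=0,
                 missing_homozygote_policy="available")
    assert len(avail) == 1 and avail["ranks"].iloc[0] == [1]


def test_min_nonmissing_drops_sparse_analytes():
    V = np.random.default_rng(6).normal(size=(30, 2))
    V[10:, 1] = np.nan
    m = _matrix(V, platform="metabolite")
    samples = list(m.values.index)
    pcvs = _pcv_frame([("v0", "G0", [samples[0]])])
    assoc = scan(pcvs, m, k=30, min_nonmissing=15)
    assert set(assoc["analyte"]) <= {"A0"}


# --------------------------------------------------------- relevance ----

def test_apply_relevance_in_cis_and_mqtl():
    assoc = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3", "v4"],
            "gene": ["G", "G", "G", "G"],
            "analyte": ["P_enc_by_G", "P_other", "M_linked_G", "M_linked_H"],
            "platform": ["protein", "protein", "metabolite", "metabolite"],
            "tail": ["low"] * 4,
            "ranks": [[1]] * 4,
            "n_nonmissing": [100] * 4,
        }
    )
    maps = RelevanceMaps(
        protein_to_genes={"P_enc_by_G": frozenset({"G", "X"}), "P_other": frozenset({"H"})},
        gene_metabolite_pairs={("G", "M_linked_G"), ("H", "M_linked_H")},
        pair_sources={("G", "M_linked_G"): "mGWAS"},
    )
    annotated, ppcvs, mpcvs = apply_relevance(assoc, maps)
    assert list(ppcvs["variant_id"]) == ["v1"]   # multi-gene aptamer matches on any
    assert list(mpcvs["variant_id"]) == ["v3"]
    assert annotated.loc[annotated["variant_id"] == "v2", "relevance"].iloc[0] == "none"
    assert annotated.loc[annotated["variant_id"] == "v4", "relevance"].iloc[0] == "none"


def test_planted_pairs_recovered_as_relevance_filtered_hits(small_cohort):
    from koscan.pcv import select_pcvs

    pcvs = select_pcvs(small_cohort.dataset)
    for rec in small_cohort.truth["knockouts"]:
        for analyte in rec["affected_analytes"]:
            platform = "protein" if analyte.startswith("PROT") else "metabolite"
            matrix = small_cohort.phenotypes[platform]
            assoc = scan(pcvs, matrix, k=20, min_nonmissing=200)
            _, ppcvs, mpcvs = apply_relevance(assoc, small_cohort.maps)
            hits = ppcvs if platform == "protein" else mpcvs
            assert rec["variant_id"] in set(hits["variant_id"])


# -------------------------------------------------------- sensitivity ----

def test_sensitivity_rules_nest_and_report():
    rng = np.random.default_rng(7)
    V = rng.normal(size=(300, 20))
    samples = [f"s{i:03d}" for i in range(300)]
    m = _matrix(V, samples)
    pcvs = _pcv_frame(
        [(f"v{i}", f"G{i}", list(rng.choice(samples, rng.integers(1, 3), replace=False)))
         for i in range(60)]
    )
    results, summary = sensitivity_scan(pcvs, m, min_nonmissing=0)
    key = lambda df: set(zip(df["variant_id"], df["analyte"]))
    assert key(results["top5"]) <= key(results["top10"]) <= key(results["top20"])
    assert set(summary["rule"]) == {"top20", "top10", "top5", "sd3"}


def test_constant_analyte_emits_nothing_under_sd_rule():
    V = np.zeros((50, 1))
    m = _matrix(V)
    samples = list(m.values.index)
    pcvs = _pcv_frame([("v0", "G0", [samples[0]])])
    results, _ = sensitivity_scan(pcvs, m, rules=("sd3",), min_nonmissing=0)
    assert len(results["sd3"]) == 0
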