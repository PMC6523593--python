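"""Sample QC, LD pruning, KING-robust kinship, IBS0 and concordance."""

import numpy as np
import pandas as pd
import pytest

import walnutsnp as w
from walnutsnp.relatedness import PairCounts, apply_prefilters

from conftest import make_matrix


# -- sample QC ----------------------------------------------------------------

def test_sample_qc_call_rate_boundary():
    m = w.MISSING
    geno = np.zeros((3, 100), dtype=np.int8)
    geno[1, :4] = m   # call rate 0.96 -> excluded
    geno[2, :3] = m   # call rate 0.97 -> retained (rule is strict <)
    gm = make_matrix(geno)
    kept, report = w.sample_qc(gm)
    assert kept.samples == ["ind0", "ind2"]
    assert report.set_index("sample").loc["ind1", "excluded"]


def test_sample_qc_matches_bruteforce_recount(founders_small):
    _, gm, _ = founders_small
    cfg = w.SimConfig(n_founders=27, n_sites=2_000, geno_error_rate=0, missing_rate=0.05)
    noisy, _, _ = w.inject_errors(gm, cfg, seed=31)
    kept, report = w.sample_qc(noisy, min_call_rate=0.96)
    expected_excluded = {
        s for i, s in enumerate(noisy.samples)
        if sum(1 for g in noisy.geno[i] if g != w.MISSING) / noisy.n_sites < 0.96
    }
    assert set(report.loc[report["excluded"], "sample"]) == expected_excluded
    assert set(kept.samples) == set(noisy.samples) - expected_excluded


def test_sample_qc_all_dropped_is_an_error():
    gm = make_matrix(np.full((2, 10), w.MISSING, dtype=np.int8))
    with pytest.raises(ValueError):
        w.sample_qc(gm)


# -- LD pruning ---------------------------------------------------------------

def test_ld_prune_removes_duplicate_keeps_independent():
    rng = np.random.default_rng(8)
    a = rng.integers(0, 3, 50).astype(np.int8)
    b = rng.integers(0, 3, 50).astype(np.int8)
    gm = make_matrix(np.column_stack([a, a, b]), positions=[100, 200, 60_000])
    kept = w.ld_prune(gm)
    assert kept == ["s0", "s2"]  # duplicate pruned; far/independent site kept


def test_ld_prune_satisfies_r2_bound_exhaustively():
    rng = np.random.default_rng(9)
    base = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
    cols, pos = [], []
    for i in range(20):
        src = base[:, rng.integers(0, 5)].copy()
        flip = rng.random(40) < 0.2
        src[flip] = rng.integers(0, 3, size=int(flip.sum()))
        cols.append(src)
        pos.append(1 + i * 5_000)  # all within overlapping 50-kb windows
    gm = make_matrix(np.column_stack(cols), positions=pos)
    kept_ids = w.ld_prune(gm)
    idx = {s: i for i, s in enumerate(gm.sites["site_id"])}
    kept = [idx[s] for s in kept_ids]
    for a in kept:
        for b in kept:
            if a < b and abs(pos[a] - pos[b]) <= 50_000:
                assert not (w.ld_r2(gm.geno[:, a], gm.geno[:, b]) > 0.25)


# -- pair counts and estimators -------------------------------------------------

def test_pairwise_counts_hand_example():
    c = w.pairwise_counts(np.array([0, 1, 2, 1]), np.array([2, 1, 0, 1]))
    assert c == PairCounts(n_het_het=2, n_opp_hom=2, n_het_i=2, n_het_j=2, n_shared=4)


def test_pairwise_counts_identical_and_missing():
    g = np.array([0, 1, 1, 2, w.MISSING, 1], dtype=np.int8)
    c = w.pairwise_counts(g, g)
    assert c.n_opp_hom == 0 and c.n_het_het == 3 and c.n_shared == 5
    # missing in either vector drops the site from every count
    c2 = w.pairwise_counts(np.array([1, w.MISSING]), np.array([w.MISSING, 1]))
    assert c2.n_shared == 0 and np.isnan(w.ibs0(c2))


def test_kinship_formula_values():
    identical = w.pairwise_counts(np.array([0, 1, 1, 2, 1]), np.array([0, 1, 1, 2, 1]))
    assert w.king_robust_kinship(identical) == pytest.approx(0.5)
    # (2,2,2,2,4): k = (2-4)/4 + 1/2 - 4/8 = -0.5
    assert w.king_robust_kinship(PairCounts(2, 2, 2, 2, 4)) == pytest.approx(-0.5)
    assert np.isnan(w.king_robust_kinship(PairCounts(0, 1, 0, 3, 10)))


def test_parent_offspring_kinship_and_ibs0():
    """Mean k over replicates near 0.25; IBS0 exactly 0 without error."""
    ks = []
    for rep in range(20):
        cfg = w.SimConfig(
            n_founders=10, n_sites=10_000, geno_error_rate=0, missing_rate=0,
            seed=100 + rep,
        )
        founders, _ = w.simulate_founders(cfg)
        gm, _ = w.simulate_pedigree(
            founders, w.CrossPlan().add(founders.samples[0], founders.samples[1], 1),
            seed=200 + rep,
        )
        pruned = apply_prefilters(gm)
        c = w.pairwise_counts(
            pruned.genotypes_of(founders.samples[0]), pruned.genotypes_of("off_00000")
        )
        ks.append(w.king_robust_kinship(c))
        assert w.ibs0(c) == 0.0
    assert abs(np.mean(ks) - 0.25) < 0.02


# -- relatedness matrix ---------------------------------------------------------

def test_relatedness_matrix_pair_count_and_symmetries(family_sim):
    gm, _ = family_sim
    sub = gm.subset_samples(gm.samples[:12])
    pairs = w.relatedness_matrix(sub, prefilter=False)
    assert len(pairs) == 12 * 11 // 2

    # permuting samples leaves pair values unchanged
    perm = list(reversed(sub.samples))
    pairs_perm = w.relatedness_matrix(sub.subset_samples(perm), prefilter=False)
    key = lambda df: {
        frozenset((i, j)): (k, ib)
        for i, j, k, ib in zip(df.sample_i, df.sample_j, df.kinship, df.ibs0)
    }
    a, b = key(pairs), key(pairs_perm)
    assert a.keys() == b.keys()
    for pair in a:
        assert a[pair] == pytest.approx(b[pair], nan_ok=True)

    # site order invariance
    order = np.random.default_rng(0).permutation(sub.n_sites)
    pairs_sites = w.relatedness_matrix(sub.subset_sites(order), prefilter=False)
    c = key(pairs_sites)
    for pair in a:
        assert a[pair] == pytest.approx(c[pair], nan_ok=True)


def test_relatedness_matrix_agrees_with_scalar_path(family_sim):
    gm, _ = family_sim
    sub = gm.subset_samples(gm.samples[:8])
    pairs = w.relatedness_matrix(sub, prefilter=False)
    for _, row in pairs.iterrows():
        c = w.pairwise_counts(sub.genotypes_of(row.sample_i), sub.genotypes_of(row.sample_j))
        assert row.kinship == pytest.approx(w.king_robust_kinship(c), abs=1e-5)
        assert row.ibs0 == pytest.approx(w.ibs0(c), abs=1e-7)


def test_injected_duplicate_is_the_only_high_kinship_pair(founders_small):
    _, gm, _ = founders_small
    from walnutsnp.genotypes import concat_samples

    dup = w.GenotypeMatrix(["copy_of_f0"], gm.sites.copy(), gm.geno[:1].copy())
    combined = concat_samples(gm, dup)
    pairs = w.relatedness_matrix(combined)
    high = pairs[pairs["kinship"] > 0.45]
    assert len(high) == 1
    assert {high.iloc[0]["sample_i"], high.iloc[0]["sample_j"]} == {
        gm.samples[0], "copy_of_f0"
    }


# -- concordance ----------------------------------------------------------------

def test_concordance_identical_and_single_mismatch():
    geno = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (1, 25))
    gm = make_matrix(geno)
    per, mean = w.genotype_concordance(gm, gm)
    assert mean == pytest.approx(100.0)
    other = gm.copy()
    other.geno[0, 0] = 2 - other.geno[0, 0]  # flip one of 100 calls
    _, mean2 = w.genotype_concordance(gm, other)
    assert mean2 == pytest.approx(99.0)


def test_concordance_tracks_injected_error_rate(founders_small):
    _, gm, _ = founders_small
    cfg = w.SimConfig(n_founders=27, n_sites=2_000, geno_error_rate=0.05, missing_rate=0)
    noisy, err, _ = w.inject_errors(gm, cfg, seed=77)
    _, mean = w.genotype_concordance(gm, noisy)
    expected = 100.0 * (1 - err.mean())
    assert mean == pytest.approx(expected, abs=0.2)


def test_concordance_requires_shared_sites():
    gm = make_matrix(np.zeros((2, 5), dtype=np.int8))
    other = make_matrix(np.zeros((2, 5), dtype=np.int8))
    other.sites["site_id"] = [f"x{i}" for i in range(5)]
    with pytest.raises(ValueError):
        w.genotype_concordance(gm, other)
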