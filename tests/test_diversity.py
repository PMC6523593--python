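"""Diversity statistics, robust sets, PCA and UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest

import walnutsnp as w
from walnutsnp.diversity import per_site_mendel_errors

from conftest import make_matrix


# -- per-SNP statistics ---------------------------------------------------------

def test_snp_stats_worked_examples():
    m = w.MISSING
    geno = np.array(
        [
            [0, 1, 1, 2],   # p_alt = 0.5 -> MAF 0.5, Het 0.5
            [0, 0, 0, 0],   # monomorphic -> MAF 0, Het 0
            [m, m, m, m],   # undefined
            [0, 1, m, 2],   # missing rate 0.25
        ],
        dtype=np.int8,
    ).T
    gm = make_matrix(geno)
    per_site, means = w.snp_stats(gm)
    assert per_site.loc[0, "maf"] == pytest.approx(0.5)
    assert per_site.loc[0, "het"] == pytest.approx(0.5)
    assert per_site.loc[1, "maf"] == 0.0 and per_site.loc[1, "het"] == 0.0
    assert np.isnan(per_site.loc[2, "maf"])
    assert per_site.loc[3, "missing_rate"] == pytest.approx(0.25)
    assert means["n_undefined"] == 1


def test_snp_stats_means_match_bruteforce(founders_small):
    _, gm, _ = founders_small
    cfg = w.SimConfig(n_founders=27, n_sites=2_000, geno_error_rate=0, missing_rate=0.03)
    noisy, _, _ = w.inject_errors(gm, cfg, seed=91)
    per_site, means = w.snp_stats(noisy)
    mafs, hets = [], []
    for j in range(noisy.n_sites):
        col = [g for g in noisy.geno[:, j] if g != w.MISSING]
        if not col:
            continue
        p = sum(col) / (2 * len(col))
        mafs.append(min(p, 1 - p))
        hets.append(sum(1 for g in col if g == 1) / len(col))
    assert means["mean_maf"] == pytest.approx(np.mean(mafs))
    assert means["mean_het"] == pytest.approx(np.mean(hets))


# -- F_IS ------------------------------------------------------------------------

def test_fis_extremes():
    # every member heterozygous at every site, p = 0.5 -> F_IS = 1 - 1/0.5 = -1
    gm = make_matrix(np.ones((6, 50), dtype=np.int8))
    fis = w.fis_per_family(gm, {s: "fam" for s in gm.samples})
    assert fis.loc[0, "fis"] == pytest.approx(-1.0)

    # exact HWE proportions at p=0.5: 1 AA, 2 Aa, 1 aa -> Ho = He -> F_IS = 0
    col = np.array([0, 1, 1, 2], dtype=np.int8)
    gm_hwe = make_matrix(np.tile(col[:, None], (1, 40)))
    fis = w.fis_per_family(gm_hwe, {s: "fam" for s in gm_hwe.samples}, min_family_size=4)
    assert fis.loc[0, "fis"] == pytest.approx(0.0)


def test_fis_small_families_skipped_and_monomorphic_nan():
    gm = make_matrix(np.zeros((6, 10), dtype=np.int8))
    fams = {s: ("A" if i < 2 else "B") for i, s in enumerate(gm.samples)}
    fis = w.fis_per_family(gm, fams, min_family_size=4)
    assert list(fis["family"]) == ["B"]  # family A too small
    assert np.isnan(fis.loc[0, "fis"])  # all monomorphic


def test_fis_simulated_family_matches_direct_formula(founders_small):
    _, founders, _ = founders_small
    gm, _ = w.simulate_pedigree(
        founders, w.CrossPlan().add(founders.samples[0], founders.samples[1], 20), seed=92
    )
    members = [s for s in gm.samples if s.startswith("off_")]
    fis = w.fis_per_family(gm, {s: "f1" for s in members})
    sub = gm.subset_samples(members)
    p = sub.alt_allele_frequencies()
    poly = (p > 0) & (p < 1)
    ho = ((sub.geno == 1).sum(axis=0) / sub.n_samples)[poly].mean()
    he = (2 * p * (1 - p))[poly].mean()
    assert fis.loc[0, "fis"] == pytest.approx(1 - ho / he)
    # a sib family has an inherent heterozygote excess against its own
    # allele frequencies (e.g. Aa x aa segregation gives F_IS = -1/3)
    assert fis.loc[0, "fis"] < 0


def test_fis_near_zero_for_hwe_random_mating_group():
    cfg = w.SimConfig(n_founders=27, n_sites=10_000, geno_error_rate=0, missing_rate=0, seed=95)
    gm, _ = w.simulate_founders(cfg)
    fis = w.fis_per_family(gm, {s: "panel" for s in gm.samples})
    assert abs(fis.loc[0, "fis"]) < 0.02


# -- robust sets ------------------------------------------------------------------

def test_robust_sets_zero_error_membership():
    labels = pd.Series(
        {"a": "PHR", "b": "PHR", "c": "NMH", "d": "OTV", "e": "MHR", "f": "ABvar"}
    )
    errors = pd.Series({"a": 0, "b": 1, "c": 0, "d": 2, "e": 0, "f": 0})
    phr, nmh_otv = w.derive_robust_sets(labels, errors)
    assert phr == ["a"]  # b has a Mendelian error
    assert set(nmh_otv) == {"c", "f"}  # d excluded, e not an eligible class


def test_robust_sets_vacuous_without_trios_warns():
    labels = pd.Series({"a": "PHR", "b": "NMH"})
    with pytest.warns(UserWarning, match="robust sets equal"):
        phr, nmh_otv = w.derive_robust_sets(labels, None)
    assert phr == ["a"] and nmh_otv == ["b"]


def test_robust_sets_shrink_monotonically_with_more_trios(family_sim):
    gm, truth = family_sim
    cfg = w.SimConfig(n_founders=27, n_sites=2_000, geno_error_rate=0.05, missing_rate=0)
    noisy, _, _ = w.inject_errors(gm, cfg, seed=93)
    labels = pd.Series("PHR", index=gm.sites["site_id"].to_numpy())

    import networkx as nx

    def graph_with(children):
        g = nx.DiGraph()
        for c in children:
            for p, _, d in truth.in_edges(c, data=True):
                g.add_edge(p, c, provenance="new", role=d["role"])
        return g

    offspring = [n for n in truth.nodes if truth.in_degree(n) > 0]
    errs_small = per_site_mendel_errors(noisy, graph_with(offspring[:5]))
    errs_big = per_site_mendel_errors(noisy, graph_with(offspring))
    phr_small, _ = w.derive_robust_sets(labels, errs_small)
    phr_big, _ = w.derive_robust_sets(labels, errs_big)
    assert set(phr_big) <= set(phr_small)
    assert len(phr_big) < len(phr_small)  # 5% error: more trios catch more sites


# -- PCA ---------------------------------------------------------------------------

def test_pca_duplicate_coords_and_proportions(founders_small):
    from walnutsnp.genotypes import concat_samples

    _, gm, _ = founders_small
    dup = w.GenotypeMatrix(["dup"], gm.sites.copy(), gm.geno[:1].copy())
    coords, proportions = w.pca(concat_samples(gm, dup))
    np.testing.assert_allclose(
        coords.loc[gm.samples[0]].to_numpy(), coords.loc["dup"].to_numpy(), atol=1e-8
    )
    assert proportions.sum() == pytest.approx(1.0)
    assert (proportions >= -1e-12).all()


def test_pca_separates_divergent_populations():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(94)
    n_sites = 1_000
    p1 = rng.uniform(0.1, 0.4, n_sites)
    shift = rng.choice([-0.25, 0.25], n_sites)
    p2 = np.clip(p1 + shift, 0.05, 0.95)
    pop1 = rng.binomial(2, p1, size=(15, n_sites)).astype(np.int8)
    pop2 = rng.binomial(2, p2, size=(15, n_sites)).astype(np.int8)
    gm = make_matrix(np.vstack([pop1, pop2]))
    coords, _ = w.pca(gm, n_components=2)
    labels = [0] * 15 + [1] * 15
    assert silhouette_score(coords[["PC1"]], labels) > 0


def test_pca_degenerate_input_raises():
    gm = make_matrix(np.zeros((3, 10), dtype=np.int8))
    with pytest.raises(ValueError):
        w.pca(gm)


# -- IBS distance and UPGMA ---------------------------------------------------------

def test_ibs_distance_closed_form():
    geno = np.array(
        [
            [0, 0, 0, 0],
            [0, 0, 0, 0],   # identical -> distance 0
            [2, 2, 2, 2],   # opposite hom everywhere -> distance 1
            [1, 1, 1, 1],   # het vs hom -> half sharing -> 0.5
        ],
        dtype=np.int8,
    )
    d = w.ibs_distance(make_matrix(geno))
    assert d.loc["ind0", "ind1"] == pytest.approx(0.0)
    assert d.loc["ind0", "ind2"] == pytest.approx(1.0)
    assert d.loc["ind0", "ind3"] == pytest.approx(0.5)


def test_upgma_two_leaves_and_identical_join_first():
    d = pd.DataFrame(
        [[0.0, 0.2], [0.2, 0.0]], index=["a", "b"], columns=["a", "b"]
    )
    assert w.upgma(d) == "(a:0.1,b:0.1);"

    d3 = pd.DataFrame(
        [[0.0, 0.0, 0.6], [0.0, 0.0, 0.6], [0.6, 0.6, 0.0]],
        index=list("abc"), columns=list("abc"),
    )
    newick = w.upgma(d3)
    assert newick.startswith("((a:0.0,b:0.0)")


def _tree_heights_and_cophenetic(newick, labels):
    """Leaf-pair cophenetic distances parsed with an established tree library."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    coph = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ta, tb = tree.find(a), tree.find(b)
            coph[frozenset((a, b))] = ta.distance(tb)
    root_dists = [tree.find(x).distance(tree.root()) for x in labels]
    return coph, root_dists


@pytest.mark.parametrize("seed", range(6))
def test_upgma_matches_scipy_average_linkage_oracle(seed):
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(seed)
    n = rng.integers(4, 7)
    labels = [f"t{i}" for i in range(n)]
    cond = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
    d = squareform(cond)
    df = pd.DataFrame(d, index=labels, columns=labels)
    newick = w.upgma(df)
    coph, root_dists = _tree_heights_and_cophenetic(newick, labels)
    expected = squareform(cophenet(linkage(cond, method="average")))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            assert coph[frozenset((a, labels[j]))] == pytest.approx(
                expected[i, j], abs=1e-9
            )
    # ultrametric: every leaf equidistant from the root
    assert max(root_dists) - min(root_dists) < 1e-9


def test_upgma_rejects_bad_matrices():
    bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError):
        w.upgma(bad)
    nan = pd.DataFrame(
        [[0.0, np.nan], [np.nan, 0.0]], index=["a", "b"], columns=["a", "b"]
    )
    with pytest.raises(ValueError):
        w.upgma(nan)
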