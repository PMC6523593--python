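"""Threshold calibration, pair classification, Mendelian tests, parent assignment."""

import numpy as np
import pandas as pd
import pytest

import walnutsnp as w
from walnutsnp.pedigree import (
    DUO_IMPOSSIBLE,
    TRIO_IMPOSSIBLE,
    Thresholds,
    accepted_edges,
    recorded_relationships,
)
from walnutsnp.relatedness import relatedness_matrix
from walnutsnp.simulate import corrupt_records, pedigree_to_records

from conftest import make_matrix


# -- classification -------------------------------------------------------------

@pytest.mark.parametrize(
    "k,ibs0,expected",
    [
        (0.48, 0.0, "DUPLICATE"),
        (0.25, 0.01, "PARENT_OFFSPRING"),
        (0.25, 0.05, "FULL_SIB"),
        (0.10, 0.0, "OTHER"),
        (0.16, 0.03, "PARENT_OFFSPRING"),  # both boundaries inclusive for PO
        (0.16, 0.031, "FULL_SIB"),
        (0.45, 0.0, "PARENT_OFFSPRING"),  # duplicate needs strictly > 0.45
        (float("nan"), 0.0, "OTHER"),
    ],
)
def test_classify_pair(k, ibs0, expected):
    assert w.classify_pair(k, ibs0, Thresholds()) == expected


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(first_degree_k=0.5, duplicate_k=0.45)
    with pytest.raises(ValueError):
        Thresholds(mendel_max_rate=1.2)


# -- calibration ----------------------------------------------------------------

def _pair_frame(rows):
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "kinship", "ibs0"])


def test_calibration_percentile_and_ibs0_max():
    rng = np.random.default_rng(0)
    # 200 known first-degree pairs whose empirical 2.5th percentile is ~0.16
    ks = np.sort(rng.uniform(0.16, 0.35, 195))
    ks = np.concatenate([np.linspace(0.10, 0.159, 5), ks])  # 2.5% below 0.16
    rows, known = [], []
    for n, k in enumerate(ks):
        i, j = f"p{n}", f"c{n}"
        rel = "PO" if n % 2 else "FS"
        ib = [0.0, 0.01, 0.03][n % 3] if rel == "PO" else 0.05
        rows.append((i, j, k, ib))
        known.append((i, j, rel))
    th, report = w.calibrate_thresholds(
        _pair_frame(rows), pd.DataFrame(known, columns=["sample_i", "sample_j", "relation"])
    )
    assert report["calibrated"]
    assert th.first_degree_k == pytest.approx(np.quantile(ks, 0.025))
    # max IBS0 among known PO pairs above the bound
    assert th.po_ibs0_max == pytest.approx(0.03)


def test_calibration_without_known_po_warns_and_defaults():
    pairs = _pair_frame([("a", "b", 0.2, 0.01)])
    known = pd.DataFrame([("a", "b", "FS")], columns=["sample_i", "sample_j", "relation"])
    with pytest.warns(UserWarning, match="no known PO"):
        th, report = w.calibrate_thresholds(pairs, known)
    assert th == Thresholds() and not report["calibrated"]


def test_calibration_zero_error_pedigree_gives_zero_ibs0(family_sim):
    gm, truth = family_sim
    pairs = relatedness_matrix(gm)
    known = recorded_relationships(pedigree_to_records(truth))
    th, report = w.calibrate_thresholds(pairs, known)
    assert th.po_ibs0_max == 0.0
    assert report["n_known_po"] > 0


# -- Mendelian test -------------------------------------------------------------

def test_trio_table_matches_transmission_probability_oracle():
    """All 27 parent-parent-child dosage combinations vs an independent oracle."""

    def transmission_prob(p_geno: int, allele: int) -> float:
        return {0: [1.0, 0.0], 1: [0.5, 0.5], 2: [0.0, 1.0]}[p_geno][allele]

    for p1 in range(3):
        for p2 in range(3):
            for c in range(3):
                prob = sum(
                    transmission_prob(p1, a) * transmission_prob(p2, c - a)
                    for a in (0, 1)
                    if 0 <= c - a <= 1
                )
                assert TRIO_IMPOSSIBLE[p1, p2, c] == (prob == 0.0)
    # duo: error iff opposite homozygotes
    for p in range(3):
        for c in range(3):
            assert DUO_IMPOSSIBLE[p, c] == ({p, c} == {0, 2})


def test_mendelian_examples_and_rates():
    hom_ref = np.zeros(10, dtype=np.int8)
    het = np.ones(10, dtype=np.int8)
    hom_alt = np.full(10, 2, dtype=np.int8)
    rate, flags = w.mendelian_inconsistency(het, hom_ref, hom_ref)  # AA x AA -> Aa
    assert rate == 1.0 and flags.all()
    rate, _ = w.mendelian_inconsistency(hom_alt, hom_ref)  # duo opposite homozygotes
    assert rate == 1.0
    for child in (hom_ref, het, hom_alt):  # duo with het parent: anything goes
        rate, _ = w.mendelian_inconsistency(child, het)
        assert rate == 0.0
    with pytest.raises(ValueError):
        w.mendelian_inconsistency(
            np.full(5, w.MISSING, dtype=np.int8), hom_ref[:5]
        )


def test_mendelian_denominator_is_jointly_called_sites():
    child = np.array([2, w.MISSING, 0], dtype=np.int8)
    parent = np.array([0, 0, w.MISSING], dtype=np.int8)
    rate, flags = w.mendelian_inconsistency(child, parent)
    assert rate == 1.0 and flags.tolist() == [True, False, False]


def test_true_trio_rates_with_and_without_error():
    from walnutsnp.evaluation import mendelian_error_rates

    res = mendelian_error_rates(seed=55, n_sites=5_000, geno_error_rate=0.01)
    assert res["clean_trio_rate"] == 0.0
    assert 0.0 < res["noisy_trio_rate"] < 0.05


# -- parent assignment -----------------------------------------------------------

def _reconstruct(gm, truth, mislabel_rate=0.0, seed=1):
    records, mask = corrupt_records(truth, mislabel_rate, seed=seed)
    pairs = relatedness_matrix(gm)
    graph, review = w.assign_parents(gm, pairs, records, Thresholds())
    return graph, review, records, mask


def test_zero_error_complete_records_confirms_everything(family_sim):
    gm, truth = family_sim
    graph, _, _, _ = _reconstruct(gm, truth)
    got = {(u, v) for u, v, _ in accepted_edges(graph)}
    assert got == set(truth.edges)
    assert all(
        d["provenance"] == "recorded_confirmed" for _, _, d in accepted_edges(graph)
    )


def test_mislabelled_dams_are_flagged_and_corrected(founders_small):
    _, founders, _ = founders_small
    plan = w.CrossPlan()
    for d, s in [(0, 1), (2, 3), (4, 5)]:
        plan.add(founders.samples[d], founders.samples[s], 10)
    gm, truth = w.simulate_pedigree(founders, plan, seed=61)
    rng = np.random.default_rng(62)
    records = pedigree_to_records(truth)
    # force exactly three dam mislabels onto known children
    victims = ["off_00000", "off_00012", "off_00025"]
    truth_dams = {}
    for v in victims:
        i = records.index[records["id"] == v][0]
        truth_dams[v] = records.at[i, "dam"]
        records.at[i, "dam"] = founders.samples[20]  # unrelated founder
    pairs = relatedness_matrix(gm)
    graph, _ = w.assign_parents(gm, pairs, records, Thresholds())
    for v in victims:
        assert graph.edges[founders.samples[20], v]["provenance"] == "recorded_rejected"
        assert graph.edges[truth_dams[v], v]["provenance"] == "corrected"
        assert graph.edges[truth_dams[v], v]["role"] == "dam"


def test_open_pollination_sire_recovered_as_new(founders_small):
    _, founders, _ = founders_small
    plan = w.CrossPlan().add(founders.samples[0], founders.samples[1], 6)
    for _ in range(4):
        plan.add(founders.samples[2], w.OPEN, 1)
    gm, truth = w.simulate_pedigree(founders, plan, seed=63)
    graph, _, _, _ = _reconstruct(gm, truth)
    open_children = [c for c in truth.nodes if truth.nodes[c].get("open_pollinated")]
    assert open_children
    for c in open_children:
        sire = next(p for p, _, d in truth.in_edges(c, data=True) if d["role"] == "sire")
        assert graph.edges[sire, c]["provenance"] == "new"
        assert graph.edges[sire, c]["role"] == "sire"


def test_unorientable_po_pairs_go_to_review(family_sim):
    gm, truth = family_sim
    pairs = relatedness_matrix(gm)
    records = pedigree_to_records(truth)
    # withhold all generation information: every PO pair is unorientable
    gens = {s: None for s in gm.samples}
    graph, review = w.assign_parents(gm, pairs, records, Thresholds(), generations=gens)
    assert len(accepted_edges(graph)) == 0
    assert (review["issue"] == "unoriented_po").sum() >= truth.number_of_edges()


def test_duplicates_collapse_to_best_call_rate(family_sim):
    from walnutsnp.genotypes import concat_samples

    gm, truth = family_sim
    dup_geno = gm.genotypes_of(gm.samples[0])[None, :].copy()
    dup_geno[0, :100] = w.MISSING  # worse call rate than the original
    dup = w.GenotypeMatrix(["dup0"], gm.sites.copy(), dup_geno)
    combined = concat_samples(gm, dup)
    pairs = relatedness_matrix(combined)
    graph, _ = w.assign_parents(combined, pairs, pedigree_to_records(truth), Thresholds())
    assert graph.nodes["dup0"].get("duplicate_of") == gm.samples[0]
    assert not any(u == "dup0" or v == "dup0" for u, v, _ in accepted_edges(graph))
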