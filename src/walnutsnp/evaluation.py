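"""End-to-end evaluation runs on synthetic pedigrees.

These routines re-run the full method on freshly simulated data and
measure how well known quantities are recovered: kinship coefficients for
canonical relationship classes, pedigree reconstruction accuracy with and
without genotyping error and record mislabelling, and Mendelian test
behaviour. They back both the acceptance checks and the worked examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, concat_samples
from .pedigree import (
    Thresholds,
    accepted_edges,
    assign_parents,
    classify_pair,
    mendelian_inconsistency,
)
from .relatedness import (
    PrefilterConfig,
    apply_prefilters,
    ibs0,
    king_robust_kinship,
    pairwise_counts,
    relatedness_matrix,
)
from .simulate import (
    OPEN,
    CrossPlan,
    SimConfig,
    corrupt_records,
    inject_errors,
    simulate_founders,
    simulate_pedigree,
)

RELATIONSHIP_EXPECTED_K = {
    "duplicate": 0.5,
    "parent_offspring": 0.25,
    "full_sib": 0.25,
    "half_sib": 0.125,
    "unrelated": 0.0,
}


def kinship_recovery(
    n_replicates: int = 100,
    n_sites: int = 10_000,
    n_founders: int = 27,
    seed: int = 0,
    prefilter_cfg: PrefilterConfig = PrefilterConfig(),
) -> dict:
    """Mean KING-robust kinship per relationship class over replicates.

    Each replicate simulates an error-free founder panel, one full-sib
    family, one half-sib child and a duplicated founder, prefilters and
    LD-prunes the sites, and estimates kinship/IBS0 for one pair of each
    class: duplicate, parent-offspring, full sibs, half sibs, unrelated.

    Returns the per-class mean kinship, the largest absolute deviation
    from the expected values, and the maximum parent-offspring IBS0
    (exactly 0 without genotyping error).
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, 2))
    ks: dict[str, list[float]] = {r: [] for r in RELATIONSHIP_EXPECTED_K}
    po_ibs0: list[float] = []
    for s1, s2 in rep_seeds:
        cfg = SimConfig(
            n_founders=n_founders,
            n_sites=n_sites,
            geno_error_rate=0.0,
            missing_rate=0.0,
            seed=int(s1),
        )
        founders, _ = simulate_founders(cfg)
        f = founders.samples
        plan = CrossPlan().add(f[0], f[1], 2).add(f[0], f[2], 1)
        gm, _ = simulate_pedigree(founders, plan, seed=int(s2))
        dup = GenotypeMatrix(
            ["dup_of_f3"], gm.sites.copy(), gm.genotypes_of(f[3])[None, :].copy()
        )
        gm = concat_samples(gm, dup)
        pruned = apply_prefilters(gm, prefilter_cfg)
        pairs = {
            "duplicate": (f[3], "dup_of_f3"),
            "parent_offspring": (f[0], "off_00000"),
            "full_sib": ("off_00000", "off_00001"),
            "half_sib": ("off_00000", "off_00002"),
            "unrelated": (f[4], f[5]),
        }
        for rel, (a, b) in pairs.items():
            c = pairwise_counts(pruned.genotypes_of(a), pruned.genotypes_of(b))
            ks[rel].append(king_robust_kinship(c))
            if rel == "parent_offspring":
                po_ibs0.append(ibs0(c))
    means = {rel: float(np.mean(v)) for rel, v in ks.items()}
    max_dev = max(abs(means[r] - e) for r, e in RELATIONSHIP_EXPECTED_K.items())
    return {
        "mean_kinship": means,
        "max_abs_deviation": float(max_dev),
        "po_ibs0_max": float(np.max(po_ibs0)),
        "n_replicates": n_replicates,
        "n_sites": n_sites,
    }


def pedigree_recovery(
    seed: int,
    n_founders: int = 27,
    n_families: int = 25,
    offspring_per_family: int = 22,
    n_open: int = 10,
    n_sites: int = 10_000,
    geno_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    mislabel_rate: float = 0.0,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """Reconstruct a simulated pedigree and score it against the truth.

    Simulates founders plus full-sib families (and optionally
    open-pollinated offspring whose sire is unrecorded), corrupts the
    genotypes and the recorded pedigree at the given rates, runs the
    relatedness pipeline and :func:`assign_parents`, and reports:

    * exact recovery (accepted edges == true edges, orientation included);
    * parent-offspring classification recall over true PO pairs;
    * duplicate calls among non-duplicate pairs (should be none);
    * fraction of injected mislabels flagged ``recorded_rejected``;
    * fraction of mislabelled slots where the true parent was recovered;
    * fraction of open-pollinated offspring whose true sire was found.
    """
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2**31 - 1, size=6)
    cfg = SimConfig(
        n_founders=n_founders,
        n_sites=n_sites,
        geno_error_rate=geno_error_rate,
        missing_rate=missing_rate,
        mislabel_rate=mislabel_rate,
        seed=int(s[0]),
    )
    founders, _ = simulate_founders(cfg)
    f = founders.samples
    plan = CrossPlan()
    for _ in range(n_families):
        dam, sire = rng.choice(n_founders, size=2, replace=False)
        plan.add(f[dam], f[sire], offspring_per_family)
    for _ in range(n_open):
        plan.add(f[int(rng.integers(0, n_founders))], OPEN, 1)
    gm, truth = simulate_pedigree(founders, plan, seed=int(s[1]))
    observed, _, _ = inject_errors(gm, cfg, seed=int(s[2]))
    records, mislabel_mask = corrupt_records(truth, mislabel_rate, seed=int(s[3]))

    pairs = relatedness_matrix(observed)
    # orient PO pairs by the true generation metadata (the analogue of a
    # breeding program's cross years, recorded independently of parentage)
    generations = {n: truth.nodes[n]["generation"] for n in truth.nodes}
    graph, _ = assign_parents(observed, pairs, records, thresholds, generations=generations)

    # --- edge recovery -----------------------------------------------------
    true_edges = {(u, v) for u, v in truth.edges}
    got_edges = {(u, v) for u, v, _ in accepted_edges(graph)}
    n_missed = len(true_edges - got_edges)
    n_false = len(got_edges - true_edges)

    # --- PO classification recall ------------------------------------------
    lut = {}
    for i, j, k, ib in zip(pairs["sample_i"], pairs["sample_j"], pairs["kinship"], pairs["ibs0"]):
        lut[frozenset((i, j))] = (k, ib)
    n_po = n_po_called = 0
    for u, v in true_edges:
        k, ib = lut[frozenset((u, v))]
        n_po += 1
        if classify_pair(k, ib, thresholds) == "PARENT_OFFSPRING":
            n_po_called += 1

    # --- false duplicates ---------------------------------------------------
    n_false_dup = int((pairs["kinship"] > thresholds.duplicate_k).sum())

    # --- mislabel flagging and correction ------------------------------------
    flagged = recovered = n_mislabels = 0
    truth_parents = {
        child: {d["role"]: p for p, _, d in truth.in_edges(child, data=True)}
        for child in truth.nodes
    }
    for _, row in mislabel_mask.iterrows():
        child = row["id"]
        for slot, col in (("dam", "dam_mislabelled"), ("sire", "sire_mislabelled")):
            if not row[col]:
                continue
            n_mislabels += 1
            wrong = records.set_index("id").at[child, slot]
            if graph.has_edge(wrong, child) and (
                graph.edges[wrong, child]["provenance"] == "recorded_rejected"
            ):
                flagged += 1
            true_p = truth_parents[child][slot]
            if graph.has_edge(true_p, child) and (
                graph.edges[true_p, child]["provenance"] in ("corrected", "new")
            ):
                recovered += 1

    # --- open-pollination sire discovery -------------------------------------
    open_children = [c for c in truth.nodes if truth.nodes[c].get("open_pollinated")]
    n_open_found = sum(
        1
        for c in open_children
        if graph.has_edge(truth_parents[c]["sire"], c)
        and graph.edges[truth_parents[c]["sire"], c]["provenance"] == "new"
    )

    return {
        "n_true_edges": len(true_edges),
        "n_accepted_edges": len(got_edges),
        "n_missed_edges": n_missed,
        "n_false_edges": n_false,
        "exact": n_missed == 0 and n_false == 0,
        "po_recall": n_po_called / n_po if n_po else float("nan"),
        "n_false_duplicates": n_false_dup,
        "n_mislabels": n_mislabels,
        "mislabels_flagged": flagged,
        "mislabels_true_parent_recovered": recovered,
        "n_open_children": len(open_children),
        "open_sires_recovered": n_open_found,
    }


def mendelian_error_rates(seed: int, n_sites: int = 10_000, geno_error_rate: float = 0.01) -> dict:
    """Trio Mendelian inconsistency rates on a clean and an error-injected trio."""
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2**31 - 1, size=3)
    cfg = SimConfig(
        n_founders=4, n_sites=n_sites, geno_error_rate=geno_error_rate,
        missing_rate=0.0, seed=int(s[0]),
    )
    founders, _ = simulate_founders(cfg)
    f = founders.samples
    gm, _ = simulate_pedigree(founders, CrossPlan().add(f[0], f[1], 1), seed=int(s[1]))
    clean_rate, _ = mendelian_inconsistency(
        gm.genotypes_of("off_00000"), gm.genotypes_of(f[0]), gm.genotypes_of(f[1])
    )
    noisy, _, _ = inject_errors(gm, cfg, seed=int(s[2]))
    noisy_rate, _ = mendelian_inconsistency(
        noisy.genotypes_of("off_00000"), noisy.genotypes_of(f[0]), noisy.genotypes_of(f[1])
    )
    return {"clean_trio_rate": clean_rate, "noisy_trio_rate": noisy_rate}
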