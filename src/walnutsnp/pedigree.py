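"""Pedigree reconstruction from pairwise kinship, IBS0 and Mendelian tests.

The workflow mirrors how a breeding program validates its historical
pedigree ledger against array genotypes:

1. calibrate classification thresholds from the recorded relationships
   (the lower bound of the central 95% kinship interval over known
   parent-offspring and full-sib pairs; the maximum IBS0 among known
   parent-offspring pairs);
2. classify every pair as DUPLICATE / PARENT_OFFSPRING / FULL_SIB / OTHER;
3. collapse duplicate samples to the highest-call-rate representative;
4. validate recorded parents with the duo Mendelian test, replace rejected
   records when a classified parent-offspring partner passes, accept trios
   when the trio inconsistency rate stays below 5%;
5. emit a directed parent->child graph with per-edge provenance
   (recorded_confirmed / recorded_rejected / corrected / new).

Parent-vs-child orientation of a PO pair is not decidable from kinship and
IBS0 alone; generation metadata (recorded or supplied) orients edges, and
unorientable pairs go to a review list rather than being guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

UNKNOWN_PARENT = "0"

ACCEPTED_PROVENANCES = ("recorded_confirmed", "corrected", "new")


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (defaults = published calibration)."""

    duplicate_k: float = 0.45
    first_degree_k: float = 0.16
    po_ibs0_max: float = 0.03
    mendel_max_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.first_degree_k < self.duplicate_k <= 0.5:
            raise ValueError("need 0 < first_degree_k < duplicate_k <= 0.5")
        for name in ("po_ibs0_max", "mendel_max_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def recorded_relationships(records: pd.DataFrame) -> pd.DataFrame:
    """Known PO and FS pairs implied by a recorded pedigree table.

    PO pairs: (recorded parent, child) for every known parent entry.
    FS pairs: children sharing both recorded parents (both known).
    Returns columns ``sample_i, sample_j, relation``.
    """
    rows = []
    for _, r in records.iterrows():
        for parent in (r["dam"], r["sire"]):
            if parent != UNKNOWN_PARENT:
                rows.append((parent, r["id"], "PO"))
    both_known = records[(records["dam"] != UNKNOWN_PARENT) & (records["sire"] != UNKNOWN_PARENT)]
    for _, sub in both_known.groupby(["dam", "sire"]):
        for a, b in combinations(sorted(sub["id"]), 2):
            rows.append((a, b, "FS"))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "relation"])


def _pair_lookup(pairs: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    lut = {}
    for i, j, k, ib in zip(
        pairs["sample_i"], pairs["sample_j"], pairs["kinship"], pairs["ibs0"]
    ):
        lut[(i, j)] = (k, ib)
        lut[(j, i)] = (k, ib)
    return lut


def calibrate_thresholds(
    pairs: pd.DataFrame,
    known: pd.DataFrame,
    defaults: Thresholds = Thresholds(),
    central_coverage: float = 0.95,
) -> tuple[Thresholds, dict]:
    """Calibrate thresholds from recorded relationships.

    ``first_degree_k`` becomes the lower bound of the central 95% kinship
    interval (the 2.5th percentile) over known PO + FS pairs;
    ``po_ibs0_max`` the maximum IBS0 among known PO pairs that already pass
    the first-degree bound (so mislabelled records, whose kinship is near
    zero, cannot inflate it). Without known PO pairs the defaults are
    returned with a warning.
    """
    lut = _pair_lookup(pairs)
    known_vals = {
        rel: [
            lut[(i, j)]
            for i, j, rel_ in zip(known["sample_i"], known["sample_j"], known["relation"])
            if rel_ == rel and (i, j) in lut
        ]
        for rel in ("PO", "FS")
    }
    if not known_vals["PO"]:
        warnings.warn("no known PO pairs with genotypes; using default thresholds", stacklevel=2)
        return defaults, {"calibrated": False}

    first_k = np.array([k for k, _ in known_vals["PO"] + known_vals["FS"]], dtype=float)
    first_k = first_k[~np.isnan(first_k)]
    lower_q = (1.0 - central_coverage) / 2.0
    first_degree_k = float(np.quantile(first_k, lower_q))
    po = np.array(known_vals["PO"], dtype=float)
    po_ok = po[~np.isnan(po).any(axis=1)]
    po_ok = po_ok[po_ok[:, 0] >= first_degree_k]
    if len(po_ok) == 0:
        warnings.warn(
            "no known PO pair passes the first-degree bound; using default IBS0 threshold",
            stacklevel=2,
        )
        po_ibs0_max = defaults.po_ibs0_max
    else:
        po_ibs0_max = float(po_ok[:, 1].max())
    first_degree_k = min(max(first_degree_k, 1e-6), defaults.duplicate_k - 1e-6)
    th = Thresholds(
        duplicate_k=defaults.duplicate_k,
        first_degree_k=first_degree_k,
        po_ibs0_max=po_ibs0_max,
        mendel_max_rate=defaults.mendel_max_rate,
    )
    report = {
        "calibrated": True,
        "n_known_po": len(known_vals["PO"]),
        "n_known_fs": len(known_vals["FS"]),
        "first_degree_k": first_degree_k,
        "po_ibs0_max": po_ibs0_max,
    }
    return th, report


def classify_pair(k: float, ibs0: float, th: Thresholds = Thresholds()) -> str:
    """DUPLICATE / PARENT_OFFSPRING / FULL_SIB / OTHER from (k, IBS0)."""
    if np.isnan(k) or np.isnan(ibs0):
        return "OTHER"
    if k > th.duplicate_k:
        return "DUPLICATE"
    if k >= th.first_degree_k:
        return "PARENT_OFFSPRING" if ibs0 <= th.po_ibs0_max else "FULL_SIB"
    return "OTHER"


# ---------------------------------------------------------------------------
# Mendelian inheritance test
# ---------------------------------------------------------------------------

def _possible_children(p1: int, p2: int) -> set[int]:
    """Child dosages reachable from two parent dosages by one allele each."""
    transmit = {0: {0}, 1: {0, 1}, 2: {1}}
    return {a + b for a in transmit[p1] for b in transmit[p2]}


#: trio_impossible[p1, p2, c] == True iff child dosage c is Mendelian-impossible
TRIO_IMPOSSIBLE = np.zeros((3, 3, 3), dtype=bool)
for _p1 in range(3):
    for _p2 in range(3):
        for _c in range(3):
            TRIO_IMPOSSIBLE[_p1, _p2, _c] = _c not in _possible_children(_p1, _p2)

#: duo_impossible[p, c] == True iff parent and child are opposite homozygotes
DUO_IMPOSSIBLE = np.zeros((3, 3), dtype=bool)
DUO_IMPOSSIBLE[0, 2] = DUO_IMPOSSIBLE[2, 0] = True


def mendelian_inconsistency(
    child: np.ndarray,
    parent1: np.ndarray,
    parent2: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mendelian inconsistency rate of a duo or trio.

    Duo rule: a site is inconsistent iff child and parent are opposite
    homozygotes. Trio rule: inconsistent iff the child dosage cannot be
    produced by one allele from each parent (e.g. parents 0 x 0 with child
    1 or 2; parents 0 x 2 with any homozygous child; parents 2 x 2 with
    child 0 or 1; parents 0 x 1 with child 2; parents 1 x 2 with child 0).

    The rate denominator is the number of sites where the child and every
    supplied parent are called. Returns ``(rate, flags)`` with ``flags`` a
    full-length boolean array marking inconsistent sites. Raises if no
    jointly called sites exist.
    """
    child = np.asarray(child)
    parent1 = np.asarray(parent1)
    ok = (child != MISSING) & (parent1 != MISSING)
    if parent2 is not None:
        parent2 = np.asarray(parent2)
        ok &= parent2 != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no jointly non-missing sites for the Mendelian test")
    flags = np.zeros(child.shape, dtype=bool)
    if parent2 is None:
        flags[ok] = DUO_IMPOSSIBLE[parent1[ok], child[ok]]
    else:
        flags[ok] = TRIO_IMPOSSIBLE[parent1[ok], parent2[ok], child[ok]]
    return float(flags.sum()) / n, flags


# ---------------------------------------------------------------------------
# Parent assignment
# ---------------------------------------------------------------------------

def _generations_from_records(records: pd.DataFrame) -> dict[str, int | None]:
    """Generation depth implied by the recorded pedigree (None on cycles)."""
    parents = {
        r["id"]: [p for p in (r["dam"], r["sire"]) if p != UNKNOWN_PARENT]
        for _, r in records.iterrows()
    }
    gen: dict[str, int | None] = {}

    def depth(node: str, stack: frozenset) -> int | None:
        if node in gen:
            return gen[node]
        if node in stack:
            return None  # recorded cycle: unresolvable
        ps = parents.get(node, [])
        if not ps:
            gen[node] = 0
            return 0
        ds = [depth(p, stack | {node}) for p in ps]
        if any(d is None for d in ds):
            gen[node] = None
        else:
            gen[node] = 1 + max(ds)
        return gen[node]

    for node in parents:
        depth(node, frozenset())
    return gen


def _collapse_duplicates(
    pairs: pd.DataFrame, th: Thresholds, call_rates: pd.Series
) -> dict[str, str]:
    """Map every sample to its duplicate-group representative.

    Groups are connected components of the k > duplicate_k graph; the
    representative is the member with the highest call rate (ties:
    lexicographic id).
    """
    dup = pairs[pairs["kinship"] > th.duplicate_k]
    g = nx.Graph()
    g.add_edges_from(zip(dup["sample_i"], dup["sample_j"]))
    mapping: dict[str, str] = {}
    for comp in nx.connected_components(g):
        rep = max(comp, key=lambda s: (call_rates.get(s, 0.0), s))
        for s in comp:
            mapping[s] = rep
    return mapping


def assign_parents(
    gm: GenotypeMatrix,
    pairs: pd.DataFrame,
    records: pd.DataFrame,
    th: Thresholds = Thresholds(),
    generations: dict[str, int | None] | None = None,
    max_candidates: int = 6,
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Validate and correct a recorded pedigree against the genotypes.

    Parameters
    ----------
    gm
        Genotype matrix used for the Mendelian duo/trio tests (all
        genotyped samples; need not be LD-pruned).
    pairs
        Pairwise table from :func:`walnutsnp.relatedness.relatedness_matrix`.
    records
        Recorded pedigree (columns ``id, dam, sire``; "0" = unknown).
    generations
        Optional sample -> generation mapping used to orient
        parent-offspring pairs (lower = older). Defaults to the depth
        implied by the recorded pedigree; samples without a resolvable
        generation leave their PO pairs unoriented (sent to review).

    Returns
    -------
    (graph, review)
        ``graph``: directed parent->child graph; accepted edges carry
        ``provenance`` in {recorded_confirmed, corrected, new} plus the
        supporting ``mendel_rate`` / ``ibs0`` / slot ``role``; rejected
        recorded parents stay in the graph with provenance
        ``recorded_rejected``. Duplicate samples are collapsed onto their
        highest-call-rate representative (node attribute
        ``duplicate_of`` on the removed ids). ``review`` lists unoriented
        PO pairs and candidate parents beyond the two accepted.
    """
    call_rates = gm.sample_call_rates()
    dup_map = _collapse_duplicates(pairs, th, call_rates)
    rep = lambda s: dup_map.get(s, s)

    if generations is None:
        generations = _generations_from_records(records)

    genotyped = set(gm.samples)
    graph = nx.DiGraph()
    for s in gm.samples:
        if rep(s) == s:
            graph.add_node(s, generation=generations.get(s))
        else:
            graph.add_node(s, duplicate_of=rep(s), generation=generations.get(s))

    # classify pairs among representatives
    po_partners: dict[str, list[str]] = {}
    pair_ibs0: dict[tuple[str, str], float] = {}
    review_rows: list[dict] = []
    for i, j, k, ib in zip(pairs["sample_i"], pairs["sample_j"], pairs["kinship"], pairs["ibs0"]):
        if rep(i) != i or rep(j) != j:
            continue
        call = classify_pair(k, ib, th)
        if call != "PARENT_OFFSPRING":
            continue
        pair_ibs0[(i, j)] = pair_ibs0[(j, i)] = ib
        gi, gj = generations.get(i), generations.get(j)
        if gi is None or gj is None or gi == gj:
            review_rows.append(
                {"sample": i, "other": j, "issue": "unoriented_po", "kinship": k, "ibs0": ib}
            )
            continue
        parent, child = (i, j) if gi < gj else (j, i)
        po_partners.setdefault(child, []).append(parent)

    rec = records.set_index("id")

    def duo_rate(child: str, parent: str) -> float:
        r, _ = mendelian_inconsistency(gm.genotypes_of(child), gm.genotypes_of(parent))
        return r

    for child in gm.samples:
        if rep(child) != child:
            continue
        recorded = {}
        if child in rec.index:
            for slot in ("dam", "sire"):
                p = rec.at[child, slot]
                if p != UNKNOWN_PARENT:
                    recorded[slot] = rep(p)

        candidates = list(dict.fromkeys(po_partners.get(child, [])))
        confirmed_slots: dict[str, str] = {}
        rejected_slots: dict[str, str] = {}
        for slot, p in recorded.items():
            ok = p in genotyped and p in candidates and duo_rate(child, p) < th.mendel_max_rate
            if ok:
                confirmed_slots[slot] = p
            else:
                rejected_slots[slot] = p
                if p in genotyped:
                    graph.add_edge(p, child, provenance="recorded_rejected", role=slot)

        pool = list(confirmed_slots.values()) + [
            c for c in candidates if c not in recorded.values()
        ]
        pool = list(dict.fromkeys(pool))
        scored = sorted(
            ((duo_rate(child, p), pair_ibs0.get((child, p), np.nan), p) for p in pool),
            key=lambda t: (t[0], t[1] if not np.isnan(t[1]) else 1.0, t[2]),
        )
        scored = [t for t in scored if t[0] < th.mendel_max_rate]
        top = scored[:max_candidates]

        final: list[tuple[str, float]] = []  # (parent, supporting rate)
        if len(top) >= 2:
            best = None
            for (r1, _, p1), (r2, _, p2) in combinations(top, 2):
                tr, _ = mendelian_inconsistency(
                    gm.genotypes_of(child), gm.genotypes_of(p1), gm.genotypes_of(p2)
                )
                key = (tr, pair_ibs0.get((child, p1), 1.0) + pair_ibs0.get((child, p2), 1.0))
                if best is None or key < best[0]:
                    best = (key, p1, p2, tr)
            if best is not None and best[3] < th.mendel_max_rate:
                final = [(best[1], best[3]), (best[2], best[3])]
        if not final and top:
            r, _, p = top[0]
            final = [(p, r)]

        if len(scored) > 2:
            for r, ib, p in scored[2:]:
                if p not in [f[0] for f in final]:
                    review_rows.append(
                        {
                            "sample": child,
                            "other": p,
                            "issue": "excess_candidate",
                            "kinship": np.nan,
                            "ibs0": ib,
                        }
                    )

        slots_taken: set[str] = set()
        for p, rate in final:
            if p == confirmed_slots.get("dam") or p == confirmed_slots.get("sire"):
                slot = "dam" if p == confirmed_slots.get("dam") else "sire"
                prov = "recorded_confirmed"
            elif "dam" in rejected_slots and "dam" not in slots_taken:
                slot, prov = "dam", "corrected"
            elif "sire" in rejected_slots and "sire" not in slots_taken:
                slot, prov = "sire", "corrected"
            else:
                slot = "dam" if "dam" not in set(confirmed_slots) | slots_taken else "sire"
                prov = "new"
            slots_taken.add(slot)
            graph.add_edge(
                p,
                child,
                provenance=prov,
                role=slot,
                mendel_rate=rate,
                ibs0=pair_ibs0.get((child, p), np.nan),
            )

    review = pd.DataFrame(review_rows, columns=["sample", "other", "issue", "kinship", "ibs0"])
    return graph, review


def accepted_edges(graph: nx.DiGraph) -> list[tuple[str, str, dict]]:
    """Parent->child edges with accepted provenance (excludes rejections)."""
    return [
        (u, v, d)
        for u, v, d in graph.edges(data=True)
        if d.get("provenance") in ACCEPTED_PROVENANCES
    ]


def graph_to_records(graph: nx.DiGraph) -> pd.DataFrame:
    """Export the accepted pedigree as a 3-column table (id, dam, sire)."""
    rows = {}
    for node in graph.nodes:
        if "duplicate_of" in graph.nodes[node]:
            continue
        rows[node] = {"id": node, "dam": UNKNOWN_PARENT, "sire": UNKNOWN_PARENT}
    for u, v, d in accepted_edges(graph):
        rows[v][d.get("role", "dam")] = u
    return pd.DataFrame(rows.values(), columns=["id", "dam", "sire"])
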