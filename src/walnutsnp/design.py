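"""Panel selection for the genotyping array.

Three routes put a filtered site onto the array:

* ``HIGH_MOD_EFF`` — sites whose predicted effect on a gene is HIGH or
  MODERATE (mis-sense / non-sense changes);
* ``ALL_HOM`` — sites homozygous in every called founder, with at most a
  configurable number of missing calls (candidate fixed alleles);
* ``INFP`` — "in focal point" tagSNPs: within non-overlapping 10-kb windows
  tiled over each scaffold, uninformative sites are dropped and a greedy
  tag selection keeps a maximal set with pairwise LD r² below threshold
  (default 0.81).

A/T and C/G sites cost two probes (one per strand cannot distinguish the
alleles); everything else costs one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

REASON_PRIORITY = ("HIGH_MOD_EFF", "ALL_HOM", "INFP")


def select_effect_snps(sites: pd.DataFrame) -> list[str]:
    """Site ids with a HIGH or MODERATE predicted genic effect."""
    if "effect_class" not in sites.columns:
        raise KeyError("site table is missing required annotation field 'effect_class'")
    mask = sites["effect_class"].isin(("HIGH", "MODERATE"))
    return sites.loc[mask, "site_id"].tolist()


def select_all_hom(
    gm: GenotypeMatrix, max_missing: int = 3, mode: str = "either"
) -> list[str]:
    """Sites with only homozygous founder genotypes and few missing calls.

    ``mode="either"`` (default) accepts homozygotes for either allele;
    ``mode="alt_only"`` requires every called genotype to be homozygous
    alternate. Sites with more than ``max_missing`` missing calls are
    rejected.
    """
    if mode not in ("either", "alt_only"):
        raise ValueError(f"unknown ALL_HOM mode: {mode!r}")
    g = gm.geno
    missing = g == MISSING
    n_missing = missing.sum(axis=0)
    het = (g == 1).any(axis=0)
    if mode == "either":
        ok = ~het
    else:
        ok = ((g == 2) | missing).all(axis=0)
    ok &= n_missing <= max_missing
    return gm.sites.loc[ok, "site_id"].tolist()


def ld_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over jointly non-missing entries. Returns ``nan`` (the
    "no LD information" signal, treated as r²=0 by the pruning routines)
    when fewer than two joint entries remain or either vector is constant.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    x = g_i[ok].astype(float)
    y = g_j[ok].astype(float)
    if len(x) < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def pairwise_r2_matrix(g: np.ndarray) -> np.ndarray:
    """All-pairs squared Pearson correlation between dosage columns.

    Missing-data aware: each pair is correlated over its jointly called
    samples, matching :func:`ld_r2`. Pairs with fewer than two joint calls
    or zero variance get nan.
    """
    called = (g != MISSING).astype(np.float64)
    x = np.where(g == MISSING, 0, g).astype(np.float64)
    x2 = x * x
    n = called.T @ called
    sx = x.T @ called  # [i, j] = sum of column i over sites shared with j
    sxy = x.T @ x
    sx2 = x2.T @ called
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_i = n * sx2 - sx * sx
        denom = var_i * var_i.T
        r2 = np.where((n >= 2) & (denom > 0), cov * cov / np.where(denom > 0, denom, 1), np.nan)
    return r2


def make_windows(scaffold_lengths: dict[str, int], window_size: int = 10_000) -> pd.DataFrame:
    """Tile each scaffold with non-overlapping windows (1-based, inclusive).

    The final partial window is kept. Focal point = window midpoint.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"scaffold {scaf!r} has non-positive length")
        start = 1
        while start <= length:
            end = min(start + window_size - 1, length)
            rows.append((scaf, start, end, (start + end) // 2))
            start = end + 1
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "focal_point"])


def assign_windows(sites: pd.DataFrame, window_size: int = 10_000) -> pd.Series:
    """Window key ``(scaffold, window_index)`` for each site by position."""
    widx = (sites["pos"].to_numpy(int) - 1) // window_size
    return pd.Series(list(zip(sites["scaffold"], widx)), index=sites.index, name="window")


def select_tag_snps(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.81,
    window_size: int = 10_000,
    max_missing: int = 6,
) -> list[str]:
    """Greedy tagSNP selection within tiled focal-point windows.

    Within each window: sites that are all-heterozygous or all-homozygous
    in the panel, or have more than ``max_missing`` missing calls, are
    discarded first. Remaining candidates are visited in descending MAF
    order (ties: ascending position) and accepted iff their r² with every
    already-accepted site in the window is strictly below the threshold
    (a pair at exactly the threshold counts as too correlated).
    """
    sites = gm.sites
    g = gm.geno
    missing = g == MISSING
    n_missing = missing.sum(axis=0)
    called = ~missing
    all_het = ((g == 1) | missing).all(axis=0) & called.any(axis=0)
    all_hom = (((g == 0) | (g == 2)) | missing).all(axis=0)
    informative = ~(all_het | all_hom) & (n_missing <= max_missing)

    maf = gm.minor_allele_frequencies()
    windows = assign_windows(sites, window_size)
    chosen: list[str] = []
    for _, idx in sites.groupby(windows, sort=False).groups.items():
        cand = [i for i in idx if informative[i]]
        # descending MAF, tie: ascending position
        cand.sort(key=lambda i: (-maf[i], sites.at[i, "pos"]))
        accepted: list[int] = []
        for i in cand:
            r2s = (ld_r2(g[:, i], g[:, j]) for j in accepted)
            if all(not (r2 >= r2_threshold) for r2 in r2s):  # nan -> no information -> accept
                accepted.append(i)
        accepted.sort(key=lambda i: sites.at[i, "pos"])
        chosen.extend(sites.loc[accepted, "site_id"])
    return chosen


def probe_cost(ref: str, alt: str) -> int:
    """2 for A/T and C/G SNPs (need one probe per allele), else 1."""
    pair = frozenset((str(ref).upper(), str(alt).upper()))
    return 2 if pair in (frozenset("AT"), frozenset("CG")) else 1


@dataclass
class SelectionResult:
    """Final panel with per-site selection reason and probe accounting."""

    table: pd.DataFrame  # site_id, scaffold, pos, ref, alt, reason, probe_cost
    totals_by_reason: dict[str, int]
    total_probe_cost: int
    shortfall: int = 0  # sites short of target_total, 0 if met or no target

    @property
    def site_ids(self) -> list[str]:
        return self.table["site_id"].tolist()

    def summary(self) -> dict:
        return {
            "n_selected": len(self.table),
            "totals_by_reason": dict(self.totals_by_reason),
            "total_probe_cost": self.total_probe_cost,
            "shortfall": self.shortfall,
        }


def assemble_panel(
    effect_ids: list[str],
    all_hom_ids: list[str],
    tag_ids: list[str],
    sites: pd.DataFrame,
    gm: GenotypeMatrix | None = None,
    target_total: int | None = None,
    probe_budget: int | None = None,
    window_size: int = 10_000,
) -> SelectionResult:
    """Union the three selection routes into the final panel.

    Sites in multiple routes take the highest-priority reason
    (HIGH_MOD_EFF > ALL_HOM > INFP). If ``target_total`` or
    ``probe_budget`` is exceeded, only INFP sites are trimmed — round-robin
    across windows, lowest-MAF first within each window — so effect and
    ALL_HOM sites are never dropped. An unreachable target is reported via
    ``shortfall`` (and a warning), never silently.
    """
    sites_idx = sites.set_index("site_id")
    reason: dict[str, str] = {}
    for ids, r in ((tag_ids, "INFP"), (all_hom_ids, "ALL_HOM"), (effect_ids, "HIGH_MOD_EFF")):
        for sid in ids:
            if sid not in sites_idx.index:
                raise KeyError(f"selected site {sid!r} not in site table")
            reason[sid] = r  # later loops overwrite with higher priority

    chosen = pd.DataFrame(
        {
            "site_id": list(reason.keys()),
            "reason": list(reason.values()),
        }
    )
    for col in ("scaffold", "pos", "ref", "alt"):
        chosen[col] = sites_idx.loc[chosen["site_id"], col].to_numpy()
    chosen["probe_cost"] = [
        probe_cost(r, a) for r, a in zip(chosen["ref"], chosen["alt"])
    ]

    maf_by_id: dict[str, float] = {}
    if gm is not None:
        maf = gm.minor_allele_frequencies()
        maf_by_id = dict(zip(gm.sites["site_id"], maf))
    chosen["maf"] = chosen["site_id"].map(maf_by_id).fillna(0.0)

    def over_budget(df: pd.DataFrame) -> bool:
        if target_total is not None and len(df) > target_total:
            return True
        if probe_budget is not None and df["probe_cost"].sum() > probe_budget:
            return True
        return False

    if over_budget(chosen):
        infp = chosen[chosen["reason"] == "INFP"].copy()
        infp["window"] = list(
            zip(infp["scaffold"], (infp["pos"].to_numpy(int) - 1) // window_size)
        )
        # per-window queues, lowest MAF first (tie: descending position = last added)
        queues: dict = {
            w: list(sub.sort_values(["maf", "pos"], ascending=[True, False])["site_id"])
            for w, sub in infp.groupby("window", sort=True)
        }
        order = sorted(queues)
        drop: list[str] = []
        kept = chosen.set_index("site_id")
        n_kept = len(kept)
        cost_kept = int(kept["probe_cost"].sum())

        def still_over() -> bool:
            if target_total is not None and n_kept > target_total:
                return True
            if probe_budget is not None and cost_kept > probe_budget:
                return True
            return False

        while still_over() and any(queues.values()):
            for w in order:
                if not still_over():
                    break
                if queues[w]:
                    sid = queues[w].pop(0)
                    drop.append(sid)
                    n_kept -= 1
                    cost_kept -= int(kept.at[sid, "probe_cost"])
        chosen = chosen[~chosen["site_id"].isin(drop)]
        if still_over():
            warnings.warn(
                "panel still exceeds target after trimming all INFP sites; "
                "effect/ALL_HOM sites are never trimmed",
                stacklevel=2,
            )

    shortfall = 0
    if target_total is not None and len(chosen) < target_total:
        shortfall = target_total - len(chosen)
        warnings.warn(
            f"panel target {target_total} unreachable: {len(chosen)} sites available "
            f"(shortfall {shortfall})",
            stacklevel=2,
        )

    chosen = chosen.sort_values(["scaffold", "pos"]).reset_index(drop=True)
    totals = {r: int((chosen["reason"] == r).sum()) for r in REASON_PRIORITY}
    return SelectionResult(
        table=chosen[["site_id", "scaffold", "pos", "ref", "alt", "reason", "probe_cost"]],
        totals_by_reason=totals,
        total_probe_cost=int(chosen["probe_cost"].sum()),
        shortfall=shortfall,
    )
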