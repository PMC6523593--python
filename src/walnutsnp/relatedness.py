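"""Pairwise relatedness from SNP dosages: KING-robust kinship and IBS0.

The KING-robust estimator infers the kinship coefficient between two
individuals from genotype-pair counts alone, without reference allele
frequencies, which keeps it unbiased in the presence of population
structure. Writing ``N_Aa,Aa`` for the number of sites where both samples
are heterozygous, ``N_AA,aa`` for opposite-homozygote sites and
``N^i_Aa`` for the heterozygote count of sample *i* over the jointly
called sites:

    k = (N_Aa,Aa - 2 N_AA,aa) / (2 min(N^i_Aa, N^j_Aa))
        + 1/2 - (N^i_Aa + N^j_Aa) / (4 min(N^i_Aa, N^j_Aa))

Expected values: 0.5 for identical genotypes, 0.25 for parent-offspring
and full sibs, 0.125 for half sibs, 0 for unrelated pairs. IBS0 — the
proportion of jointly called sites with opposite homozygotes — separates
parent-offspring (exactly 0 absent genotyping error) from full sibs.

Before estimation the genotype matrix passes the study prefilters: drop
samples below a 0.97 call rate, drop sites with missing rate above 0.2 or
MAF below 0.05, and LD-prune at r² 0.25 in 50-kb sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import pairwise_r2_matrix
from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PrefilterConfig:
    """Site/sample prefilters applied before kinship estimation."""

    max_missing_rate: float = 0.2
    min_maf: float = 0.05
    ld_r2: float = 0.25
    ld_window_bases: int = 50_000
    min_sample_call_rate: float = 0.97

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "min_sample_call_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.ld_window_bases <= 0:
            raise ValueError("ld_window_bases must be positive")


class PairCounts(NamedTuple):
    """Genotype-pair counts over jointly non-missing sites."""

    n_het_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int
    n_shared: int


def sample_qc(
    gm: GenotypeMatrix, min_call_rate: float = 0.97
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples whose call rate is below the threshold.

    Returns the retained matrix and an exclusion report (sample, call_rate,
    excluded). Raises if every sample would be dropped.
    """
    rates = gm.sample_call_rates()
    excluded = rates < min_call_rate
    report = pd.DataFrame(
        {"sample": rates.index, "call_rate": rates.to_numpy(), "excluded": excluded.to_numpy()}
    )
    keep = [s for s, ex in zip(rates.index, excluded) if not ex]
    if not keep:
        raise ValueError(f"all {gm.n_samples} samples fall below call rate {min_call_rate}")
    return gm.subset_samples(keep), report


def ld_prune(gm: GenotypeMatrix, cfg: PrefilterConfig = PrefilterConfig()) -> list[str]:
    """Greedy LD pruning in sliding windows along each scaffold.

    Sites are visited in position order; a site is kept iff its r² with
    every already-kept site within ``ld_window_bases`` upstream is at most
    ``ld_r2``. Pairs with no LD information (r² = nan) never exclude a
    site. Deterministic given the input order.
    """
    sites = gm.sites
    g = gm.geno
    kept_ids: list[str] = []
    for _, idx in sites.groupby("scaffold", sort=False).groups.items():
        order = sites.loc[idx].sort_values("pos").index.to_numpy()
        pos = sites.loc[order, "pos"].to_numpy()
        # precomputed r2 between scaffold-local columns (missing-aware)
        r2 = pairwise_r2_matrix(g[:, order])
        kept: list[int] = []  # scaffold-local indices, ascending position
        for a in range(len(order)):
            ok = True
            for b in reversed(kept):
                if pos[a] - pos[b] > cfg.ld_window_bases:
                    break
                if r2[a, b] > cfg.ld_r2:  # nan compares False: no information, keep
                    ok = False
                    break
            if ok:
                kept.append(a)
        kept_ids.extend(sites.loc[order[kept], "site_id"])
    return kept_ids


def pairwise_counts(g_i: np.ndarray, g_j: np.ndarray) -> PairCounts:
    """Genotype-pair counts for one sample pair over jointly called sites."""
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    a, b = g_i[ok], g_j[ok]
    return PairCounts(
        n_het_het=int(((a == 1) & (b == 1)).sum()),
        n_opp_hom=int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum()),
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
        n_shared=int(ok.sum()),
    )


def king_robust_kinship(counts: PairCounts) -> float:
    """KING-robust kinship coefficient; nan when either sample has no hets."""
    m = min(counts.n_het_i, counts.n_het_j)
    if m == 0:
        return float("nan")
    return (
        (counts.n_het_het - 2.0 * counts.n_opp_hom) / (2.0 * m)
        + 0.5
        - (counts.n_het_i + counts.n_het_j) / (4.0 * m)
    )


def ibs0(counts: PairCounts) -> float:
    """Proportion of jointly called sites with opposite homozygotes."""
    if counts.n_shared == 0:
        return float("nan")
    return counts.n_opp_hom / counts.n_shared


def site_prefilter_mask(gm: GenotypeMatrix, cfg: PrefilterConfig) -> np.ndarray:
    """Boolean mask of sites passing the missing-rate and MAF prefilters."""
    missing_ok = gm.site_missing_rates() <= cfg.max_missing_rate
    maf = gm.minor_allele_frequencies()
    maf_ok = np.nan_to_num(maf, nan=0.0) >= cfg.min_maf
    return missing_ok & maf_ok


def apply_prefilters(
    gm: GenotypeMatrix, cfg: PrefilterConfig = PrefilterConfig()
) -> GenotypeMatrix:
    """Missing-rate and MAF site filters followed by LD pruning."""
    pruned = gm.subset_sites(site_prefilter_mask(gm, cfg))
    return pruned.subset_sites_by_id(ld_prune(pruned, cfg))


def relatedness_matrix(
    gm: GenotypeMatrix,
    cfg: PrefilterConfig = PrefilterConfig(),
    prefilter: bool = True,
) -> pd.DataFrame:
    """All-pairs KING-robust kinship and IBS0 after the study prefilters.

    Returns one row per unordered pair (sample order as in ``gm``) with the
    genotype-pair counts, ``kinship`` and ``ibs0``. Undefined pairs (no
    shared sites, or no heterozygotes in one sample) carry nan rather than
    failing. Output is invariant to sample and site order up to row order.
    """
    work = apply_prefilters(gm, cfg) if prefilter else gm
    g = work.geno
    het = (g == 1).astype(np.float32)
    hom_ref = (g == 0).astype(np.float32)
    hom_alt = (g == 2).astype(np.float32)
    called = (g != MISSING).astype(np.float32)

    n_hh = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    n_shared = called @ called.T
    het_i = het @ called.T  # [i, j] = hets of i over sites shared with j

    min_het = np.minimum(het_i, het_i.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        kin = np.where(
            min_het > 0,
            (n_hh - 2.0 * n_opp) / (2.0 * min_het) + 0.5 - (het_i + het_i.T) / (4.0 * min_het),
            np.nan,
        )
        ib = np.where(n_shared > 0, n_opp / np.maximum(n_shared, 1), np.nan)

    iu, ju = np.triu_indices(work.n_samples, k=1)
    samples = np.asarray(work.samples, dtype=object)
    return pd.DataFrame(
        {
            "sample_i": samples[iu],
            "sample_j": samples[ju],
            "n_shared": n_shared[iu, ju].astype(int),
            "n_het_het": n_hh[iu, ju].astype(int),
            "n_opp_hom": n_opp[iu, ju].astype(int),
            "n_het_i": het_i[iu, ju].astype(int),
            "n_het_j": het_i[ju, iu].astype(int),
            "kinship": kin[iu, ju],
            "ibs0": ib[iu, ju],
        }
    )


def genotype_concordance(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    sample_map: dict[str, str] | None = None,
) -> tuple[pd.Series, float]:
    """Percent identical calls between two genotyping runs.

    Compares jointly non-missing genotypes at shared site ids, per sample
    (``sample_map`` maps ids in ``gm_a`` to ids in ``gm_b``; defaults to
    the shared ids). Returns (per-sample % concordance, mean %).
    """
    shared_sites = [s for s in gm_a.sites["site_id"] if s in set(gm_b.sites["site_id"])]
    if not shared_sites:
        raise ValueError("no shared sites between the two matrices")
    if sample_map is None:
        shared = [s for s in gm_a.samples if s in set(gm_b.samples)]
        sample_map = {s: s for s in shared}
    if not sample_map:
        raise ValueError("no samples to compare")
    a = gm_a.subset_sites_by_id(shared_sites)
    b = gm_b.subset_sites_by_id(shared_sites)
    out = {}
    for sa, sb in sample_map.items():
        ga = a.genotypes_of(sa)
        gb = b.genotypes_of(sb)
        ok = (ga != MISSING) & (gb != MISSING)
        n = int(ok.sum())
        out[sa] = 100.0 * float((ga[ok] == gb[ok]).mean()) if n else float("nan")
    per_sample = pd.Series(out, name="concordance_pct")
    return per_sample, float(np.nanmean(per_sample.to_numpy()))
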