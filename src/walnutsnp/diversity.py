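"""Diversity statistics, robust SNP sets, PCA and UPGMA clustering.

Per-site minor allele frequency, observed heterozygosity and missing rate;
per-family fixation index F_IS = 1 - Ho/He; "robust" SNP subsets defined
by zero Mendelian inconsistencies across all accepted trios and duos;
allele-frequency-scaled PCA of the dosage matrix; and a UPGMA dendrogram
on allele-sharing distance (1 - IBS), exported as newick.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import accepted_edges, mendelian_inconsistency

ROBUST_NMH_OTV_CLASSES = ("NMH", "OTV", "AAvar", "ABvar", "BBvar")


def snp_stats(gm: GenotypeMatrix, site_ids: list[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-site MAF, observed heterozygosity and missing rate, plus set means.

    All-missing sites get nan statistics and are excluded from the
    (unweighted) set means; their count is reported.
    """
    work = gm if site_ids is None else gm.subset_sites_by_id(site_ids)
    if work.n_sites == 0:
        raise ValueError("empty site set")
    g = work.geno
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (g == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    maf = work.minor_allele_frequencies()
    missing = work.site_missing_rates()
    per_site = pd.DataFrame(
        {
            "site_id": work.sites["site_id"],
            "maf": maf,
            "het": het,
            "missing_rate": missing,
        }
    )
    defined = n_called > 0
    means = {
        "n_sites": int(work.n_sites),
        "n_undefined": int((~defined).sum()),
        "mean_maf": float(np.nanmean(maf[defined])) if defined.any() else float("nan"),
        "mean_het": float(np.nanmean(het[defined])) if defined.any() else float("nan"),
        "mean_missing_rate": float(missing.mean()),
    }
    return per_site, means


def fis_per_family(
    gm: GenotypeMatrix,
    families: dict[str, str] | pd.Series,
    min_family_size: int = 5,
) -> pd.DataFrame:
    """Fixation index per family: F_IS = 1 - mean(Ho) / mean(He).

    Both means are taken over the family's polymorphic sites; expected
    heterozygosity He = 2p(1-p) uses the family's own allele frequencies.
    Negative values indicate an excess of heterozygotes relative to
    Hardy-Weinberg (typical of outbred full-sib families). Families smaller
    than ``min_family_size`` are skipped; a family with no polymorphic
    sites is reported with nan.
    """
    fam = pd.Series(families)
    rows = []
    for family, members in fam.groupby(fam).groups.items():
        members = [m for m in members if m in gm.samples]
        if len(members) < min_family_size:
            continue
        sub = gm.subset_samples(members)
        g = sub.geno
        called = g != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, np.where(called, g, 0).sum(axis=0) / (2 * n_called), np.nan)
        poly = (n_called > 0) & (p > 0) & (p < 1)
        if not poly.any():
            rows.append((family, len(members), 0, float("nan"), float("nan"), float("nan")))
            continue
        ho = ((g == 1).sum(axis=0) / n_called)[poly]
        he = (2 * p * (1 - p))[poly]
        mean_ho = float(ho.mean())
        mean_he = float(he.mean())
        fis = 1.0 - mean_ho / mean_he
        rows.append((family, len(members), int(poly.sum()), mean_ho, mean_he, fis))
    return pd.DataFrame(
        rows, columns=["family", "n_members", "n_polymorphic", "mean_ho", "mean_he", "fis"]
    )


def per_site_mendel_errors(gm: GenotypeMatrix, graph) -> pd.Series:
    """Mendelian error count per site over all accepted trios and duos.

    For every child in the reconstructed pedigree the trio rule is applied
    when both parents are accepted, the duo rule otherwise.
    """
    counts = np.zeros(gm.n_sites, dtype=int)
    parents_of: dict[str, list[str]] = {}
    for u, v, _ in accepted_edges(graph):
        parents_of.setdefault(v, []).append(u)
    for child, parents in parents_of.items():
        if child not in gm.samples:
            continue
        parents = [p for p in parents if p in gm.samples]
        if not parents:
            continue
        if len(parents) >= 2:
            _, flags = mendelian_inconsistency(
                gm.genotypes_of(child), gm.genotypes_of(parents[0]), gm.genotypes_of(parents[1])
            )
        else:
            _, flags = mendelian_inconsistency(gm.genotypes_of(child), gm.genotypes_of(parents[0]))
        counts += flags
    return pd.Series(counts, index=gm.sites["site_id"].to_numpy(), name="mendel_errors")


def derive_robust_sets(
    class_labels: pd.Series,
    mendel_errors: pd.Series | None,
) -> tuple[list[str], list[str]]:
    """Zero-Mendelian-error subsets of the genotyping quality classes.

    ``class_labels``: site_id -> quality class (PHR, NMH, OTV, AAvar,
    ABvar, BBvar, MHR, CRBT, HHR, Other). Returns (robust PHR, robust
    NMH+OTV) where the second set unions NMH, OTV, AAvar, ABvar and BBvar
    sites. With no Mendelian evidence (``mendel_errors`` None or empty)
    the full class sets are returned with a warning — the zero-error
    condition is vacuously true.
    """
    class_labels = pd.Series(class_labels)
    if mendel_errors is None or len(mendel_errors) == 0:
        warnings.warn(
            "no trios/duos tested: robust sets equal the input class sets", stacklevel=2
        )
        errors = pd.Series(0, index=class_labels.index)
    else:
        errors = pd.Series(mendel_errors).reindex(class_labels.index).fillna(0)
    clean = errors == 0
    robust_phr = class_labels.index[(class_labels == "PHR") & clean].tolist()
    robust_nmh = class_labels.index[
        class_labels.isin(ROBUST_NMH_OTV_CLASSES) & clean
    ].tolist()
    return robust_phr, robust_nmh


def pca(
    gm: GenotypeMatrix,
    site_ids: list[str] | None = None,
    n_components: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the dosage matrix with allele-frequency scaling.

    Dosages are centred by 2p and scaled by sqrt(2p(1-p)) with p the
    sample alternate-allele frequency; missing entries are mean-imputed
    (zero after centring). Monomorphic or all-missing sites are dropped.
    Returns the sample coordinates (``PC1..PCk``) and the full vector of
    variance-explained proportions (sums to 1).
    """
    work = gm if site_ids is None else gm.subset_sites_by_id(site_ids)
    if work.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    g = work.geno.astype(float)
    called = work.geno != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, g, 0).sum(axis=0) / (2 * n_called), np.nan)
    poly = (n_called > 0) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("PCA needs at least two polymorphic sites")
    g = g[:, poly]
    called = called[:, poly]
    p = p[poly]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    x[~called] = 0.0  # mean imputation after centring
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    if eigval.sum() <= 0:
        raise ValueError("degenerate genotype matrix: zero total variance")
    proportions = eigval / eigval.sum()
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    out = pd.DataFrame(
        coords, index=work.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return out, proportions


def ibs_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing distance matrix: 1 - mean per-site IBS proportion.

    Per-site IBS between dosages a and b is 1 - |a - b| / 2 (identical
    genotypes share both alleles, het vs hom share one, opposite
    homozygotes none), averaged over jointly called sites. Raises if any
    pair has no jointly called site.
    """
    g = gm.geno
    ind = [(g == c).astype(np.float32) for c in (0, 1, 2)]
    called = (g != MISSING).astype(np.float32)
    n_shared = called @ called.T
    absdiff = (
        2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
        + ind[0] @ ind[1].T
        + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T
        + ind[2] @ ind[1].T
    )
    if (n_shared == 0).any():
        raise ValueError("some sample pair shares no called sites")
    d = (absdiff / 2.0) / n_shared
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=gm.samples, columns=gm.samples)


def upgma(distances: pd.DataFrame) -> str:
    """UPGMA tree from a symmetric distance matrix, as rooted newick.

    Iteratively merges the nearest pair of clusters with size-weighted
    average linkage; the merge height is half the pair distance, so all
    leaves are equidistant from the root (ultrametric). Ties are broken by
    the lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf), making the output deterministic.
    """
    labels = list(distances.index)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    d = distances.to_numpy(float).copy()
    if not np.allclose(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
        raise ValueError("distances must be symmetric and non-negative with zero diagonal")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")

    # active clusters: key -> (label, size, height, newick fragment)
    active = {i: (labels[i], 1, 0.0, labels[i]) for i in range(len(labels))}
    dist = {
        (i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
    }
    next_key = len(labels)
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((active[kv[0][0]][0], active[kv[0][1]][0])))),
        )
        (a, b), dab = best
        la, na, ha, nwa = active[a]
        lb, nb, hb, nwb = active[b]
        if lb < la:  # children ordered by label for deterministic output
            a, b = b, a
            (la, na, ha, nwa), (lb, nb, hb, nwb) = (lb, nb, hb, nwb), (la, na, ha, nwa)
        h = dab / 2.0
        # shortest round-trip float repr: exact branch lengths, clean output
        newick = f"({nwa}:{float(h - ha)!r},{nwb}:{float(h - hb)!r})"
        merged = (min(la, lb), na + nb, h, newick)
        for other in list(active):
            if other in (a, b):
                continue
            ka = (min(a, other), max(a, other))
            kb = (min(b, other), max(b, other))
            dnew = (na * dist[ka] + nb * dist[kb]) / (na + nb)
            del dist[ka], dist[kb]
            dist[(min(other, next_key), max(other, next_key))] = dnew
        del dist[(min(a, b), max(a, b))], active[a], active[b]
        active[next_key] = merged
        next_key += 1
    (_, _, _, newick) = next(iter(active.values()))
    return newick + ";"
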