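"""Dosage-coded genotype matrix shared by all pipeline stages.

Genotypes are stored as int8 dosages of the alternate allele:
0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
``MISSING`` (-1) = no call. Coordinates are 1-based throughout (VCF
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

SITE_COLUMNS = ["site_id", "scaffold", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of allele dosages plus site metadata.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``geno``.
    sites
        Site table with at least ``site_id``, ``scaffold``, ``pos``,
        ``ref``, ``alt`` columns; one row per column of ``geno``.
    geno
        int8 array of shape ``(n_samples, n_sites)`` with values in
        {0, 1, 2, MISSING}.
    """

    samples: list[str]
    sites: pd.DataFrame
    geno: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype array shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns: {missing_cols}")
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        self.sites = self.sites.reset_index(drop=True)

    # -- basic shape -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def genotypes_of(self, sample: str) -> np.ndarray:
        return self.geno[self.sample_index(sample)]

    # -- per-sample / per-site summaries ---------------------------------
    def sample_call_rates(self) -> pd.Series:
        """Fraction of non-missing calls per sample."""
        rates = (self.geno != MISSING).mean(axis=1)
        return pd.Series(rates, index=self.samples, name="call_rate")

    def site_missing_rates(self) -> np.ndarray:
        return (self.geno == MISSING).mean(axis=0)

    def alt_allele_frequencies(self) -> np.ndarray:
        """Per-site alternate allele frequency from non-missing dosages.

        Sites with no calls get ``nan``.
        """
        called = self.geno != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.geno, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.alt_allele_frequencies()
        return np.minimum(p, 1.0 - p)

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.sites.copy(), self.geno[idx].copy())

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer positions (keeps order)."""
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = arr.astype(int)
        return GenotypeMatrix(
            list(self.samples), self.sites.iloc[idx].reset_index(drop=True), self.geno[:, idx].copy()
        )

    def subset_sites_by_id(self, site_ids) -> "GenotypeMatrix":
        pos = pd.Index(self.sites["site_id"])
        idx = pos.get_indexer(list(site_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(site_ids, idx) if i < 0]
            raise KeyError(f"unknown site ids: {missing[:5]}")
        return self.subset_sites(idx)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.sites.copy(), self.geno.copy())


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same site table."""
    if not a.sites["site_id"].equals(b.sites["site_id"]):
        raise ValueError("site tables differ; cannot stack samples")
    dup = set(a.samples) & set(b.samples)
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)[:5]}")
    return GenotypeMatrix(a.samples + b.samples, a.sites.copy(), np.vstack([a.geno, b.geno]))
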