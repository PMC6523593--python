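"""Synthetic founder panels, crosses, genotyping errors and site annotations.

The generator emulates the data underlying a walnut breeding-program
genotyping study: a small panel of highly heterozygous founders (mean
observed heterozygosity ~0.26), multi-generation controlled and
open-pollinated crosses recorded in a (possibly mislabelled) pedigree,
per-genotype error and missingness, and VCF-style per-site quality and
array-design annotations. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotypes import MISSING, GenotypeMatrix, concat_samples

#: Sentinel sire id for an open-pollinated cross (sire drawn at random).
OPEN = "OPEN"

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults follow the study conditions: 27 founders, heterozygosity
    target 0.26, biallelic SNPs spread over scaffolds. ``maf_distribution``
    is a spec string: ``"uniform(a,b)"``, ``"beta(a,b)"`` (scaled to
    [0, 0.5]) or ``"fixed(p)"``. When ``None``, a uniform law
    ``uniform(0.05, b)`` is derived with ``b`` solved so the mean
    Hardy-Weinberg heterozygosity 2pq equals ``target_het``.
    """

    n_founders: int = 27
    n_sites: int = 10_000
    n_scaffolds: int = 20
    scaffold_length: int = 5_000_000
    maf_distribution: str | None = None
    target_het: float = 0.26
    geno_error_rate: float = 0.01
    missing_rate: float = 0.01
    mislabel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_sites", "n_scaffolds", "scaffold_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("target_het", "geno_error_rate", "missing_rate", "mislabel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sites < self.n_scaffolds:
            raise ValueError("need at least one site per scaffold")

    def resolved_maf_distribution(self) -> str:
        """The MAF spec string, deriving the default from ``target_het``."""
        if self.maf_distribution is not None:
            return self.maf_distribution
        lo = 0.05

        def mean_het(hi: float) -> float:
            # mean of 2p(1-p) for p ~ U(lo, hi), closed form
            return (lo + hi) - 2.0 / 3.0 * (lo * lo + lo * hi + hi * hi)

        if not mean_het(lo + 1e-6) <= self.target_het <= mean_het(0.5):
            raise ValueError(
                f"target_het={self.target_het} unreachable with uniform MAF on [0.05, 0.5]"
            )
        hi = brentq(lambda b: mean_het(b) - self.target_het, lo + 1e-6, 0.5)
        return f"uniform({lo},{hi:.6f})"

    def draw_mafs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        spec = self.resolved_maf_distribution()
        name, _, args = spec.partition("(")
        vals = [float(x) for x in args.rstrip(")").split(",")] if args.rstrip(")") else []
        name = name.strip().lower()
        if name == "uniform":
            a, b = vals
            if not 0 <= a <= b <= 0.5:
                raise ValueError("uniform MAF bounds must satisfy 0 <= a <= b <= 0.5")
            return rng.uniform(a, b, size=n)
        if name == "beta":
            a, b = vals
            return 0.5 * rng.beta(a, b, size=n)
        if name == "fixed":
            (p,) = vals
            if not 0 <= p <= 0.5:
                raise ValueError("fixed MAF must be in [0, 0.5]")
            return np.full(n, p)
        raise ValueError(f"unknown maf_distribution: {spec!r}")


@dataclass(frozen=True)
class Cross:
    """One planned cross: ``sire`` may be :data:`OPEN` for open pollination."""

    dam: str
    sire: str
    n_offspring: int

    def __post_init__(self) -> None:
        if self.dam == self.sire:
            raise ValueError(f"dam and sire are identical: {self.dam!r}")
        if self.n_offspring <= 0:
            raise ValueError("n_offspring must be positive")


@dataclass
class CrossPlan:
    """Ordered list of crosses; later crosses may use earlier offspring."""

    crosses: list[Cross] = field(default_factory=list)

    def add(self, dam: str, sire: str, n_offspring: int) -> "CrossPlan":
        self.crosses.append(Cross(dam, sire, n_offspring))
        return self

    def __iter__(self):
        return iter(self.crosses)

    def __len__(self) -> int:
        return len(self.crosses)


def _make_site_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out sites over scaffolds with sorted, distinct 1-based positions."""
    per = np.full(cfg.n_scaffolds, cfg.n_sites // cfg.n_scaffolds)
    per[: cfg.n_sites % cfg.n_scaffolds] += 1
    rows = []
    for s, k in enumerate(per):
        pos = np.sort(rng.choice(cfg.scaffold_length, size=k, replace=False) + 1)
        rows.append(pd.DataFrame({"scaffold": f"scaffold_{s:04d}", "pos": pos}))
    sites = pd.concat(rows, ignore_index=True)
    ref_idx = rng.integers(0, 4, size=len(sites))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(sites))) % 4
    sites["ref"] = _NUCS[ref_idx]
    sites["alt"] = _NUCS[alt_idx]
    sites.insert(0, "site_id", [f"snp_{i:07d}" for i in range(len(sites))])
    return sites[["site_id", "scaffold", "pos", "ref", "alt"]]


def simulate_founders(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw an unrelated founder panel under Hardy-Weinberg equilibrium.

    Each site gets a true minor allele frequency from the configured
    distribution; the minor allele is assigned to REF or ALT with equal
    probability so the alternate-allele frequency spans (0, 1). Founder
    dosages are Binomial(2, p_alt) per sample.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The founder matrix and a site truth table with columns
        ``site_id, scaffold, pos, ref, alt, true_maf, true_alt_freq``.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _make_site_table(cfg, rng)
    maf = cfg.draw_mafs(rng, len(sites))
    minor_is_alt = rng.random(len(sites)) < 0.5
    p_alt = np.where(minor_is_alt, maf, 1.0 - maf)
    geno = rng.binomial(2, p_alt, size=(cfg.n_founders, len(sites))).astype(np.int8)
    samples = [f"founder_{i:03d}" for i in range(cfg.n_founders)]
    truth = sites.copy()
    truth["true_maf"] = maf
    truth["true_alt_freq"] = p_alt
    return GenotypeMatrix(samples, sites, geno), truth


def _gametes(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted alt-allele count per site under Mendelian segregation.

    Homozygotes transmit their allele; heterozygotes a fair coin. A missing
    parent genotype (should not occur on clean simulated input) transmits a
    fair coin as an uninformative fallback.
    """
    het = parent_geno == 1
    out = (parent_geno == 2).astype(np.int8)
    coin = rng.integers(0, 2, size=parent_geno.shape).astype(np.int8)
    out[het] = coin[het]
    missing = parent_geno == MISSING
    if missing.any():
        out[missing] = coin[missing]
    return out


def simulate_pedigree(
    founders: GenotypeMatrix,
    plan: CrossPlan,
    seed: int,
    open_sire_candidates: list[str] | None = None,
) -> tuple[GenotypeMatrix, nx.DiGraph]:
    """Breed offspring from a cross plan and return the true pedigree.

    Every offspring genotype is one Mendelian allele draw per parent per
    site. For :data:`OPEN` crosses the sire is drawn uniformly from
    ``open_sire_candidates`` (default: all founders except the dam); the
    truth graph still records the realised sire, with the node flagged
    ``open_pollinated`` so recorded-pedigree exports can blank it.

    Returns the combined matrix (founders then offspring, in plan order)
    and a directed parent->child graph with edge attribute ``role`` in
    {"dam", "sire"} and node attribute ``generation``.
    """
    rng = np.random.default_rng(seed)
    truth = nx.DiGraph()
    for s in founders.samples:
        truth.add_node(s, generation=0, open_pollinated=False)

    geno_by_id: dict[str, np.ndarray] = {
        s: founders.geno[i] for i, s in enumerate(founders.samples)
    }
    generation: dict[str, int] = {s: 0 for s in founders.samples}
    new_samples: list[str] = []
    new_rows: list[np.ndarray] = []
    counter = 0
    for cross in plan:
        if cross.dam not in geno_by_id:
            raise KeyError(f"unknown dam id: {cross.dam!r}")
        is_open = cross.sire == OPEN
        if not is_open and cross.sire not in geno_by_id:
            raise KeyError(f"unknown sire id: {cross.sire!r}")
        for _ in range(cross.n_offspring):
            if is_open:
                pool = open_sire_candidates or [
                    s for s in founders.samples if s != cross.dam
                ]
                pool = [s for s in pool if s != cross.dam]
                if not pool:
                    raise ValueError("no eligible open-pollination sires")
                sire = pool[rng.integers(0, len(pool))]
            else:
                sire = cross.sire
            child = f"off_{counter:05d}"
            counter += 1
            g = _gametes(geno_by_id[cross.dam], rng) + _gametes(geno_by_id[sire], rng)
            geno_by_id[child] = g.astype(np.int8)
            gen = max(generation[cross.dam], generation[sire]) + 1
            generation[child] = gen
            truth.add_node(child, generation=gen, open_pollinated=is_open)
            truth.add_edge(cross.dam, child, role="dam")
            truth.add_edge(sire, child, role="sire")
            new_samples.append(child)
            new_rows.append(geno_by_id[child])

    offspring = GenotypeMatrix(
        new_samples,
        founders.sites.copy(),
        np.vstack(new_rows) if new_rows else np.empty((0, founders.n_sites), np.int8),
    )
    return concat_samples(founders, offspring), truth


def inject_errors(
    gm: GenotypeMatrix, cfg: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Apply symmetric genotype-flip errors, then missingness.

    Each called genotype is independently replaced, with probability
    ``cfg.geno_error_rate``, by one of the two other dosage codes (chosen
    uniformly), then set missing with probability ``cfg.missing_rate``.

    Returns ``(corrupted matrix, error_mask, missing_mask)`` where the
    boolean masks mark flipped and masked entries.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    geno = gm.geno.copy()
    called = geno != MISSING
    err = (rng.random(geno.shape) < cfg.geno_error_rate) & called
    if err.any():
        # flip to one of the two other codes, uniformly
        shift = rng.integers(1, 3, size=int(err.sum()))
        geno[err] = ((geno[err] + shift) % 3).astype(np.int8)
    miss = (rng.random(geno.shape) < cfg.missing_rate) & called
    geno[miss] = MISSING
    return GenotypeMatrix(list(gm.samples), gm.sites.copy(), geno), err, miss


def pedigree_to_records(truth: nx.DiGraph) -> pd.DataFrame:
    """Faithful 3-column recorded-pedigree table (id, dam, sire; "0" unknown).

    Sires of open-pollinated offspring are recorded as unknown, as a
    breeding program's ledger would.
    """
    rows = []
    for node in truth.nodes:
        dam = sire = "0"
        for parent, _, d in truth.in_edges(node, data=True):
            if d["role"] == "dam":
                dam = parent
            else:
                sire = parent
        if truth.nodes[node].get("open_pollinated", False):
            sire = "0"
        rows.append((node, dam, sire))
    return pd.DataFrame(rows, columns=["id", "dam", "sire"])


def corrupt_records(
    truth: nx.DiGraph,
    mislabel_rate: float,
    seed: int,
    candidates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recorded pedigree with mislabelling errors injected.

    Each known recorded parent entry is independently replaced with
    probability ``mislabel_rate`` by a wrong id drawn uniformly from
    ``candidates`` (default: all ids in the graph), excluding the child
    itself and both of its true parents — a "mislabel" that happens to name
    a true parent is not an error in any detectable sense.

    Returns ``(records, mislabel_mask)``; the mask has boolean columns
    ``dam_mislabelled`` / ``sire_mislabelled`` per child row.
    """
    if not 0.0 <= mislabel_rate <= 1.0:
        raise ValueError("mislabel_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = pedigree_to_records(truth)
    pool_all = list(candidates) if candidates is not None else list(truth.nodes)
    mask = pd.DataFrame(
        {
            "id": records["id"],
            "dam_mislabelled": False,
            "sire_mislabelled": False,
        }
    )
    for i, row in records.iterrows():
        true_parents = {p for p, _, _ in truth.in_edges(row["id"], data=True)}
        for col, flag in (("dam", "dam_mislabelled"), ("sire", "sire_mislabelled")):
            if row[col] == "0":
                continue
            if rng.random() < mislabel_rate:
                pool = [c for c in pool_all if c != row["id"] and c not in true_parents]
                if not pool:
                    continue
                records.at[i, col] = pool[rng.integers(0, len(pool))]
                mask.at[i, flag] = True
    return records, mask


# ---------------------------------------------------------------------------
# Site annotation
# ---------------------------------------------------------------------------

#: Fraction of sites seeded to fail each filter predicate, by rule id.
DEFAULT_FAIL_FRACTIONS: dict[str, float] = {
    "qual": 0.05,
    "mq": 0.05,
    "depth": 0.05,
    "strand": 0.05,
    "dp4_support": 0.05,
    "indel": 0.03,
    "multiallelic": 0.03,
    "flank": 0.05,
    "sixteen_mer": 0.05,
    "p_convert": 0.05,
}

EFFECT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER", "NONE")


def annotate_sites(
    gm: GenotypeMatrix,
    seed: int,
    fail_fractions: dict[str, float] | None = None,
    effect_fractions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Attach VCF-style quality and array-design annotations to sites.

    Baseline annotations are drawn to pass every filter predicate; for each
    rule id in ``fail_fractions`` an independent random subset of sites is
    then overwritten with values that fail that predicate, and the truth is
    recorded in a ``seeded_fail_<rule>`` column. AC/AN are computed from the
    genotypes actually present in ``gm`` (so the allele-frequency predicate
    has a computed, not seeded, truth column ``fails_freq``).
    """
    rng = np.random.default_rng(seed)
    frac = dict(DEFAULT_FAIL_FRACTIONS)
    if fail_fractions:
        frac.update(fail_fractions)
    for k, v in frac.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fail fraction for {k!r} must be in [0, 1]")

    n = gm.n_sites
    df = gm.sites.copy()

    called = gm.geno != MISSING
    df["AN"] = 2 * called.sum(axis=0)
    df["AC"] = np.where(called, gm.geno, 0).sum(axis=0)

    # baseline: everything passes
    df["QUAL"] = rng.uniform(100.0, 2000.0, n).round(2)
    df["MQ"] = rng.uniform(40.0, 60.0, n).round(2)
    dp = rng.integers(400, 4001, n)
    df["DP"] = dp
    # DP4 split: high-quality fraction >= 0.8, both alleles on both strands
    hq = np.floor(dp * rng.uniform(0.85, 1.0, n)).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(df["AN"] > 0, df["AC"] / np.maximum(df["AN"], 1), 0.5)
    alt_frac = np.clip(alt_frac, 0.1, 0.9)
    alt_reads = np.clip((hq * alt_frac).astype(int), 4, np.maximum(hq - 4, 4))
    ref_reads = hq - alt_reads
    rf = np.clip((ref_reads * rng.uniform(0.4, 0.6, n)).astype(int), 2, None)
    af = np.clip((alt_reads * rng.uniform(0.4, 0.6, n)).astype(int), 2, None)
    df["DP4_ref_fwd"] = rf
    df["DP4_ref_rev"] = np.maximum(ref_reads - rf, 2)
    df["DP4_alt_fwd"] = af
    df["DP4_alt_rev"] = np.maximum(alt_reads - af, 2)

    df["is_indel"] = False
    df["n_alleles"] = 2
    df["flank_variant_left"] = rng.random(n) < 0.10
    df["flank_variant_right"] = np.where(
        df["flank_variant_left"], False, rng.random(n) < 0.10
    )
    df["sixteen_mer_count"] = rng.integers(1, 301, n)
    df["p_convert_fwd"] = rng.uniform(0.61, 1.0, n).round(4)
    df["p_convert_rev"] = rng.uniform(0.61, 1.0, n).round(4)

    eff = dict({"HIGH": 0.01, "MODERATE": 0.03, "LOW": 0.06, "MODIFIER": 0.30, "NONE": 0.60})
    if effect_fractions:
        eff.update(effect_fractions)
    probs = np.array([eff[c] for c in EFFECT_CLASSES], dtype=float)
    probs = probs / probs.sum()
    df["effect_class"] = rng.choice(np.array(EFFECT_CLASSES, dtype=object), size=n, p=probs)

    def seeded(rule: str) -> np.ndarray:
        m = rng.random(n) < frac[rule]
        df[f"seeded_fail_{rule}"] = m
        return m

    m = seeded("qual")
    df.loc[m, "QUAL"] = rng.uniform(0.0, 60.0, int(m.sum())).round(2)
    m = seeded("mq")
    df.loc[m, "MQ"] = rng.uniform(0.0, 20.0, int(m.sum())).round(2)
    m = seeded("depth")
    k = int(m.sum())
    low = rng.random(k) < 0.5
    vals = np.where(low, rng.integers(0, 200, k), rng.integers(4581, 9000, k))
    df.loc[m, "DP"] = vals
    # keep DP4 sum <= DP and supportive on the low side
    sub = df.loc[m, ["DP4_ref_fwd", "DP4_ref_rev", "DP4_alt_fwd", "DP4_alt_rev"]].to_numpy(float)
    tot = np.maximum(sub.sum(axis=1), 1)
    scale = np.minimum(1.0, 0.9 * vals / tot)
    df.loc[m, ["DP4_ref_fwd", "DP4_ref_rev", "DP4_alt_fwd", "DP4_alt_rev"]] = np.maximum(
        np.floor(sub * scale[:, None]), 2
    ).astype(int)
    m = seeded("strand")
    # fail the default both-strand-support rule: one component drops to <= 1
    which = rng.integers(0, 4, int(m.sum()))
    cols = ["DP4_ref_fwd", "DP4_ref_rev", "DP4_alt_fwd", "DP4_alt_rev"]
    for j, col in enumerate(cols):
        rows = df.index[m][which == j]
        df.loc[rows, col] = rng.integers(0, 2, len(rows))
    m = seeded("dp4_support")
    sub = df.loc[m, cols].to_numpy(float)
    dp_m = df.loc[m, "DP"].to_numpy(float)
    tot = np.maximum(sub.sum(axis=1), 1)
    scale = 0.5 * dp_m / tot  # sum(DP4)/DP ~ 0.5 < 0.75
    df.loc[m, cols] = np.maximum(np.floor(sub * scale[:, None]), 0).astype(int)
    m = seeded("indel")
    df.loc[m, "is_indel"] = True
    m = seeded("multiallelic")
    df.loc[m, "n_alleles"] = 3
    m = seeded("flank")
    df.loc[m, ["flank_variant_left", "flank_variant_right"]] = True
    m = seeded("sixteen_mer")
    df.loc[m, "sixteen_mer_count"] = rng.integers(301, 1001, int(m.sum()))
    m = seeded("p_convert")
    df.loc[m, "p_convert_fwd"] = rng.uniform(0.0, 0.6, int(m.sum())).round(4)
    df.loc[m, "p_convert_rev"] = rng.uniform(0.0, 0.6, int(m.sum())).round(4)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(df["AN"] > 0, df["AC"] / np.maximum(df["AN"], 1), np.nan)
    df["fails_freq"] = (ratio < 0.05) | (ratio > 0.95)

    # construction invariant: sum(DP4) <= DP
    dp4_sum = df[cols].sum(axis=1)
    over = dp4_sum > df["DP"]
    if over.any():
        df.loc[over, "DP"] = dp4_sum[over]
    return df


def default_cross_plan(
    founders: list[str],
    n_families: int = 10,
    offspring_per_family: int = 20,
    n_open: int = 0,
    seed: int = 0,
) -> CrossPlan:
    """Convenience plan: random founder pairs, optionally open-pollinated dams."""
    rng = np.random.default_rng(seed)
    plan = CrossPlan()
    for _ in range(n_families):
        dam, sire = rng.choice(len(founders), size=2, replace=False)
        plan.add(founders[dam], founders[sire], offspring_per_family)
    for _ in range(n_open):
        dam = rng.integers(0, len(founders))
        plan.add(founders[dam], OPEN, 1)
    return plan
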