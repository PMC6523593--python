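"""Quality and array-candidate filters over annotated variant sites.

Two filter stages are applied to a multi-sample callset before array
design. The quality stage removes low-confidence calls (site quality,
mapping quality, aggregate depth, strand support, high-quality read
fraction, extreme allele frequency); the array-candidate stage removes
sites unlikely to convert into working array probes (indels, multiallelic
sites, variants flanked on both sides, repetitive 16-mer context, poor
probe conversion scores on both strands). Every threshold is configurable;
defaults are the published design values.

Boundary semantics follow the printed comparators exactly: QUAL <= 60
fails, DP < 200 or DP > 4580 fails, AC/AN < 0.05 fails (0.05 itself
passes), 16-mer count > 300 fails, P-convert <= 0.6 on BOTH strands fails.

The strand rule is ambiguous in its source description; by default a site
is removed unless both alleles are seen more than once on both strands
(``strand_mode="require_both_strands"``). The literal reading — remove
when all four DP4 components exceed 1 — is available with
``strand_mode="literal"``.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QUALITY_RULES = ("qual", "mq", "depth", "strand", "dp4_support", "freq")
ARRAY_RULES = ("indel", "multiallelic", "flank", "sixteen_mer", "p_convert")
ALL_RULES = QUALITY_RULES + ARRAY_RULES

_DP4_COLS = ("DP4_ref_fwd", "DP4_ref_rev", "DP4_alt_fwd", "DP4_alt_rev")

_REQUIRED_QUALITY = ("QUAL", "MQ", "DP", *_DP4_COLS, "AC", "AN")
_REQUIRED_ARRAY = (
    "is_indel",
    "n_alleles",
    "flank_variant_left",
    "flank_variant_right",
    "sixteen_mer_count",
    "p_convert_fwd",
    "p_convert_rev",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both filter stages (defaults = published values)."""

    min_qual: float = 60.0  # fail if QUAL <= min_qual
    min_mq: float = 20.0  # fail if MQ <= min_mq
    min_dp: int = 200  # fail if DP < min_dp
    max_dp: int = 4580  # fail if DP > max_dp
    min_dp4_fraction: float = 0.75  # fail if sum(DP4)/DP < this
    min_freq: float = 0.05  # fail if AC/AN < this
    max_freq: float = 0.95  # fail if AC/AN > this
    strand_mode: str = "require_both_strands"  # or "literal"
    max_sixteen_mer: int = 300  # fail if 16-mer count > this
    min_p_convert: float = 0.6  # fail if both strands <= this
    strict: bool = False  # abort on malformed records in run_filters

    def __post_init__(self) -> None:
        if self.strand_mode not in ("require_both_strands", "literal"):
            raise ValueError(f"unknown strand_mode: {self.strand_mode!r}")


@dataclass
class FilterReport:
    """Audit trail of a filter run.

    ``failed_rules`` lists, per site, every failed rule in canonical order;
    ``first_fail_counts`` attributes each removed site to its first failing
    rule so the per-rule counts partition the removals.
    """

    n_input: int
    n_pass: int
    failed_rules: pd.Series  # site_id -> tuple of rule ids (empty if passing)
    first_fail_counts: dict[str, int]
    n_malformed: int = 0

    @property
    def pass_mask(self) -> pd.Series:
        return self.failed_rules.apply(lambda r: len(r) == 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.failed_rules.index,
                "pass": [len(r) == 0 for r in self.failed_rules],
                "failed_rules": [",".join(r) for r in self.failed_rules],
            }
        )

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass": self.n_pass,
            "n_malformed": self.n_malformed,
            "removed_by_rule": dict(self.first_fail_counts),
        }


def _require(site: Mapping, fields: tuple[str, ...]) -> None:
    for f in fields:
        if f not in site or site[f] is None or (
            isinstance(site[f], float) and np.isnan(site[f])
        ):
            raise KeyError(f"site is missing required annotation field {f!r}")


def quality_filter(site: Mapping, cfg: FilterConfig = FilterConfig()) -> tuple[bool, list[str]]:
    """Evaluate the quality-stage predicates on one site.

    Returns ``(passed, reasons)`` where ``reasons`` lists every failed rule
    id in canonical order. A missing annotation field raises ``KeyError``
    naming the field.
    """
    _require(site, _REQUIRED_QUALITY)
    reasons = []
    if site["QUAL"] <= cfg.min_qual:
        reasons.append("qual")
    if site["MQ"] <= cfg.min_mq:
        reasons.append("mq")
    if site["DP"] < cfg.min_dp or site["DP"] > cfg.max_dp:
        reasons.append("depth")
    dp4 = [site[c] for c in _DP4_COLS]
    all_above_one = all(x > 1 for x in dp4)
    if cfg.strand_mode == "literal":
        if all_above_one:
            reasons.append("strand")
    elif not all_above_one:
        reasons.append("strand")
    if site["DP"] > 0 and sum(dp4) / site["DP"] < cfg.min_dp4_fraction:
        reasons.append("dp4_support")
    if site["AN"] > 0:
        ratio = site["AC"] / site["AN"]
        if ratio < cfg.min_freq or ratio > cfg.max_freq:
            reasons.append("freq")
    return (len(reasons) == 0, reasons)


def array_candidate_filter(
    site: Mapping, cfg: FilterConfig = FilterConfig()
) -> tuple[bool, list[str]]:
    """Evaluate the array-candidate (probe convertibility) predicates."""
    _require(site, _REQUIRED_ARRAY)
    reasons = []
    if site["is_indel"]:
        reasons.append("indel")
    if site["n_alleles"] > 2:
        reasons.append("multiallelic")
    if site["flank_variant_left"] and site["flank_variant_right"]:
        reasons.append("flank")
    if site["sixteen_mer_count"] > cfg.max_sixteen_mer:
        reasons.append("sixteen_mer")
    if site["p_convert_fwd"] <= cfg.min_p_convert and site["p_convert_rev"] <= cfg.min_p_convert:
        reasons.append("p_convert")
    return (len(reasons) == 0, reasons)


def _vector_failures(sites: pd.DataFrame, cfg: FilterConfig) -> dict[str, np.ndarray]:
    """Vectorised per-rule failure masks over a site table."""
    for f in _REQUIRED_QUALITY + _REQUIRED_ARRAY:
        if f not in sites.columns:
            raise KeyError(f"site table is missing required annotation field {f!r}")
    dp4 = sites[list(_DP4_COLS)].to_numpy(float)
    dp = sites["DP"].to_numpy(float)
    all_above_one = (dp4 > 1).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            sites["AN"].to_numpy(float) > 0,
            sites["AC"].to_numpy(float) / np.maximum(sites["AN"].to_numpy(float), 1),
            np.nan,
        )
        dp4_frac = np.where(dp > 0, dp4.sum(axis=1) / np.maximum(dp, 1), 1.0)
    fails = {
        "qual": sites["QUAL"].to_numpy(float) <= cfg.min_qual,
        "mq": sites["MQ"].to_numpy(float) <= cfg.min_mq,
        "depth": (dp < cfg.min_dp) | (dp > cfg.max_dp),
        "strand": all_above_one if cfg.strand_mode == "literal" else ~all_above_one,
        "dp4_support": dp4_frac < cfg.min_dp4_fraction,
        "freq": (ratio < cfg.min_freq) | (ratio > cfg.max_freq),
        "indel": sites["is_indel"].to_numpy(bool),
        "multiallelic": sites["n_alleles"].to_numpy(int) > 2,
        "flank": sites["flank_variant_left"].to_numpy(bool)
        & sites["flank_variant_right"].to_numpy(bool),
        "sixteen_mer": sites["sixteen_mer_count"].to_numpy(int) > cfg.max_sixteen_mer,
        "p_convert": (sites["p_convert_fwd"].to_numpy(float) <= cfg.min_p_convert)
        & (sites["p_convert_rev"].to_numpy(float) <= cfg.min_p_convert),
    }
    return fails


def run_filters(
    sites: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the quality stage then the array-candidate stage to a site table.

    Array-stage predicates are only attributed for sites that survive the
    quality stage (matching the two-stage pipeline), but ``failed_rules``
    records every failed quality rule for removed sites. Returns the
    surviving sites (original order) and a :class:`FilterReport`.
    """
    if len(sites) == 0:
        empty = pd.Series([], dtype=object, name="failed_rules")
        return sites.copy(), FilterReport(0, 0, empty, {r: 0 for r in ALL_RULES})
    fails = _vector_failures(sites, cfg)

    qual_fail = np.zeros(len(sites), dtype=bool)
    for r in QUALITY_RULES:
        qual_fail |= fails[r]
    failed_lists: list[tuple[str, ...]] = []
    first_fail = {r: 0 for r in ALL_RULES}
    for i in range(len(sites)):
        row_rules = [r for r in QUALITY_RULES if fails[r][i]]
        if not row_rules:  # survived quality stage; evaluate array stage
            row_rules = [r for r in ARRAY_RULES if fails[r][i]]
        if row_rules:
            first_fail[row_rules[0]] += 1
        failed_lists.append(tuple(row_rules))

    failed_series = pd.Series(failed_lists, index=sites["site_id"].to_numpy(), name="failed_rules")
    pass_mask = np.array([len(r) == 0 for r in failed_lists])
    survivors = sites.loc[pass_mask].reset_index(drop=True)
    report = FilterReport(
        n_input=len(sites),
        n_pass=int(pass_mask.sum()),
        failed_rules=failed_series,
        first_fail_counts=first_fail,
    )
    return survivors, report
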