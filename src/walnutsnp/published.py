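"""Published genotyping summary counts for the 700K walnut SNP array.

The array's validation on a 1284-tree walnut collection was reported as a
table of variant counts per Axiom genotyping quality class (PHR, NMH, OTV,
MHR, CRBT, HHR, the PHR variance subclasses AAvar/ABvar/BBvar, and Other)
broken down by the three selection routes (ALL_HOM, HIGH_MOD_EFF, INFP),
plus the sizes of the zero-Mendelian-error component sets behind the
"robust NMH + OTV" panel and the MAF distribution of the tiled SNPs.

These printed counts are inputs; the totals, percentages and conversion
rates derived from them are computed here, never stored.
"""

from __future__ import annotations

import pandas as pd

QUALITY_CLASSES = ("AAvar", "ABvar", "BBvar", "HHR", "CRBT", "MHR", "NMH", "Other", "OTV", "PHR")

#: variants per selection route x genotyping quality class
CLASS_COUNTS = pd.DataFrame(
    {
        "AAvar": {"ALL_HOM": 69, "HIGH_MOD_EFF": 385, "INFP": 5066},
        "ABvar": {"ALL_HOM": 158, "HIGH_MOD_EFF": 423, "INFP": 7159},
        "BBvar": {"ALL_HOM": 182, "HIGH_MOD_EFF": 388, "INFP": 5413},
        "HHR": {"ALL_HOM": 1, "HIGH_MOD_EFF": 4, "INFP": 102},
        "CRBT": {"ALL_HOM": 250, "HIGH_MOD_EFF": 1432, "INFP": 24764},
        "MHR": {"ALL_HOM": 334, "HIGH_MOD_EFF": 1647, "INFP": 25718},
        "NMH": {"ALL_HOM": 2216, "HIGH_MOD_EFF": 9401, "INFP": 73117},
        "Other": {"ALL_HOM": 2820, "HIGH_MOD_EFF": 3986, "INFP": 91597},
        "OTV": {"ALL_HOM": 1772, "HIGH_MOD_EFF": 923, "INFP": 10802},
        "PHR": {"ALL_HOM": 3040, "HIGH_MOD_EFF": 47691, "INFP": 288798},
    },
    dtype=int,
)[list(QUALITY_CLASSES)]

#: zero-Mendelian-error counts behind the robust NMH + OTV set
ROBUST_NMH_OTV_COMPONENTS = {
    "NMH": 45_344,
    "OTV": 152,
    "AAvar": 1_380,
    "ABvar": 2_192,
    "BBvar": 906,
}

#: tiled-SNP counts per minor-allele-frequency bin
MAF_BIN_COUNTS = {
    "0.05-0.09": 160_473,
    "0.10-0.19": 156_359,
    "0.20-0.29": 106_164,
    "0.30-0.39": 101_743,
    "0.40-0.50": 84_919,
}


def class_totals() -> pd.Series:
    """Variants per quality class, summed over selection routes."""
    return CLASS_COUNTS.sum(axis=0)


def selection_totals() -> pd.Series:
    """Variants per selection route, summed over quality classes."""
    return CLASS_COUNTS.sum(axis=1)


def array_total() -> int:
    """Total variants tiled on the array."""
    return int(CLASS_COUNTS.to_numpy().sum())


def class_percentages() -> pd.Series:
    """Percent of tiled variants per quality class."""
    return 100.0 * class_totals() / array_total()


def conversion_rate(selection: str, quality_class: str = "PHR") -> float:
    """Percent of a selection route's variants landing in a quality class."""
    return 100.0 * CLASS_COUNTS.at[selection, quality_class] / CLASS_COUNTS.loc[selection].sum()


def robust_nmh_otv_total() -> int:
    """Size of the robust NMH + OTV set (sum of its component classes)."""
    return sum(ROBUST_NMH_OTV_COMPONENTS.values())


def maf_bins_total() -> int:
    return sum(MAF_BIN_COUNTS.values())
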