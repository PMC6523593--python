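"""Readers and writers: VCF 4.x, annotation/pedigree/pair TSVs, run config.

Genotypes travel as VCF (INFO: DP, DP4, MQ, AC, AN; per-sample GT); the
array-design annotations that have no standard VCF home (effect class,
flanking-variant flags, 16-mer count, probe conversion scores, seeded
truth labels) travel as a site-keyed TSV. Positions are 1-based
throughout; a missing GT becomes the missing dosage code.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING, GenotypeMatrix

_VCF_INFO_HEADER = """\
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=DP4,Number=4,Type=Integer,Description="high-quality ref-forward, ref-reverse, alt-forward and alt-reverse bases">
##INFO=<ID=MQ,Number=1,Type=Integer,Description="Average mapping quality">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count in genotypes">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total number of alleles in called genotypes">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

#: columns that live in the annotation TSV rather than the VCF
ANNOTATION_COLUMNS = [
    "effect_class",
    "flank_variant_left",
    "flank_variant_right",
    "sixteen_mer_count",
    "p_convert_fwd",
    "p_convert_rev",
    "is_indel",
    "n_alleles",
]


def write_vcf(gm: GenotypeMatrix, path: str | Path, annotations: pd.DataFrame | None = None) -> None:
    """Write a multi-sample VCF 4.2 with DP/DP4/MQ/AC/AN INFO and GT calls.

    INFO fields are taken from ``annotations`` (site-ordered like ``gm``)
    when provided, else omitted. Scaffold contig lines are emitted for
    every scaffold present.
    """
    sites = gm.sites
    ann = annotations.set_index("site_id") if annotations is not None else None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=walnutsnp\n")
        for scaf in pd.unique(sites["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, row in sites.iterrows():
            if ann is not None and row["site_id"] in ann.index:
                a = ann.loc[row["site_id"]]
                qual = f"{float(a['QUAL']):g}" if "QUAL" in a else "."
                info = (
                    f"DP={int(a['DP'])};"
                    f"DP4={int(a['DP4_ref_fwd'])},{int(a['DP4_ref_rev'])},"
                    f"{int(a['DP4_alt_fwd'])},{int(a['DP4_alt_rev'])};"
                    f"MQ={int(round(float(a['MQ'])))};AC={int(a['AC'])};AN={int(a['AN'])}"
                )
            else:
                qual, info = ".", "."
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.geno[:, j])
            fh.write(
                f"{row['scaffold']}\t{row['pos']}\t{row['site_id']}\t{row['ref']}\t"
                f"{row['alt']}\t{qual}\t.\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a VCF into a site table and a dosage genotype matrix.

    The site table carries any of QUAL/MQ/DP/DP4/AC/AN found, plus
    ``n_alleles`` (1 + number of ALT alleles) and ``is_indel`` derived from
    the alleles, so multiallelic and indel records reach the
    array-candidate filter. Missing or half-missing GT calls map to the
    missing dosage code. A parse failure raises with the record number.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    geno_cols = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for n, rec in enumerate(vcf, start=1):
        try:
            alts = rec.ALT or []
            info = dict(rec.INFO)
            dp4 = info.get("DP4")
            rows.append(
                {
                    "site_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                    "scaffold": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alts[0] if alts else ".",
                    "n_alleles": 1 + len(alts),
                    "is_indel": rec.is_indel,
                    "QUAL": rec.QUAL,
                    "MQ": info.get("MQ"),
                    "DP": info.get("DP"),
                    "DP4_ref_fwd": dp4[0] if dp4 is not None else None,
                    "DP4_ref_rev": dp4[1] if dp4 is not None else None,
                    "DP4_alt_fwd": dp4[2] if dp4 is not None else None,
                    "DP4_alt_rev": dp4[3] if dp4 is not None else None,
                    "AC": info.get("AC"),
                    "AN": info.get("AN"),
                }
            )
            geno_cols.append(remap[rec.gt_types])
        except Exception as exc:  # pragma: no cover - depends on malformed input
            raise ValueError(f"malformed VCF record #{n} in {path}: {exc}") from exc
    sites = pd.DataFrame(rows)
    geno = (
        np.column_stack(geno_cols).astype(np.int8)
        if geno_cols
        else np.empty((len(samples), 0), np.int8)
    )
    return sites, GenotypeMatrix(samples, sites[["site_id", "scaffold", "pos", "ref", "alt"]], geno)


# -- TSV helpers -------------------------------------------------------------

def write_annotations(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pedigree(records: pd.DataFrame, path: str | Path) -> None:
    records[["id", "dam", "sire"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    if list(df.columns[:3]) != ["id", "dam", "sire"]:
        raise ValueError(f"pedigree file {path} must have columns id, dam, sire")
    return df


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- run configuration -------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """YAML/JSON run configuration as a plain dict (YAML is a JSON superset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
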