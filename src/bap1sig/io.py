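"""Readers and writers for the pipeline's file dialects.

All tabular formats are TSV; coordinates are 1-based inclusive (MAF/SEG
convention).  The MAF dialect uses the standard column names
(Tumor_Sample_Barcode, Chromosome, Start_Position, Reference_Allele,
Tumor_Seq_Allele2, Variant_Classification, t_depth, t_alt_count, FILTER)
plus a ``caller``/``callers`` provenance column; extra columns are
tolerated and preserved.
"""

from __future__ import annotations

import logging

import pandas as pd

from bap1sig._exceptions import InputError
from bap1sig.signatures import GeneSet

log = logging.getLogger(__name__)

#: internal name -> MAF column
MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "classification": "Variant_Classification",
    "t_depth": "t_depth",
    "t_alt_count": "t_alt_count",
    "filter": "FILTER",
}
_MAF_OPTIONAL = {"tumor_type": "tumor_type", "caller": "caller", "callers": "callers",
                 "gene": "Hugo_Symbol"}


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-dialect TSV into the internal variant-call schema.

    Column order is free and extra columns are carried through unchanged;
    a missing required column raises an ``InputError`` naming it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, comment="#")
    rename = {}
    for internal, maf in MAF_COLUMNS.items():
        if maf not in df.columns:
            raise InputError(f"MAF file {path} missing required column {maf!r}")
        rename[maf] = internal
    for internal, maf in _MAF_OPTIONAL.items():
        if maf in df.columns:
            rename[maf] = internal
    df = df.rename(columns=rename)
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] <= 0).any():
        raise InputError("MAF positions must be positive (1-based)")
    if (df["t_alt_count"] > df["t_depth"]).any():
        raise InputError("t_alt_count exceeds t_depth")
    return df


def write_maf(df: pd.DataFrame, path) -> None:
    inv = {v: k for k, v in {**MAF_COLUMNS, **_MAF_OPTIONAL}.items()}
    out = df.rename(columns={internal: maf for maf, internal in inv.items()})
    out.to_csv(path, sep="\t", index=False)


def read_gene_cn(path) -> pd.DataFrame:
    """Gene-level copy-number TSV: sample_id, gene, copy_number."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene", "copy_number"):
        if col not in df.columns:
            raise InputError(f"gene-CN file {path} missing column {col!r}")
    return df


def read_segments(path) -> pd.DataFrame:
    """SEG-dialect TSV: sample_id, chrom, start, end, copy_number
    (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("sample_id", "chrom", "start", "end", "copy_number"):
        if col not in df.columns:
            raise InputError(f"segment file {path} missing column {col!r}")
    if (df["start"] > df["end"]).any():
        raise InputError("segment with start > end")
    return df


def read_counts(path) -> pd.DataFrame:
    """Gene-by-sample counts TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise InputError("negative counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "PFI.time", "PFI"):
        if col not in df.columns:
            raise InputError(f"clinical file {path} missing column {col!r}")
    return df


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gmt(path) -> list[GeneSet]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a line are dropped with a warning; a line with
    fewer than three fields raises an ``InputError`` with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has {len(fields)} "
                                 "fields (need >= 3)")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                log.warning("%s:%d: %d duplicate genes dropped in set %s",
                            path, lineno, len(genes) - len(uniq), name)
            sets.append(GeneSet(name=name, genes=uniq))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


def read_signature(path) -> tuple[list[str], list[str]]:
    """Two-column signature TSV (gene, sign in {+1,-1}) -> (up, down)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "sign"} <= set(df.columns):
        raise InputError(f"signature file {path} needs columns gene, sign")
    up = df.loc[df["sign"] > 0, "gene"].tolist()
    down = df.loc[df["sign"] < 0, "gene"].tolist()
    return up, down


def write_signature(up: list[str], down: list[str], path) -> None:
    pd.DataFrame({"gene": list(up) + list(down),
                  "sign": [1] * len(up) + [-1] * len(down)}
                 ).to_csv(path, sep="\t", index=False)
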