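"""BAP1 alteration-state classification from copy number and mutations.

Combines a gene-level copy-number loss call (CN < 2) with the harmonized
mutant-sample set into the four-way label
{Unaltered, MutOnly, CNOnly, CN+Mut}, and summarizes the genomic extent
of copy-number loss from masked segment tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from bap1sig._exceptions import InputError

log = logging.getLogger(__name__)

LABELS = ("Unaltered", "MutOnly", "CNOnly", "CN+Mut")


def call_cn_loss(gene_cn: pd.DataFrame, gene: str = "BAP1") -> pd.Series:
    """Per-sample loss flag: gene-level copy number below two.

    ``gene_cn`` has columns (sample_id, gene, copy_number).  Samples with
    missing copy number are excluded from the result (logged); negative
    copy numbers are an input error.
    """
    sub = gene_cn[gene_cn["gene"] == gene]
    if (sub["copy_number"].dropna() < 0).any():
        raise InputError("negative gene-level copy number")
    missing = sub[sub["copy_number"].isna()]["sample_id"]
    if len(missing):
        log.info("excluding %d samples with missing %s copy number", len(missing), gene)
    sub = sub.dropna(subset=["copy_number"])
    flags = pd.Series((sub["copy_number"] < 2).to_numpy(),
                      index=pd.Index(sub["sample_id"], name="sample_id"),
                      name="cn_loss")
    return flags


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge closed intervals that overlap (1-based inclusive)."""
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def segment_width_stats(segments: pd.DataFrame,
                        locus: tuple[str, int, int],
                        loss_flags: pd.Series,
                        sample_types: pd.Series) -> dict:
    """Loss-segment widths around a locus, per sample and per tumor type.

    For each sample flagged as gene-level loss, loss segments
    (copy_number < 2) overlapping the closed locus interval are merged and
    their widths summed to one width per sample.  Returns per-sample
    widths, per-type median/IQR, and the list of discordant samples
    (gene-level loss but no overlapping loss segment).
    """
    chrom, lstart, lend = locus
    loss_samples = loss_flags.index[loss_flags.astype(bool)]
    seg = segments[(segments["chrom"] == chrom)
                   & (segments["copy_number"] < 2)
                   & (segments["start"] <= lend)
                   & (segments["end"] >= lstart)]
    widths, discordant = [], []
    by_sample = dict(tuple(seg.groupby("sample_id")))
    for s in loss_samples:
        if s not in by_sample:
            discordant.append(s)
            continue
        merged = _merge_intervals(list(zip(by_sample[s]["start"], by_sample[s]["end"])))
        width = sum(e - st + 1 for st, e in merged)
        widths.append((s, sample_types.loc[s], width))
    per_sample = pd.DataFrame(widths, columns=["sample_id", "tumor_type", "width"])
    if len(per_sample):
        per_type = per_sample.groupby("tumor_type")["width"].agg(
            n="size", median="median",
            q1=lambda x: x.quantile(0.25), q3=lambda x: x.quantile(0.75))
    else:
        per_type = pd.DataFrame(columns=["n", "median", "q1", "q3"])
    if discordant:
        log.warning("%d samples with gene-level loss but no overlapping loss segment",
                    len(discordant))
    return dict(per_sample=per_sample, per_type=per_type, discordant=sorted(discordant))


def classify_alteration(loss_flags: pd.Series,
                        mutant_samples,
                        cohort: pd.DataFrame) -> pd.DataFrame:
    """Four-way alteration label for every cohort sample.

    ``loss_flags`` is the :func:`call_cn_loss` output, ``mutant_samples``
    the set of sample_ids with retained mutations, and ``cohort`` the
    sample metadata (index sample_id, with a tumor_type column).  Mutant
    samples absent from the CN table are labelled MutOnly with a warning.
    The labels partition the cohort; row order of the inputs is irrelevant.
    """
    mutant_samples = set(mutant_samples)
    no_cn = mutant_samples - set(loss_flags.index)
    if no_cn & set(cohort.index):
        log.warning("%d mutant samples missing from CN table; labelled MutOnly",
                    len(no_cn & set(cohort.index)))
    rows = []
    for s in cohort.index:
        loss = bool(loss_flags.get(s, False))
        mut = s in mutant_samples
        label = ("CN+Mut" if loss and mut else "CNOnly" if loss
                 else "MutOnly" if mut else "Unaltered")
        rows.append((s, cohort.loc[s, "tumor_type"], label, loss, mut))
    out = pd.DataFrame(rows, columns=["sample_id", "tumor_type", "label",
                                      "cn_loss", "mutant"]).set_index("sample_id")
    out["altered"] = out["label"] != "Unaltered"
    return out


def alteration_summary(status: pd.DataFrame) -> pd.DataFrame:
    """Per-type and overall label counts (rows partition the cohort)."""
    tab = (status.groupby(["tumor_type", "label"]).size().unstack(fill_value=0)
           .reindex(columns=LABELS, fill_value=0))
    tab["n_altered"] = tab[["MutOnly", "CNOnly", "CN+Mut"]].sum(axis=1)
    tab["n_total"] = tab[list(LABELS)].sum(axis=1)
    tab["pct_altered"] = 100 * tab["n_altered"] / tab["n_total"]
    return tab
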