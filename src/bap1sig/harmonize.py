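"""Multi-caller somatic variant harmonization and filtering.

Merges per-caller MAF-dialect call tables into one deduplicated call set
(after allele normalization), applies quality / consequence / expression
filters, summarizes the retained calls, and compares against a legacy
callset for concordance.

Coordinates are 1-based inclusive throughout (MAF convention); deleted or
inserted alleles may be written ``"-"`` (MAF style) or carried on a padded
anchor base (VCF style) — both normalize to the same key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bap1sig._exceptions import ConfigError, InputError

log = logging.getLogger(__name__)

#: Consequence severity for resolving classification conflicts between
#: callers (lower = more deleterious).  Conservative, documented ordering:
#: nonsense > frameshift > splice > in-frame > missense > everything else.
SEVERITY = {
    "Nonsense_Mutation": 0,
    "Frame_Shift_Del": 1,
    "Frame_Shift_Ins": 1,
    "Splice_Site": 2,
    "In_Frame_Del": 3,
    "In_Frame_Ins": 3,
    "Missense_Mutation": 4,
}
_SEVERITY_DEFAULT = 9

#: Non-synonymous / non-intronic rule: classifications dropped by default.
NONCODING_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"})

DELETERIOUS_CLASSES = frozenset(
    {"Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site"})

KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


def normalize_allele(pos: int, ref: str, alt: str,
                     context: str | None = None,
                     context_start: int | None = None) -> tuple[int, str, str]:
    """Canonical (pos, ref, alt) for one variant.

    Trims the shared prefix (advancing ``pos``), then the shared suffix,
    treating ``"-"`` as the empty allele; prefix-first trimming collapses
    a VCF-style anchor-padded indel onto its minimal MAF representation.
    If a reference ``context`` string (1-based start ``context_start``)
    is supplied, pure indels are additionally left-aligned within it.
    Empty alleles are returned as ``"-"``.
    """
    r = "" if ref in ("-", "", None) else str(ref)
    a = "" if alt in ("-", "", None) else str(alt)
    # shared prefix
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    # shared suffix
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    if context is not None and context_start is not None and (not r or not a):
        seq = r or a  # deleted (r) or inserted (a) bases
        while seq and pos > context_start:
            left = context[pos - 1 - context_start]
            if left != seq[-1]:
                break
            seq = left + seq[:-1]
            pos -= 1
        if r:
            r = seq
        else:
            a = seq
    return pos, (r or "-"), (a or "-")


def indel_length(ref: str, alt: str) -> int:
    """max(len(ref), len(alt)) - 1 for indels; 0 for SNVs/MNVs of equal length."""
    r = "" if ref == "-" else str(ref)
    a = "" if alt == "-" else str(alt)
    if len(r) == len(a):
        return 0
    return max(len(r), len(a)) - 1


def _severity(classification: str) -> int:
    return SEVERITY.get(classification, _SEVERITY_DEFAULT)


def merge_callsets(callsets: list[pd.DataFrame],
                   context: str | None = None,
                   context_start: int | None = None) -> pd.DataFrame:
    """Union of caller tables collapsed on (sample, chrom, pos, ref, alt).

    Alleles are normalized before keying.  Collapsed records take their
    numeric fields (t_depth, t_alt_count) from the caller with the highest
    t_depth; ``callers`` is the comma-joined sorted union.  Conflicting
    classifications on one key keep the most deleterious (with a warning).
    Output is sorted by key, so the merge is input-order invariant and
    idempotent.
    """
    frames = [df for df in callsets if df is not None and len(df)]
    if not frames:
        cols = ["sample_id", "tumor_type", "chrom", "pos", "ref", "alt",
                "classification", "t_depth", "t_alt_count", "filter",
                "callers", "vaf", "indel_length"]
        return pd.DataFrame(columns=cols)
    df = pd.concat(frames, ignore_index=True).copy()
    if "callers" not in df.columns:
        df["callers"] = df["caller"]
    norm = [normalize_allele(p, r, a, context, context_start)
            for p, r, a in zip(df["pos"], df["ref"], df["alt"])]
    df[["pos", "ref", "alt"]] = pd.DataFrame(norm, index=df.index)

    out = []
    for key, grp in df.groupby(KEY, sort=True):
        best = grp.loc[grp["t_depth"].idxmax()]
        classes = set(grp["classification"])
        if len(classes) > 1:
            log.warning("conflicting classifications %s at %s; keeping most deleterious",
                        sorted(classes), key)
        classification = min(classes, key=lambda c: (_severity(c), c))
        callers = sorted(set(",".join(grp["callers"]).split(",")))
        rec = best.to_dict()
        rec["classification"] = classification
        rec["callers"] = ",".join(callers)
        # PASS only if every caller agreed the call passes its filters
        flags = set(grp["filter"])
        rec["filter"] = "PASS" if flags == {"PASS"} else ";".join(sorted(flags - {"PASS"}))
        out.append(rec)
    res = pd.DataFrame(out).drop(columns=["caller"], errors="ignore")
    res["vaf"] = res["t_alt_count"] / res["t_depth"]
    res["indel_length"] = [indel_length(r, a) for r, a in zip(res["ref"], res["alt"])]
    return res.reset_index(drop=True)


def apply_quality_filters(variants: pd.DataFrame,
                          vaf_min: float = 0.2,
                          alt_min: int = 2,
                          require_pass: bool = True,
                          drop_classes: frozenset = NONCODING_CLASSES,
                          ) -> tuple[pd.DataFrame, dict]:
    """Retain PASS, VAF >= vaf_min, t_alt_count >= alt_min, coding calls.

    All thresholds are inclusive.  Returns the retained table and a dict
    of per-filter drop counts (a record failing several filters is counted
    under each).
    """
    if not 0 <= vaf_min <= 1:
        raise ConfigError(f"vaf_min {vaf_min} outside [0, 1]")
    if len(variants) == 0:
        return variants.copy(), {"filter_flag": 0, "vaf": 0, "alt_count": 0,
                                 "classification": 0}
    vaf = variants["t_alt_count"] / variants["t_depth"]
    fail_flag = (variants["filter"] != "PASS") if require_pass else pd.Series(False, index=variants.index)
    fail_vaf = vaf < vaf_min
    fail_alt = variants["t_alt_count"] < alt_min
    fail_class = variants["classification"].isin(drop_classes)
    drops = {"filter_flag": int(fail_flag.sum()), "vaf": int(fail_vaf.sum()),
             "alt_count": int(fail_alt.sum()), "classification": int(fail_class.sum())}
    keep = ~(fail_flag | fail_vaf | fail_alt | fail_class)
    log.info("quality filters: %d/%d retained (drops %s)", keep.sum(), len(keep), drops)
    return variants[keep].reset_index(drop=True), drops


def apply_expression_filter(variants: pd.DataFrame,
                            expr: pd.DataFrame,
                            sample_types: pd.Series,
                            gene: str = "BAP1",
                            quantile_cut: float = 0.5,
                            min_samples: int = 5,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep variants whose sample has low within-tumor-type target-gene
    expression (at or below the ``quantile_cut`` quantile).

    ``expr`` is a normalized gene-by-sample matrix; ``sample_types`` maps
    sample_id -> tumor type for all expression samples.  Mutant samples
    missing from ``expr`` are dropped (logged); tumor types with fewer
    than ``min_samples`` expressed samples skip the filter with a warning.

    Returns (retained variants, review table).  The review table — one
    row per candidate mutant sample with its expression, within-type rank
    and retention decision — stands in for manual read-level review.
    """
    if gene not in expr.index:
        raise InputError(f"gene {gene!r} absent from expression matrix")
    gexpr = expr.loc[gene]
    review_rows, keep_samples, drop_absent = [], set(), set()
    for sample in pd.unique(variants["sample_id"]):
        if sample not in gexpr.index:
            drop_absent.add(sample)
            continue
        ttype = sample_types.loc[sample]
        cohort = gexpr[sample_types.reindex(gexpr.index) == ttype]
        n = len(cohort)
        if n < min_samples:
            log.warning("tumor type %s has %d < %d expressed samples; "
                        "expression filter skipped", ttype, n, min_samples)
            retained = True
            cut = np.nan
        else:
            cut = cohort.quantile(quantile_cut)
            retained = gexpr.loc[sample] <= cut
        rank = int((cohort <= gexpr.loc[sample]).sum())
        review_rows.append((sample, ttype, float(gexpr.loc[sample]), rank, n,
                            float(cut) if cut == cut else np.nan, bool(retained)))
        if retained:
            keep_samples.add(sample)
    if drop_absent:
        log.info("dropped %d mutant samples with no RNA data: %s",
                 len(drop_absent), sorted(drop_absent))
    review = pd.DataFrame(review_rows, columns=["sample_id", "tumor_type",
                                                "expression", "rank", "n_type",
                                                "cutoff", "retained"])
    kept = variants[variants["sample_id"].isin(keep_samples)].reset_index(drop=True)
    return kept, review


def summarize_variants(variants: pd.DataFrame,
                       cohort_meta: pd.DataFrame | None = None,
                       long_indel_min: int = 40) -> dict:
    """Per-classification and per-type summaries of a filtered call set.

    Returns a dict with ``by_class`` (count + fraction, including the
    deleterious nonsense/frameshift/splice fraction), ``by_type`` (mutant
    sample counts, and frequencies when ``cohort_meta`` with per-type
    totals is given), ``n_variants``, ``n_samples`` and ``n_long_indels``.
    """
    n = len(variants)
    if n == 0:
        return dict(by_class=pd.DataFrame(columns=["count", "fraction"]),
                    by_type=pd.DataFrame(columns=["n_mutant_samples", "frequency"]),
                    n_variants=0, n_samples=0, n_long_indels=0,
                    deleterious_fraction=0.0)
    by_class = variants["classification"].value_counts().to_frame("count")
    by_class["fraction"] = by_class["count"] / n
    if "indel_length" in variants.columns:
        lengths = variants["indel_length"]
    else:
        lengths = pd.Series([indel_length(r, a) for r, a in
                             zip(variants["ref"], variants["alt"])], index=variants.index)
    n_long = int((lengths >= long_indel_min).sum())
    mutants = variants.groupby("tumor_type")["sample_id"].nunique().to_frame("n_mutant_samples")
    if cohort_meta is not None:
        totals = cohort_meta.groupby("tumor_type").size()
        mutants["frequency"] = mutants["n_mutant_samples"] / totals.reindex(mutants.index)
    deleterious = float(variants["classification"].isin(DELETERIOUS_CLASSES).mean())
    return dict(by_class=by_class, by_type=mutants, n_variants=n,
                n_samples=int(variants["sample_id"].nunique()),
                n_long_indels=n_long, deleterious_fraction=deleterious)


@dataclass
class ConcordanceReport:
    """Partition of the union of two call sets plus near-miss pairs."""

    n_new_only: int
    n_concordant: int
    n_legacy_only: int
    assignment: pd.DataFrame    # one row per union variant with its class
    near_miss: pd.DataFrame     # same-sample pairs within the position window

    @property
    def new_fraction(self) -> float:
        total_new = self.n_new_only + self.n_concordant
        return self.n_new_only / total_new if total_new else float("nan")


def compare_callsets(new: pd.DataFrame, legacy: pd.DataFrame,
                     window: int = 10) -> ConcordanceReport:
    """Classify the union of two (identically filtered) call sets into
    new-only / concordant / legacy-only on the normalized variant key.

    Pairs of non-concordant calls from the same sample and chromosome with
    positions within ``window`` bp are listed as near-misses (likely one
    variant represented differently across pipelines); they stay in their
    new-only / legacy-only classes.
    """
    def keys(df):
        if len(df) == 0:
            return set()
        return set(map(tuple, df[KEY].itertuples(index=False, name=None)))

    knew, kleg = keys(new), keys(legacy)
    concordant = knew & kleg
    new_only, legacy_only = knew - kleg, kleg - knew
    rows = ([(*k, "concordant") for k in concordant]
            + [(*k, "new_only") for k in new_only]
            + [(*k, "legacy_only") for k in legacy_only])
    assignment = pd.DataFrame(sorted(rows), columns=KEY + ["class"])
    nm = []
    for kn in new_only:
        for kl in legacy_only:
            if kn[0] == kl[0] and kn[1] == kl[1] and abs(kn[2] - kl[2]) <= window:
                nm.append((kn[0], kn[1], kn[2], kl[2], abs(kn[2] - kl[2])))
    near_miss = pd.DataFrame(nm, columns=["sample_id", "chrom", "new_pos",
                                          "legacy_pos", "distance"])
    return ConcordanceReport(len(new_only), len(concordant), len(legacy_only),
                             assignment, near_miss)
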