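"""Harmonize the caller-specific variant tables and apply the filters.

Merges the two callers' MAFs (collapsing padded/minimal indel
representations), applies the quality filters (FILTER==PASS, VAF >= 0.2,
t_alt_count >= 2, non-synonymous/non-intronic) and the within-type
low-expression filter, then measures recovery against the planted truth
and concordance against the legacy callset.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import RESULTS, require_cohort

from bap1sig import diffexp, harmonize
from bap1sig import io as bio


def main():
    cohort = require_cohort()
    meta = bio.read_table(cohort / "meta.tsv").set_index("sample_id", drop=False)
    truth = bio.read_table(cohort / "truth_labels.tsv").set_index("sample_id")["label"]
    callsets = [bio.read_maf(p) for p in sorted(cohort.glob("calls_caller*.maf"))]

    merged = harmonize.merge_callsets(callsets)
    filtered, drops = harmonize.apply_quality_filters(merged)
    counts = bio.read_counts(cohort / "counts.tsv")
    norm = diffexp.normalized_log2(counts)
    kept, review = harmonize.apply_expression_filter(filtered, norm,
                                                     meta["tumor_type"])
    funnel = pd.DataFrame([
        ("merged", len(merged)), ("after_quality", len(filtered)),
        ("after_expression", len(kept))], columns=["stage", "n_variants"])
    funnel.to_csv(RESULTS / "02_filter_funnel.tsv", sep="\t", index=False)
    kept.to_csv(RESULTS / "02_variants_filtered.tsv", sep="\t", index=False)

    called = set(kept["sample_id"])
    true_mut = set(truth.index[truth.isin(["MutOnly", "CN+Mut"])])
    sens = len(called & true_mut) / len(true_mut)
    n_neg = len(meta) - len(true_mut)
    spec = (n_neg - len(called - true_mut)) / n_neg
    print(f"funnel: {len(merged)} merged -> {len(filtered)} quality "
          f"-> {len(kept)} expression-filtered (drops {drops})")
    print(f"recovery vs truth: sensitivity {sens:.3f}, specificity {spec:.3f}")

    summ = harmonize.summarize_variants(kept, meta)
    print(f"deleterious fraction {summ['deleterious_fraction']:.2f}, "
          f"{summ['n_long_indels']} indels >= 40bp")

    legacy = bio.read_maf(cohort / "calls_legacy.maf")
    lfilt, _ = harmonize.apply_quality_filters(harmonize.merge_callsets([legacy]))
    rep = harmonize.compare_callsets(kept, lfilt)
    rep.assignment.to_csv(RESULTS / "02_concordance.tsv", sep="\t", index=False)
    print(f"vs legacy callset: {rep.n_new_only} new, {rep.n_concordant} "
          f"concordant, {rep.n_legacy_only} legacy-only "
          f"({100 * rep.new_fraction:.0f}% of current calls are new)")


if __name__ == "__main__":
    main()
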