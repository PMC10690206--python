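"""Alteration and mutation signature scores.

Scores every sample on its own tumor type's DE-derived up/down signature
(z scale), checks how cleanly truly altered samples separate, correlates
the TT1-derived reference signature with TT2's native signature
(cross-cohort transfer), and fits the Gaussian-mixture positive/negative
classification to the mutation-vs-CN signature on pooled altered samples.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import RESULTS, SEED, require_cohort

from bap1sig import diffexp as de
from bap1sig import io as bio
from bap1sig import signatures as sig


def main():
    cohort = require_cohort()
    meta = bio.read_table(cohort / "meta.tsv").set_index("sample_id", drop=False)
    truth = bio.read_table(cohort / "truth_labels.tsv").set_index("sample_id")["label"]
    counts = bio.read_counts(cohort / "counts.tsv")
    status = bio.read_table(RESULTS / "03_alteration_status.tsv"
                            ).set_index("sample_id")
    norm = de.normalized_log2(counts)

    types = sorted(meta["tumor_type"].unique())
    sigs = {t: bio.read_signature(RESULTS / f"04_signature_{t}.tsv")
            for t in types}
    all_scores = []
    for t in types:
        cols = meta.index[meta["tumor_type"] == t]
        up, down = sigs[t]
        sc = sig.alteration_signature_score(norm[cols], up, down, t)
        sc["altered"] = status.loc[sc.index, "altered"].to_numpy()
        all_scores.append(sc)
        pos = (sc.loc[sc["altered"], "score"] > 0).mean()
        print(f"{t}: {100 * pos:.0f}% of altered samples score positive "
              f"({int(sc['altered'].sum())} altered)")
    scores = pd.concat(all_scores)
    scores.reset_index().to_csv(RESULTS / "05_alteration_scores.tsv",
                                sep="\t", index=False)

    ref = sigs[types[0]]
    exprs = {t: norm[meta.index[meta["tumor_type"] == t]] for t in types[1:]}
    corr = sig.cross_signature_correlation(exprs, ref,
                                           {t: sigs[t] for t in types[1:]})
    corr.to_csv(RESULTS / "05_cross_cohort_correlation.tsv", sep="\t")
    print(f"{types[0]}-derived vs native signature Spearman rho:")
    print(corr.round(3).to_string())

    # mutation signature: mutant (MutOnly/CN+Mut) vs CN-only contrast on the
    # altered-only subset, scored on the raw-sum scale and split by mixture
    altered = status[status["altered"]]
    mutant = altered["mutant"]
    anno = bio.read_table(cohort / "gene_anno.tsv")
    design = de.build_design(meta.loc[altered.index], mutant, ["tumor_type"])
    res = de.fit_nb_wald(counts[altered.index], design)
    res = de.adjust_and_select(res, anno)
    up, down = de.significant_genes(res)
    if up or down:
        pieces = []
        for t in types:
            cols = altered.index[altered["tumor_type"] == t]
            pieces.append(sig.mutation_signature_classify(
                norm[cols], up, down, cohort=t, seed=SEED, cutoff=np.inf))
        pooled = pd.concat(pieces)
        cutoff, info = sig.fit_score_mixture(pooled["score"], seed=SEED)
        pooled["cutoff"] = cutoff
        pooled["class"] = np.where(pooled["score"] >= cutoff, "positive", "negative")
        pooled["mutant"] = mutant.loc[pooled.index].to_numpy()
        pooled.reset_index().to_csv(RESULTS / "05_mutation_scores.tsv",
                                    sep="\t", index=False)
        enrich = pooled.groupby("class")["mutant"].mean()
        print(f"mutation signature: {len(up)} up / {len(down)} down genes, "
              f"mixture cutoff {cutoff:.1f} (raw-sum scale)")
        print("fraction mutant by class:", enrich.round(2).to_dict())
    else:
        print("mutation signature: no significant mutant-vs-CN genes at this size")


if __name__ == "__main__":
    main()
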