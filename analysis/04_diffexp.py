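"""Differential expression between altered and unaltered samples.

Per tumor type: purity-adjusted NB Wald tests with size-factor offsets,
chr3p masking (all non-BAP1 3p genes removed before adjustment, since
arm-level co-loss confounds them) and BH correction.  Writes the
significant-gene signature files used by later steps and a per-type
summary; full DE tables go to scratch.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import COHORT_DIR, RESULTS, require_cohort

from bap1sig import diffexp as de
from bap1sig import io as bio


def main():
    cohort = require_cohort()
    meta = bio.read_table(cohort / "meta.tsv").set_index("sample_id", drop=False)
    counts = bio.read_counts(cohort / "counts.tsv")
    anno = bio.read_table(cohort / "gene_anno.tsv")
    status = bio.read_table(RESULTS / "03_alteration_status.tsv"
                            ).set_index("sample_id")

    factors = de.size_factors(counts)
    rows = []
    for ttype in sorted(meta["tumor_type"].unique()):
        cols = meta.index[meta["tumor_type"] == ttype]
        design = de.build_design(meta.loc[cols], status.loc[cols, "altered"],
                                 ["purity"])
        res = de.fit_nb_wald(counts[cols], design, factors=factors.loc[cols])
        res = de.adjust_and_select(res, anno)
        res.reset_index(drop=True).to_csv(COHORT_DIR / f"de_{ttype}.tsv",
                                          sep="\t", index=False)
        up, down = de.significant_genes(res)
        bio.write_signature(up, down, RESULTS / f"04_signature_{ttype}.tsv")
        rows.append((ttype, len(res), len(up), len(down)))
        print(f"{ttype}: {len(up)} up / {len(down)} down of {len(res)} tested "
              f"genes (padj<0.05 after chr3p mask)")
    pd.DataFrame(rows, columns=["tumor_type", "n_tested", "n_up", "n_down"]
                 ).to_csv(RESULTS / "04_de_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
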