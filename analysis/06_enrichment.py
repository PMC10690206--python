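"""Preranked GSEA per tumor type and the recurrent-pathway matrix.

Builds a gene-set collection (the planted up/down response signatures
plus random control sets), ranks genes by the DE Wald statistic, runs the
permutation GSEA in each tumor type, and assembles the cross-type NES
matrix of recurrently significant pathways with hierarchical cohort
ordering.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import COHORT_DIR, RESULTS, SEED, require_cohort

from bap1sig import enrichment as en
from bap1sig import io as bio
from bap1sig.signatures import GeneSet


def main():
    cohort = require_cohort()
    genes_truth = bio.read_table(cohort / "truth_genes.tsv").set_index("gene")
    up = genes_truth.index[genes_truth["direction"] == 1].tolist()
    down = genes_truth.index[genes_truth["direction"] == -1].tolist()
    rng = np.random.default_rng(SEED)
    sets = {"RESPONSE_UP": up, "RESPONSE_DOWN": down}
    for i in range(8):
        sets[f"RANDOM_{i}"] = list(rng.choice(genes_truth.index[1:], 25,
                                              replace=False))
    bio.write_gmt([GeneSet(k, v) for k, v in sets.items()],
                  RESULTS / "06_gene_sets.gmt")

    per_cohort = {}
    for de_path in sorted(COHORT_DIR.glob("de_TT*.tsv")):
        ttype = de_path.stem.split("_")[1]
        res = pd.read_csv(de_path, sep="\t").set_index("gene")
        ranks = res["stat"].dropna()
        tab = en.gsea_permutation(ranks, sets, n_perm=1000, seed=SEED)
        per_cohort[ttype] = tab
        tab.drop(columns="name").to_csv(RESULTS / f"06_gsea_{ttype}.tsv", sep="\t")
        print(f"{ttype}: RESPONSE_UP NES {tab.loc['RESPONSE_UP', 'nes']:.2f} "
              f"(padj {tab.loc['RESPONSE_UP', 'padj']:.2g}), RESPONSE_DOWN NES "
              f"{tab.loc['RESPONSE_DOWN', 'nes']:.2f} "
              f"(padj {tab.loc['RESPONSE_DOWN', 'padj']:.2g})")

    mat = en.recurrent_pathway_matrix(per_cohort, min_types=len(per_cohort))
    mat["nes"].to_csv(RESULTS / "06_recurrent_nes_matrix.tsv", sep="\t")
    print(f"pathways significant in every tumor type: {list(mat['nes'].index)}")
    print(f"cohort clustering order: {mat['cohort_order']}")


if __name__ == "__main__":
    main()
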