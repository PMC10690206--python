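"""Shared settings for the numbered analysis scripts.

The study cohort (2 tumor types x 200 samples, 2000 genes, default noise)
is written once by 01_simulate.py under scratch/cohort/ and re-read by
every later step; summary tables go under results/.
"""

from pathlib import Path

from bap1sig.synthetic import CohortConfig

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 17

STUDY_CONFIG = CohortConfig(seed=SEED)


def require_cohort() -> Path:
    if not (COHORT_DIR / "counts.tsv").exists():
        raise SystemExit("cohort not found - run analysis/01_simulate.py first")
    return COHORT_DIR
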