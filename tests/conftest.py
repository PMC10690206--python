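import numpy as np
import pandas as pd
import pytest

from bap1sig.synthetic import CohortConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 2 tumor types x 200 samples, default noise."""
    return simulate_all(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free variant at modest size: every call detected, no decoys."""
    cfg = CohortConfig(n_types=2, samples_per_type=80, n_genes=400,
                       n_signature_genes=60, p_detect=1.0, decoy_rate=0.0,
                       seed=13)
    return simulate_all(cfg)


@pytest.fixture
def toy_variants():
    """Hand-written merged variant table spanning every filter boundary."""
    rows = [
        # sample, chrom, pos, ref, alt, class, t_depth, t_alt, filter
        ("S1", "chr3", 100, "A", "T", "Missense_Mutation", 100, 19, "PASS"),   # VAF 0.19
        ("S2", "chr3", 200, "A", "T", "Missense_Mutation", 100, 20, "PASS"),   # VAF 0.20
        ("S3", "chr3", 300, "A", "T", "Nonsense_Mutation", 100, 50, "PASS"),
        ("S4", "chr3", 400, "A", "T", "Missense_Mutation", 100, 1, "PASS"),    # alt 1
        ("S5", "chr3", 500, "A", "T", "Missense_Mutation", 4, 2, "PASS"),      # alt 2
        ("S6", "chr3", 600, "A", "T", "Intron", 100, 50, "PASS"),
        ("S7", "chr3", 700, "A", "T", "Missense_Mutation", 100, 50, "LowEVS"),
        ("S8", "chr3", 800, "A" * 40, "-", "Frame_Shift_Del", 100, 50, "PASS"),  # len 39
        ("S9", "chr3", 900, "A" * 41, "-", "Frame_Shift_Del", 100, 50, "PASS"),  # len 40
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                                     "classification", "t_depth", "t_alt_count",
                                     "filter"])
    df["tumor_type"] = "TT1"
    df["callers"] = "callerA"
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
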