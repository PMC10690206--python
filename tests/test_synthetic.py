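"""Generator contracts: determinism, planted structure, and the NB /
segment-width / survival statistical assumptions downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest

from bap1sig import ConfigError
from bap1sig.synthetic import (BAP1, BAP1_END, BAP1_START, CohortConfig,
                               generate_cohort, mixture_median_width,
                               simulate_all, simulate_counts,
                               simulate_segments_and_cn, simulate_survival,
                               simulate_variant_calls)


def test_determinism_across_all_generators():
    a = simulate_all(CohortConfig(n_types=2, samples_per_type=40, n_genes=150,
                                  n_signature_genes=20, seed=5))
    b = simulate_all(CohortConfig(n_types=2, samples_per_type=40, n_genes=150,
                                  n_signature_genes=20, seed=5))
    for key in ("meta", "counts", "gene_cn", "segments", "clinical"):
        pd.testing.assert_frame_equal(a[key], b[key])
    for ta, tb in zip(a["callsets"], b["callsets"]):
        pd.testing.assert_frame_equal(ta, tb)
    pd.testing.assert_series_equal(a["truth"].labels, b["truth"].labels)


def test_cohort_layout_and_alteration_fractions():
    cfg = CohortConfig(n_types=2, samples_per_type=50, n_genes=100,
                       n_signature_genes=10,
                       alteration_fractions=(0.05, 0.30, 0.05), seed=1)
    meta, truth = generate_cohort(cfg)
    assert len(meta) == 100
    assert meta["tumor_type"].nunique() == 2
    assert meta["purity"].between(*cfg.purity_range).all()
    n_altered = (truth.labels != "Unaltered").sum()
    # expectation 40; allow ~3 binomial SDs
    assert 25 <= n_altered <= 55


def test_zero_fractions_give_all_unaltered():
    cfg = CohortConfig(n_types=1, samples_per_type=30, n_genes=50,
                       n_signature_genes=5, alteration_fractions=(0, 0, 0), seed=2)
    _, truth = generate_cohort(cfg)
    assert (truth.labels == "Unaltered").all()


@pytest.mark.parametrize("kwargs", [
    dict(alteration_fractions=(0.6, 0.5, 0.2)),          # sums > 1
    dict(n_signature_genes=100, n_genes=100),            # not < n_genes
    dict(purity_range=(0.5, 1.5)),
    dict(samples_per_type=0),
    dict(nb_dispersion=-0.1),
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        CohortConfig(**kwargs)


def test_counts_follow_nb_mean_variance_at_large_n():
    """Moment check: alpha_hat = (var - mean) / mean^2 recovers the
    configured dispersion at n=5000 samples."""
    cfg = CohortConfig(n_types=1, samples_per_type=5000, n_genes=20,
                       n_signature_genes=2, alteration_fractions=(0, 0, 0),
                       nb_dispersion=0.1, seed=3)
    meta, truth = generate_cohort(cfg)
    counts = simulate_counts(meta, truth, cfg)
    # library-size jitter inflates the marginal variance; regress it out by
    # scaling counts to a common library factor first
    lib = counts.sum(axis=0) / counts.sum(axis=0).mean()
    scaled = counts / lib
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    alpha_hat = (v - m) / m**2
    assert abs(np.median(alpha_hat) - cfg.nb_dispersion) < 0.03
    assert (alpha_hat > 0.03).all() and (alpha_hat < 0.25).all()


def test_bap1_mean_reduced_in_altered_samples(default_sim):
    counts, truth = default_sim["counts"], default_sim["truth"]
    bap1 = counts.loc[BAP1]
    un = bap1[truth.labels == "Unaltered"].mean()
    cnmut = bap1[truth.labels == "CN+Mut"]
    if len(cnmut):
        assert cnmut.mean() < un


def test_full_detection_no_decoys_hits_every_mutant_in_every_caller():
    cfg = CohortConfig(n_types=1, samples_per_type=100, n_genes=60,
                       n_signature_genes=6, p_detect=1.0, decoy_rate=0.0, seed=4)
    meta, truth = generate_cohort(cfg)
    tables = simulate_variant_calls(meta, truth, cfg)
    mutants = set(truth.mutant_samples)
    assert mutants  # draw produced at least one mutant
    for tab in tables:
        assert set(tab["sample_id"]) == mutants
        assert (tab["filter"] == "PASS").all()


def test_cn_tables_match_truth(default_sim):
    gene_cn, truth = default_sim["gene_cn"], default_sim["truth"]
    cn = gene_cn.set_index("sample_id")["copy_number"]
    for s, label in truth.labels.items():
        expected = 1 if label in ("CNOnly", "CN+Mut") else 2
        assert cn.loc[s] == expected


def test_every_loss_segment_contains_locus(default_sim):
    segments, truth = default_sim["segments"], default_sim["truth"]
    loss_samples = set(truth.cn_loss_samples)
    seg_by_sample = segments[segments["sample_id"].isin(loss_samples)]
    covered = set()
    for _, row in seg_by_sample.iterrows():
        if row["start"] <= BAP1_START and row["end"] >= BAP1_END:
            covered.add(row["sample_id"])
    assert covered == loss_samples


def test_segment_width_median_matches_mixture():
    """Per-type observed median width agrees with the analytic mixture
    median at n=500 samples per type."""
    cfg = CohortConfig(n_types=2, samples_per_type=500, n_genes=60,
                       n_signature_genes=6,
                       alteration_fractions=(0.0, 0.5, 0.0), seed=6)
    meta, truth = generate_cohort(cfg)
    _, segments = simulate_segments_and_cn(meta, truth, cfg)
    seg = segments.merge(meta[["sample_id", "tumor_type"]].reset_index(drop=True),
                         on="sample_id")
    widths = (seg["end"] - seg["start"] + 1).groupby(seg["tumor_type"])
    for i, ttype in enumerate(["TT1", "TT2"]):
        expected = mixture_median_width(cfg, i)
        observed = widths.median()[ttype]
        assert abs(observed - expected) / expected < 0.20


def test_null_hazard_logrank_rejects_at_nominal_rate():
    """With hazard_ratio_truth=1 the truth split carries no signal: the
    logrank test rejects at roughly the nominal 5% over replicates."""
    from lifelines.statistics import multivariate_logrank_test

    rejections = 0
    for seed in range(30):
        cfg = CohortConfig(n_types=1, samples_per_type=100, n_genes=20,
                           n_signature_genes=2, hazard_ratio_truth=1.0, seed=seed)
        meta, truth = generate_cohort(cfg)
        clin = simulate_survival(meta, truth, cfg)
        groups = truth.signature_class.loc[clin["sample_id"]].to_numpy()
        if len(set(groups)) < 2:
            continue
        lr = multivariate_logrank_test(clin["PFI.time"], groups, clin["PFI"])
        rejections += lr.p_value < 0.05
    assert rejections <= 5


def test_degenerate_censoring_at_zero():
    cfg = CohortConfig(n_types=1, samples_per_type=20, n_genes=20,
                       n_signature_genes=2, censor_median_days=0, seed=7)
    meta, truth = generate_cohort(cfg)
    with np.errstate(divide="ignore"):
        clin = simulate_survival(meta, truth, cfg)
    assert (clin["PFI.time"] == 0).all()
    assert (clin["PFI"] == 0).all()


def test_signature_genes_avoid_chr3p(default_sim):
    genes = default_sim["truth"].genes
    assert not (genes["is_signature"] & (genes["arm"] == "3p")).any()
    assert genes.loc[BAP1, "arm"] == "3p"
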