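"""Normalization and NB Wald testing: brute-force size-factor oracle,
GLM cross-checks against statsmodels and pydeseq2, offset absorption,
and BH / chr3p-mask selection rules."""

import numpy as np
import pandas as pd
import pytest

from bap1sig import ConfigError
from bap1sig import diffexp as de


# ------------------------------------------------------------- size factors

def test_size_factors_symmetry_and_scale():
    rng = np.random.default_rng(0)
    base = rng.integers(5, 200, size=(50, 1))
    counts = pd.DataFrame(np.repeat(base, 4, axis=1),
                          index=[f"g{i}" for i in range(50)],
                          columns=list("abcd"))
    f = de.size_factors(counts)
    assert np.allclose(f, f.iloc[0])
    doubled = counts.copy()
    doubled["d"] = counts["d"] * 2
    f2 = de.size_factors(doubled)
    assert f2["d"] == pytest.approx(2 * f2["a"])


def test_size_factors_match_brute_force_3x3():
    counts = pd.DataFrame([[10, 20, 40], [5, 10, 20], [8, 16, 32]],
                          index=list("xyz"), columns=list("abc"))
    # brute-force median-of-ratios by hand
    arr = counts.to_numpy(float)
    geo = np.array([np.prod(row) ** (1 / 3) for row in arr])
    expected = [np.median(arr[:, j] / geo) for j in range(3)]
    f = de.size_factors(counts)
    assert np.allclose(f.to_numpy(), expected)


def test_size_factor_fallback_warns(caplog):
    counts = pd.DataFrame([[0, 10], [10, 0]], index=["g1", "g2"], columns=["a", "b"])
    with caplog.at_level("WARNING"):
        f = de.size_factors(counts)
    assert np.allclose(f.to_numpy(), [1.0, 1.0])
    assert any("falling back" in r.message for r in caplog.records)


# --------------------------------------------------------------- NB GLM fit

def _sim_counts(n=60, n_genes=40, lfc=1.0, seed=0, alpha=0.1):
    rng = np.random.default_rng(seed)
    altered = np.repeat([0, 1], n // 2)
    base = rng.lognormal(np.log(100), 0.8, n_genes)
    mu = base[:, None] * np.exp2(lfc * altered[None, :])
    size = 1 / alpha
    counts = rng.negative_binomial(size, size / (size + mu))
    idx = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{i}" for i in range(n)]
    counts = pd.DataFrame(counts, index=idx, columns=cols)
    meta = pd.DataFrame({"sample_id": cols}, index=cols)
    altered = pd.Series(altered.astype(bool), index=cols)
    return counts, meta, altered


def test_nb_fit_matches_statsmodels_glm_at_fixed_dispersion():
    """Coefficients/SEs from the in-package IRLS agree with statsmodels
    GLM with the same NB dispersion."""
    import statsmodels.api as sm

    counts, meta, altered = _sim_counts(n=40, n_genes=8, lfc=1.2, seed=1)
    X = de.build_design(meta, altered)
    offset = np.zeros(len(meta))
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(float)
        beta, mu = de._irls(y, X.to_numpy(), offset, 0.1)
        glm = sm.GLM(y, X.to_numpy(),
                     family=sm.families.NegativeBinomial(alpha=0.1)).fit()
        assert np.allclose(beta, glm.params, atol=1e-5)


def test_lfc_and_pvalues_track_pydeseq2():
    """Independent cross-check of the whole DE route against pyDESeq2 on
    one simulated dataset: strong rank agreement of Wald statistics and
    matching effect directions for clearly significant genes."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats
    from scipy.stats import spearmanr

    counts, meta, altered = _sim_counts(n=50, n_genes=60, lfc=1.5, seed=2)
    # half the genes null
    counts.iloc[30:] = counts.iloc[30:].sample(frac=1, axis=1, random_state=0).to_numpy()
    ours = de.fit_nb_wald(counts, de.build_design(meta, altered))

    md = pd.DataFrame({"condition": np.where(altered, "B", "A")}, index=meta.index)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=counts.T, metadata=md,
                           design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stats.summary()
    theirs = stats.results_df
    rho = spearmanr(ours["stat"], theirs["stat"]).statistic
    assert rho > 0.95
    strong = theirs.index[theirs["padj"] < 1e-5]
    assert len(strong) > 5
    assert (np.sign(ours.loc[strong, "lfc"])
            == np.sign(theirs.loc[strong, "log2FoldChange"])).all()


def test_offset_absorption_scaling_all_counts():
    """Scaling every sample's counts is absorbed by the size-factor
    offsets: LFC estimates and Wald statistics are stable.  (Agreement is
    approximate, not exact: the NB likelihood is not scale-equivariant,
    so the refitted dispersion shifts slightly.)"""
    counts, meta, altered = _sim_counts(n=40, n_genes=10, lfc=1.0, seed=3)
    res1 = de.fit_nb_wald(counts, de.build_design(meta, altered))
    res2 = de.fit_nb_wald(counts * 4, de.build_design(meta, altered))
    assert np.allclose(res1["lfc"], res2["lfc"], atol=0.05)
    assert np.allclose(res1["stat"], res2["stat"], atol=0.1, rtol=0.2)


def test_all_zero_gene_is_ns():
    counts, meta, altered = _sim_counts(n=20, n_genes=4, seed=4)
    counts.iloc[0] = 0
    res = de.fit_nb_wald(counts, de.build_design(meta, altered))
    assert res.iloc[0]["pvalue"] == 1.0


def test_rank_deficient_design_names_columns():
    meta = pd.DataFrame({"sample_id": list("abcd"),
                         "dup": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    altered = pd.Series([0, 0, 1, 1], index=list("abcd")).astype(bool)
    meta["clone"] = altered.astype(float)  # collinear with the contrast
    with pytest.raises(ConfigError, match="clone"):
        de.build_design(meta, altered, ["dup", "clone"])


def test_permuted_labels_are_null():
    counts, meta, altered = _sim_counts(n=60, n_genes=300, lfc=2.0, seed=5)
    rng = np.random.default_rng(6)
    perm = pd.Series(rng.permutation(altered.to_numpy()), index=altered.index)
    res = de.fit_nb_wald(counts, de.build_design(meta, perm))
    assert (res["pvalue"] < 0.05).mean() < 0.12


# -------------------------------------------------------- adjust_and_select

def _results(pvals, lfcs=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(pvals))]
    return pd.DataFrame({"gene": genes, "baseMean": 100.0,
                         "lfc": lfcs if lfcs is not None else 1.0,
                         "se": 0.1, "stat": 2.0, "pvalue": pvals},
                        index=pd.Index(genes, name="gene"))


def _anno(genes, arms=None):
    return pd.DataFrame({"gene": genes, "chrom": "chr1",
                         "arm": arms if arms is not None else "q"})


def test_bh_closed_form():
    res = _results([0.01, 0.02, 0.03, 0.04])
    out = de.adjust_and_select(res, _anno(list(res.index)), mask_chr3p=False)
    assert np.allclose(out["padj"], 0.04)


def test_bh_monotone_in_rank():
    rng = np.random.default_rng(1)
    res = _results(sorted(rng.random(50)))
    out = de.adjust_and_select(res, _anno(list(res.index)), mask_chr3p=False)
    assert (np.diff(out.sort_values("pvalue")["padj"]) >= -1e-12).all()
    assert (out["padj"] >= out["pvalue"] - 1e-12).all()


def test_chr3p_mask_keeps_bap1_only():
    genes = ["BAP1", "g1", "g2", "g3"]
    res = _results([0.001, 0.001, 0.5, 0.9], genes=genes)
    anno = _anno(genes, arms=["3p", "3p", "3p", "q"])
    out = de.adjust_and_select(res, anno)
    assert "BAP1" in out.index and "g1" not in out.index and "g2" not in out.index
    assert "g3" in out.index


def test_alpha_out_of_range_rejected():
    res = _results([0.5])
    with pytest.raises(ConfigError):
        de.adjust_and_select(res, _anno(list(res.index)), alpha=1.5)


def test_direction_uses_lfc_cut():
    res = _results([0.001, 0.001], lfcs=[1.0, -2.0])
    out = de.adjust_and_select(res, _anno(list(res.index)), mask_chr3p=False,
                               lfc_cut=1.5)
    assert list(out["direction"]) == ["ns", "down"]


def test_weighted_bh_mode_runs_and_controls_budget():
    rng = np.random.default_rng(2)
    res = _results(rng.random(200))
    out = de.adjust_and_select(res, _anno(list(res.index)), mask_chr3p=False,
                               ihw_bins=4)
    assert out["padj"].between(0, 1).all()
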