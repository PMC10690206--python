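"""Covariate-adjusted negative-binomial Wald differential expression.

Altered-vs-unaltered testing within one tumor type: median-of-ratios size
factors, a per-gene NB log-linear model (log link, size-factor offsets,
per-gene maximum-likelihood dispersion with a floor), Wald tests on the
alteration coefficient, chromosome-3p masking, and Benjamini-Hochberg
adjustment.  The NB parameterization is mean/dispersion with
Var = mu + alpha * mu**2, matching the synthetic generator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from bap1sig._exceptions import ConfigError, InputError

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
_DISPERSION_CEIL = 50.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    The reference is the per-gene geometric mean over samples, restricted
    to genes with no zero count; each sample's factor is the median ratio
    of its counts to the reference.  If no gene is all-nonzero, falls back
    to library-size ratios (normalized to geometric mean 1) with a warning.
    """
    arr = counts.to_numpy(float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        log.warning("no gene with nonzero counts in all samples; "
                    "falling back to library-size factors")
        lib = arr.sum(axis=0)
        if (lib <= 0).any():
            raise InputError("sample with zero total counts")
        f = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    ref = np.exp(np.mean(np.log(arr[allpos]), axis=1))
    f = np.median(arr[allpos] / ref[:, None], axis=0)
    return pd.Series(f, index=counts.columns, name="size_factor")


def normalized_log2(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1), the expression scale used for
    signature scoring and the expression-based variant filter."""
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts / factors.reindex(counts.columns) + 1.0)


def build_design(meta: pd.DataFrame, altered: pd.Series,
                 covariates: list[str] = ()) -> pd.DataFrame:
    """Design matrix: intercept + altered (0/1) + covariates.

    Numeric covariates enter as-is; categorical ones as treatment-coded
    dummies (first level dropped).  Raises a ``ConfigError`` naming the
    collinear columns if the matrix is rank deficient.
    """
    X = pd.DataFrame({"intercept": 1.0, "altered": altered.reindex(meta.index).astype(float)},
                     index=meta.index)
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ConfigError(f"design matrix rank deficient; collinear columns: {bad}")
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    keep: list[str] = []
    bad: list[str] = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(c)
        else:
            bad.append(c)
    return bad


def _nb_negloglik(y, mu, alpha):
    """Negative NB log-likelihood (mean/dispersion parameterization)."""
    size = 1.0 / alpha
    return -np.sum(special.gammaln(y + size) - special.gammaln(size)
                   - special.gammaln(y + 1.0)
                   + size * np.log(size / (size + mu))
                   + y * np.log(mu / (size + mu)))


def _irls(y, X, offset, alpha, beta0=None, maxiter=25, tol=1e-8):
    """Fisher-scoring IRLS for the NB (or Poisson, alpha=0) log-link GLM."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    else:
        beta = beta0.copy()
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        step = new - beta
        beta = new
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta + offset, -30, 30)
    return beta, np.exp(eta)


def _cr_negloglik(y, X, mu, alpha):
    """Cox-Reid adjusted profile likelihood for the dispersion: the
    0.5*logdet penalty corrects the small-sample bias of plugging in the
    fitted means."""
    W = mu / (1.0 + alpha * mu)
    sign, logdet = np.linalg.slogdet((X.T * W) @ X)
    return _nb_negloglik(y, mu, alpha) + 0.5 * logdet


def _fit_gene(y, X, offset, alpha_init):
    """Alternate IRLS for beta and Cox-Reid profile MLE for the dispersion."""
    beta, mu = _irls(y, X, offset, 0.0)  # Poisson start
    alpha = alpha_init
    for _ in range(2):
        res = optimize.minimize_scalar(
            lambda t: _cr_negloglik(y, X, mu, np.exp(t)),
            bounds=(np.log(DISPERSION_FLOOR), np.log(_DISPERSION_CEIL)),
            method="bounded", options={"xatol": 1e-3})
        alpha = max(float(np.exp(res.x)), DISPERSION_FLOOR)
        beta, mu = _irls(y, X, offset, alpha, beta0=beta)
    W = mu / (1.0 + alpha * mu)
    XtWX = (X.T * W) @ X
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return beta, cov, alpha, mu


def fit_nb_wald(counts: pd.DataFrame, design: pd.DataFrame,
                coef: str = "altered",
                factors: pd.Series | None = None,
                dispersion_init: float = 0.1) -> pd.DataFrame:
    """Per-gene NB Wald test for one design coefficient.

    ``counts`` is genes x samples (raw integers); ``design`` comes from
    :func:`build_design` and must align with the count columns.  Size
    factors enter as log offsets, so scaling every sample's counts by a
    common factor leaves the Wald statistics unchanged.  Log2 fold changes
    and standard errors are reported on the log2 scale; two-sided p-values
    use the standard-normal reference for the Wald statistic.  All-zero
    genes get p = 1 and direction ``ns``.
    """
    if coef not in design.columns:
        raise ConfigError(f"coefficient {coef!r} not in design columns {list(design.columns)}")
    design = design.loc[counts.columns]
    X = design.to_numpy(float)
    j = list(design.columns).index(coef)
    if factors is None:
        factors = size_factors(counts)
    offset = np.log(factors.reindex(counts.columns).to_numpy(float))
    rows = []
    for gene, y in counts.iterrows():
        y = y.to_numpy(float)
        if not y.any():
            rows.append((gene, 0.0, np.nan, np.nan, np.nan, 1.0, np.nan))
            continue
        beta, cov, alpha, mu = _fit_gene(y, X, offset, dispersion_init)
        se = np.sqrt(cov[j, j])
        lfc = beta[j] / LN2
        se2 = se / LN2
        stat = beta[j] / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(stat)) if np.isfinite(stat) else 1.0
        rows.append((gene, float(np.mean(y / np.exp(offset))), lfc, se2,
                     stat, p, alpha))
    return pd.DataFrame(rows, columns=["gene", "baseMean", "lfc", "se",
                                       "stat", "pvalue", "dispersion"]
                        ).set_index("gene", drop=False)


def adjust_and_select(results: pd.DataFrame, gene_anno: pd.DataFrame,
                      alpha: float = 0.05, lfc_cut: float = 0.0,
                      mask_chr3p: bool = True, keep_gene: str = "BAP1",
                      ihw_bins: int = 0) -> pd.DataFrame:
    """chr3p masking, multiple-testing adjustment and direction calls.

    Chromosome-3p genes other than ``keep_gene`` are removed *before*
    adjustment (they are co-lost with arm-level copy-number events and
    would swamp the alteration-specific signal).  Adjustment is
    Benjamini-Hochberg; with ``ihw_bins`` > 0 a covariate-weighted variant
    is used instead: genes are binned by baseMean, each bin weighted by
    its enrichment of small p-values (weights normalized to mean 1, floor
    0.1), and BH runs on p / weight.  Direction is ``up``/``down`` iff
    padj < alpha and |lfc| > lfc_cut.
    """
    from statsmodels.stats.multitest import multipletests

    if not 0 < alpha < 1:
        raise ConfigError(f"alpha {alpha} outside (0, 1)")
    res = results.copy()
    if mask_chr3p:
        anno = gene_anno.set_index("gene") if "gene" in gene_anno.columns else gene_anno
        arm = anno["arm"].reindex(res.index)
        drop = (arm == "3p") & (res.index != keep_gene)
        res = res[~drop]
    p = res["pvalue"].fillna(1.0).to_numpy()
    if ihw_bins > 0:
        w = _binned_weights(res["baseMean"].to_numpy(), p, ihw_bins, alpha)
        padj = multipletests(np.minimum(p / w, 1.0), method="fdr_bh")[1]
    else:
        padj = multipletests(p, method="fdr_bh")[1]
    res["padj"] = padj
    sig = res["padj"] < alpha
    res["direction"] = np.where(sig & (res["lfc"] > lfc_cut), "up",
                                np.where(sig & (res["lfc"] < -lfc_cut), "down", "ns"))
    log.info("adjust_and_select: %d up, %d down of %d genes",
             (res["direction"] == "up").sum(), (res["direction"] == "down").sum(), len(res))
    return res


def _binned_weights(base_mean, p, n_bins, alpha):
    """Budget-normalized per-bin weights from small-p enrichment."""
    qs = np.quantile(base_mean, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(qs, base_mean, side="right") - 1, 0, n_bins - 1)
    w = np.ones_like(p)
    raw = np.array([max((p[bins == b] < alpha).mean(), 1e-3) if (bins == b).any() else 1.0
                    for b in range(n_bins)])
    raw = np.maximum(raw / raw.mean(), 0.1)
    raw = raw / np.mean(raw[bins])  # budget: mean weight over genes = 1
    w = raw[bins]
    return w


def significant_genes(results: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(up, down) gene lists from an adjusted DE table."""
    up = results.index[results["direction"] == "up"].tolist()
    down = results.index[results["direction"] == "down"].tolist()
    return up, down
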