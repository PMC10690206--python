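"""Per-sample gene-set and alteration/mutation signature scores.

All scores operate on log-scale normalized expression within one tumor
type: genes are median-centered across the cohort, centered values are
summed over set members per sample (sign-weighted for up/down
signatures), and sums are optionally z-transformed across samples.  The
mutation signature additionally classifies samples positive/negative by a
two-component Gaussian mixture on the (by default unstandardized) scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bap1sig._exceptions import ConfigError, InputError

log = logging.getLogger(__name__)

_SD_EPS = 1e-12


@dataclass
class GeneSet:
    """A named gene set, optionally signed (+1 up / -1 down per gene)."""

    name: str
    genes: list[str]
    signs: dict | None = None

    def __post_init__(self):
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InputError(f"gene set {self.name!r} has duplicate genes")


def _center(expr: pd.DataFrame) -> pd.DataFrame:
    """Median-center each gene across the cohort's samples."""
    return expr.sub(expr.median(axis=1), axis=0)


def _zscore(sums: pd.Series) -> pd.Series:
    sd = sums.std(ddof=0)
    if sd < _SD_EPS:
        return pd.Series(0.0, index=sums.index)
    return (sums - sums.mean()) / sd


def _present(expr: pd.DataFrame, genes, set_name: str) -> list[str]:
    present = [g for g in genes if g in expr.index]
    if not present:
        raise InputError(f"no member of gene set {set_name!r} present in matrix")
    if len(present) < len(genes):
        log.info("gene set %s: %d/%d members absent from matrix and dropped",
                 set_name, len(genes) - len(present), len(genes))
    return present


def geneset_zscore(expr: pd.DataFrame, gene_set: GeneSet,
                   cohort: str = "") -> pd.DataFrame:
    """z-scores of per-sample sums of median-centered expression of the
    set's genes, computed within one cohort (tumor type).

    ``expr`` is a log-normalized gene-by-sample matrix restricted to the
    cohort.  Samples with uniformly high set-gene expression get high
    scores.  If the sums have zero spread, all scores are 0.
    """
    present = _present(expr, gene_set.genes, gene_set.name)
    sums = _center(expr).loc[present].sum(axis=0)
    z = _zscore(sums)
    return pd.DataFrame({"sample_id": expr.columns, "signature": gene_set.name,
                         "cohort": cohort, "score": z.to_numpy(),
                         "raw_sum": sums.to_numpy()}).set_index("sample_id")


def alteration_signature_score(expr: pd.DataFrame, up_genes, down_genes,
                               cohort: str = "", scale: str = "z") -> pd.DataFrame:
    """Sign-weighted alteration signature score per sample.

    Median-centered expression of upregulated genes is summed with weight
    +1 and of downregulated genes with weight -1; the per-sample total is
    z-transformed (``scale="z"``) or left as the raw sum
    (``scale="raw_sum"``).  A positive score means the sample resembles
    the altered phenotype.  Up and down sets must be disjoint.
    """
    up_genes, down_genes = list(up_genes), list(down_genes)
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise InputError(f"up/down gene sets overlap: {sorted(overlap)[:5]}")
    if scale not in ("z", "raw_sum"):
        raise ConfigError(f"unknown scale {scale!r}")
    centered = _center(expr)
    sums = pd.Series(0.0, index=expr.columns)
    if up_genes:
        sums = sums + centered.loc[_present(expr, up_genes, "up")].sum(axis=0)
    if down_genes:
        sums = sums - centered.loc[_present(expr, down_genes, "down")].sum(axis=0)
    if not up_genes and not down_genes:
        raise InputError("both up and down gene sets are empty")
    score = _zscore(sums) if scale == "z" else sums
    return pd.DataFrame({"sample_id": expr.columns, "signature": "alteration",
                         "cohort": cohort, "score": score.to_numpy(),
                         "raw_sum": sums.to_numpy()}).set_index("sample_id")


def cross_signature_correlation(cohort_exprs: dict[str, pd.DataFrame],
                                reference_sets: tuple,
                                native_sets: dict[str, tuple],
                                min_pairs: int = 3) -> pd.DataFrame:
    """Spearman correlation between reference-derived and native scores.

    For each cohort, the reference signature (e.g. derived in UVM) and the
    cohort's own native signature are both scored on the cohort's samples;
    rho is computed over pairwise-complete observations.  Cohorts with
    fewer than ``min_pairs`` complete pairs get rho = NaN.
    """
    from scipy.stats import spearmanr

    ref_up, ref_down = reference_sets
    rows = []
    for cohort, expr in cohort_exprs.items():
        nat_up, nat_down = native_sets[cohort]
        try:
            ref = alteration_signature_score(expr, ref_up, ref_down, cohort)["score"]
            nat = alteration_signature_score(expr, nat_up, nat_down, cohort)["score"]
        except InputError as err:
            log.warning("cohort %s: %s; correlation undefined", cohort, err)
            rows.append((cohort, np.nan, 0))
            continue
        both = pd.concat([ref, nat], axis=1, keys=["ref", "native"]).dropna()
        if len(both) < min_pairs:
            rows.append((cohort, np.nan, len(both)))
            continue
        rho = spearmanr(both["ref"], both["native"]).statistic
        rows.append((cohort, float(rho), len(both)))
    return pd.DataFrame(rows, columns=["cohort", "rho", "n"]).set_index("cohort")


def fit_score_mixture(scores: pd.Series, seed: int = 0,
                      n_init: int = 10) -> tuple[float, dict]:
    """Two-component univariate Gaussian-mixture cutoff for a score vector.

    Fits an unequal-variance GMM (EM, ``n_init`` random restarts, fixed
    seed) and returns the decision boundary between the two component
    means where the posterior probabilities are equal.  Degenerate fits
    (near-empty component, or no boundary between the means) fall back to
    a median split with a warning.
    """
    from sklearn.mixture import GaussianMixture

    x = scores.to_numpy(float)
    if np.ptp(x) < _SD_EPS:
        log.warning("all scores identical; degenerate mixture, median-split fallback")
        return float(np.inf), dict(degenerate=True, means=(x[0], x[0]))
    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed,
                         covariance_type="full")
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    weights = gm.weights_[order]
    resp = gm.predict(x[:, None])
    counts = np.bincount(resp, minlength=2)
    if counts.min() == 0 or m_hi - m_lo < _SD_EPS:
        log.warning("degenerate mixture fit; median-split fallback")
        return float(np.median(x)), dict(degenerate=True, means=(m_lo, m_hi))
    from scipy.optimize import brentq

    def post_diff(v):
        post = gm.predict_proba(np.array([[v]]))[0]
        return post[order[1]] - post[order[0]]

    lo, hi = m_lo, m_hi
    if post_diff(lo) * post_diff(hi) > 0:
        log.warning("no posterior crossing between component means; median-split fallback")
        return float(np.median(x)), dict(degenerate=True, means=(m_lo, m_hi))
    cutoff = float(brentq(post_diff, lo, hi))
    return cutoff, dict(degenerate=False, means=(float(m_lo), float(m_hi)),
                        weights=tuple(float(w) for w in weights))


def mutation_signature_classify(expr: pd.DataFrame, up_genes, down_genes,
                                cohort: str = "", scale: str = "raw_sum",
                                seed: int = 0,
                                cutoff: float | None = None) -> pd.DataFrame:
    """Mutation-signature score with mixture-based positive/negative class.

    Scores as :func:`alteration_signature_score` (default on the raw-sum
    scale, the scale on which published cutoffs are stated); the cutoff is
    either supplied (to reproduce stored classifications) or estimated by
    :func:`fit_score_mixture`.  Class is positive iff score >= cutoff.
    """
    out = alteration_signature_score(expr, up_genes, down_genes, cohort, scale=scale)
    info = {}
    if cutoff is None:
        cutoff, info = fit_score_mixture(out["score"], seed=seed)
    out["cutoff"] = cutoff
    out["class"] = np.where(out["score"] >= cutoff, "positive", "negative")
    out["signature"] = "mutation"
    out.attrs["mixture"] = info
    return out
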