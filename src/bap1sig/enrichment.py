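"""Preranked gene-set enrichment analysis with a permutation null.

Weighted Kolmogorov-Smirnov running-sum enrichment scores on a ranked
gene list, gene-sampling permutation p-values and sign-matched NES
normalization (the classic preranked GSEA definition), plus the
cross-cancer recurrent-pathway matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bap1sig._exceptions import ConfigError, InputError

log = logging.getLogger(__name__)


def _validate_ranking(stats: pd.Series) -> pd.Series:
    if stats.index.has_duplicates:
        raise InputError("ranked gene list contains duplicate genes")
    if not np.isfinite(stats.to_numpy(float)).all():
        raise InputError("ranking statistic contains non-finite values")
    return stats.sort_values(ascending=False, kind="mergesort")


def preranked_es(stats: pd.Series, genes, weight: float = 1.0,
                 ) -> tuple[float, list[str]]:
    """Enrichment score and leading edge for one gene set.

    ``stats`` maps gene -> ranking statistic (sorted internally,
    descending).  Hits increment the running sum by |stat|^weight
    normalized over hits; misses decrement by 1/(N - n_set).  ES is the
    extremum of largest absolute value (ties favor the positive side);
    the leading edge is the set members at or before a positive extremum,
    or at or after a negative one.
    """
    stats = _validate_ranking(stats)
    genes = set(genes)
    hit = stats.index.isin(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise InputError("gene set has no overlap with the ranked list")
    N = len(stats)
    if n_hit == N:
        return 1.0, list(stats.index)
    w = np.abs(stats.to_numpy(float)) ** weight
    inc = np.where(hit, w, 0.0)
    denom = inc.sum()
    if denom <= 0:
        inc = hit.astype(float)
        denom = inc.sum()
    running = np.cumsum(inc / denom - (~hit) / (N - n_hit))
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es_pos, es_neg = running[i_max], running[i_min]
    # ties between the two extrema (within rounding) go to the positive side
    if es_pos >= -es_neg - 1e-12:
        es = float(es_pos)
        leading = [g for g, h in zip(stats.index[:i_max + 1], hit[:i_max + 1]) if h]
    else:
        es = float(es_neg)
        leading = [g for g, h in zip(stats.index[i_min:], hit[i_min:]) if h]
    return es, leading


def _es_for_positions(pos: np.ndarray, w: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ES for many same-size hit-position sets.

    ``pos`` is (n_perm, k), hit positions sorted ascending per row;
    ``w`` the |stat|^weight values of the full ranking.  Candidate
    extrema occur at each hit (after its increment) and just before each
    hit (after the preceding misses); the running sum is linear in
    between and returns to 0 at the end.
    """
    n_perm, k = pos.shape
    wh = w[pos]
    cum = np.cumsum(wh, axis=1) / wh.sum(axis=1, keepdims=True)
    miss = (pos - np.arange(k)[None, :]) / (N - k)
    at_hit = cum - miss                       # value at each hit
    before_hit = at_hit - wh / wh.sum(axis=1, keepdims=True)
    es_pos = at_hit.max(axis=1)
    es_neg = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    pvalue: float
    padj: float
    size: int
    leading_edge: list[str]


def gsea_permutation(stats: pd.Series, gene_sets: dict[str, list[str]],
                     n_perm: int = 1000, seed: int = 0,
                     weight: float = 1.0) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    For every distinct set size, ``n_perm`` random same-size gene samples
    from the ranking form the null ES distribution (shared across sets of
    that size).  One-sided p by ES sign against the sign-matched null
    (the classic preranked-GSEA convention, which keeps null p-values
    uniform): p = (1 + #{same-sign null beyond ES}) / (1 + #same-sign
    nulls); NES = ES / mean(|null ES| of matching sign); BH adjustment
    across sets.  Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    stats = _validate_ranking(stats)
    N = len(stats)
    w = np.abs(stats.to_numpy(float)) ** weight
    rng = np.random.default_rng(seed)
    sizes = {}
    rows = []
    for name, genes in gene_sets.items():
        n_in = sum(1 for g in set(genes) if g in stats.index)
        if n_in > N:
            raise ConfigError(f"gene set {name!r} larger than the ranking")
        es, leading = preranked_es(stats, genes, weight)
        k = n_in
        if k not in sizes:
            # shared null for all sets of size k
            pos = np.argsort(rng.random((n_perm, N)), axis=1)[:, :k]
            pos.sort(axis=1)
            sizes[k] = _es_for_positions(pos, w, N) if k < N else np.ones(n_perm)
        null = sizes[k]
        if es >= 0:
            side = null[null >= 0]
            p = (1 + int((side >= es).sum())) / (1 + len(side))
        else:
            side = null[null < 0]
            p = (1 + int((side <= es).sum())) / (1 + len(side))
        denom = np.abs(side).mean() if len(side) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        rows.append((name, es, nes, p, k, len(side), ",".join(leading)))
    out = pd.DataFrame(rows, columns=["name", "es", "nes", "pvalue", "size",
                                      "n_null_side", "leading_edge"]
                       ).set_index("name", drop=False)
    from statsmodels.stats.multitest import multipletests
    out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out


def recurrent_pathway_matrix(per_cohort: dict[str, pd.DataFrame],
                             min_types: int = 5, alpha: float = 0.05) -> dict:
    """Pathway x cohort NES matrix of recurrently significant pathways.

    Retains pathways with padj < alpha in at least ``min_types`` cohorts.
    Returns the NES matrix, significance tiers per cell
    (``padj<0.05`` / ``padj<0.1`` / ``ns``), and the cohort order from
    average-linkage hierarchical clustering on Euclidean distance of the
    NES columns.
    """
    if len(per_cohort) < min_types:
        log.warning("only %d cohorts supplied for min_types=%d", len(per_cohort), min_types)
    nes = pd.DataFrame({c: df["nes"] for c, df in per_cohort.items()})
    padj = pd.DataFrame({c: df["padj"] for c, df in per_cohort.items()})
    n_sig = (padj < alpha).sum(axis=1)
    keep = n_sig[n_sig >= min_types].index
    nes, padj = nes.loc[keep], padj.loc[keep]
    tiers = pd.DataFrame(np.where(padj < 0.05, "padj<0.05",
                                  np.where(padj < 0.1, "padj<0.1", "ns")),
                         index=padj.index, columns=padj.columns)
    order = list(nes.columns)
    if len(keep) and nes.shape[1] > 2:
        from scipy.cluster.hierarchy import leaves_list, linkage
        Z = linkage(nes.fillna(0.0).to_numpy().T, method="average", metric="euclidean")
        order = [nes.columns[i] for i in leaves_list(Z)]
    return dict(nes=nes[order], tiers=tiers[order], cohort_order=order,
                n_significant=n_sig)
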