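"""Run configuration and the umbrella pipeline.

``run_pipeline`` chains harmonize -> alteration -> diffexp -> signatures
-> enrichment -> survival per tumor type, writing every stage artifact
under the output directory together with a manifest (inputs, thresholds,
seed, software version, artifact checksums).  Rerunning with an identical
config and seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import bap1sig
from bap1sig import alteration as alt
from bap1sig import diffexp, enrichment, harmonize
from bap1sig import io as bio
from bap1sig import signatures as sig
from bap1sig import survival as surv
from bap1sig._exceptions import ConfigError
from bap1sig.synthetic import BAP1, BAP1_CHROM, BAP1_END, BAP1_START

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths, per-type covariates and thresholds for one pipeline run."""

    calls: list = field(default_factory=list)     # MAF paths, one per caller
    counts: str = ""
    gene_anno: str = ""
    gene_cn: str = ""
    segments: str = ""
    clinical: str = ""
    meta: str = ""
    gmt: str = ""                                  # optional gene sets
    legacy: str = ""                               # optional legacy callset
    covariates: dict = field(default_factory=dict)  # tumor_type -> [cols]
    vaf_min: float = 0.2
    alt_min: int = 2
    long_indel_min: int = 40
    quantile_cut: float = 0.5
    alpha: float = 0.05
    lfc_cut: float = 0.0
    min_types: int = 5
    min_mutants: int = 5
    n_perm: int = 1000
    score_scale: str = "z"
    locus: tuple = (BAP1_CHROM, BAP1_START, BAP1_END)
    seed: int = 0
    outdir: str = "pipeline_out"

    def __post_init__(self):
        if not 0 <= self.vaf_min <= 1 or not 0 < self.alpha < 1 \
                or not 0 <= self.quantile_cut <= 1:
            raise ConfigError("threshold outside its documented range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from YAML; relative input paths resolve against the
        config file's directory, and every referenced path must exist."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        base = Path(path).parent
        for attr in ("counts", "gene_anno", "gene_cn", "segments", "clinical",
                     "meta", "gmt", "legacy"):
            p = getattr(cfg, attr)
            if p:
                rp = (base / p) if not Path(p).is_absolute() else Path(p)
                if not rp.exists():
                    raise ConfigError(f"configured path {attr}={p} not resolvable")
                setattr(cfg, attr, str(rp))
        cfg.calls = [str(base / c if not Path(c).is_absolute() else c) for c in cfg.calls]
        for c in cfg.calls:
            if not Path(c).exists():
                raise ConfigError(f"configured call path {c} not resolvable")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index=False):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def write_cohort(sim: dict, outdir) -> dict:
    """Write a simulated cohort to disk in the pipeline's file dialects.

    Returns a dict of written paths; also writes the truth tables (kept
    separate from pipeline inputs).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, tab in enumerate(sim["callsets"]):
        p = out / f"calls_caller{i + 1}.maf"
        bio.write_maf(tab, p)
        paths.setdefault("calls", []).append(str(p))
    bio.write_counts(sim["counts"], out / "counts.tsv")
    bio.write_table(sim["gene_anno"], out / "gene_anno.tsv")
    bio.write_table(sim["gene_cn"], out / "gene_cn.tsv")
    bio.write_table(sim["segments"], out / "segments.tsv")
    bio.write_table(sim["clinical"], out / "clinical.tsv")
    bio.write_table(sim["meta"].reset_index(drop=True), out / "meta.tsv")
    truth = sim["truth"]
    bio.write_table(truth.labels.rename("label").reset_index(), out / "truth_labels.tsv")
    bio.write_table(truth.genes.reset_index(drop=True), out / "truth_genes.tsv")
    for name in ("counts", "gene_anno", "gene_cn", "segments", "clinical", "meta"):
        paths[name] = str(out / f"{name}.tsv")
    paths["truth_labels"] = str(out / "truth_labels.tsv")
    paths["truth_genes"] = str(out / "truth_genes.tsv")
    return paths


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis chain; returns the output directory.

    Stage failures raise :class:`PipelineError` naming the stage; partial
    outputs written by earlier stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    funnel: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return deco

    @stage("inputs")
    def inputs():
        meta = bio.read_table(config.meta).set_index("sample_id", drop=False)
        counts = bio.read_counts(config.counts)
        anno = bio.read_table(config.gene_anno)
        return meta, counts, anno

    meta, counts, gene_anno = inputs

    @stage("harmonize")
    def harmonized():
        callsets = [bio.read_maf(p) for p in config.calls]
        merged = harmonize.merge_callsets(callsets)
        funnel["n_merged"] = len(merged)
        filtered, drops = harmonize.apply_quality_filters(
            merged, vaf_min=config.vaf_min, alt_min=config.alt_min)
        funnel["n_quality"] = len(filtered)
        funnel["quality_drops"] = drops
        factors = diffexp.size_factors(counts)
        norm = diffexp.normalized_log2(counts, factors)
        kept, review = harmonize.apply_expression_filter(
            filtered, norm, meta["tumor_type"], gene=BAP1,
            quantile_cut=config.quantile_cut)
        funnel["n_expressed"] = len(kept)
        artifacts.append(_write(kept, out / "variants_filtered.tsv"))
        artifacts.append(_write(review, out / "variant_review.tsv"))
        summ = harmonize.summarize_variants(kept, meta, config.long_indel_min)
        artifacts.append(_write(summ["by_class"].reset_index(), out / "variants_by_class.tsv"))
        if config.legacy:
            legacy = bio.read_maf([config.legacy][0])
            lmerged = harmonize.merge_callsets([legacy])
            lfilt, _ = harmonize.apply_quality_filters(
                lmerged, vaf_min=config.vaf_min, alt_min=config.alt_min)
            rep = harmonize.compare_callsets(kept, lfilt)
            artifacts.append(_write(rep.assignment, out / "concordance.tsv"))
            funnel["concordance"] = dict(new_only=rep.n_new_only,
                                         concordant=rep.n_concordant,
                                         legacy_only=rep.n_legacy_only)
        return kept, norm, factors

    variants, norm_expr, factors = harmonized

    @stage("alteration")
    def altered():
        gene_cn = bio.read_gene_cn(config.gene_cn)
        segments = bio.read_segments(config.segments)
        loss = alt.call_cn_loss(gene_cn, BAP1)
        status = alt.classify_alteration(loss, set(variants["sample_id"]), meta)
        widths = alt.segment_width_stats(segments, config.locus, loss, meta["tumor_type"])
        artifacts.append(_write(status.reset_index(), out / "alteration_status.tsv"))
        artifacts.append(_write(alt.alteration_summary(status).reset_index(),
                                out / "alteration_summary.tsv"))
        artifacts.append(_write(widths["per_type"].reset_index(), out / "segment_widths.tsv"))
        return status

    status = altered

    gmt_sets = bio.read_gmt(config.gmt) if config.gmt else []
    types = sorted(meta["tumor_type"].unique())
    de_tables, scores, gsea_tables = {}, {}, {}

    for ttype in types:
        @stage(f"diffexp[{ttype}]")
        def de_one(ttype=ttype):
            samples = meta.index[meta["tumor_type"] == ttype]
            altered_flag = status.loc[samples, "altered"]
            if altered_flag.sum() == 0 or (~altered_flag).sum() == 0:
                log.info("%s: no altered/unaltered contrast; skipped", ttype)
                return None
            covs = config.covariates.get(ttype, [])
            design = diffexp.build_design(meta.loc[samples], altered_flag, covs)
            res = diffexp.fit_nb_wald(counts[samples], design,
                                      factors=factors.loc[samples])
            res = diffexp.adjust_and_select(res, gene_anno, alpha=config.alpha,
                                            lfc_cut=config.lfc_cut)
            artifacts.append(_write(res.reset_index(drop=True), out / f"de_{ttype}.tsv"))
            return res

        if de_one is None:
            continue
        de_tables[ttype] = de_one

        @stage(f"signatures[{ttype}]")
        def score_one(ttype=ttype):
            res = de_tables[ttype]
            up, down = diffexp.significant_genes(res)
            samples = meta.index[meta["tumor_type"] == ttype]
            if not up and not down:
                log.info("%s: empty signature; scoring skipped", ttype)
                return None
            sc = sig.alteration_signature_score(norm_expr[samples], up, down,
                                                cohort=ttype, scale=config.score_scale)
            sc["altered"] = status.loc[sc.index, "altered"].to_numpy()
            artifacts.append(_write(sc.reset_index(), out / f"scores_{ttype}.tsv"))
            bio.write_signature(up, down, out / f"signature_{ttype}.tsv")
            artifacts.append(out / f"signature_{ttype}.tsv")
            return sc

        scores[ttype] = score_one

        if gmt_sets:
            @stage(f"enrichment[{ttype}]")
            def gsea_one(ttype=ttype):
                res = de_tables[ttype]
                ranks = res["stat"].dropna()
                usable = {s.name: s.genes for s in gmt_sets
                          if any(g in ranks.index for g in s.genes)}
                if not usable:
                    return None
                tab = enrichment.gsea_permutation(ranks, usable,
                                                  n_perm=config.n_perm,
                                                  seed=config.seed)
                artifacts.append(_write(tab.drop(columns="name"), out / f"gsea_{ttype}.tsv",
                                        index=True))
                return tab

            if gsea_one is not None:
                gsea_tables[ttype] = gsea_one

    @stage("mutation_signature")
    def mut_sig():
        # pooled altered-only contrast (mutation vs CN-only) over tumor types
        # with enough mutant samples
        qualifying = [t for t in types
                      if (status["tumor_type"] == t).sum()
                      and (status.loc[status["tumor_type"] == t, "mutant"]).sum()
                      >= config.min_mutants]
        if not qualifying:
            return None
        pool = status[(status["tumor_type"].isin(qualifying)) & status["altered"]]
        if pool["mutant"].sum() < config.min_mutants or (~pool["mutant"]).sum() < 3:
            return None
        covs = ["tumor_type"] if len(qualifying) > 1 else []
        design = diffexp.build_design(meta.loc[pool.index], pool["mutant"], covs)
        res = diffexp.fit_nb_wald(counts[pool.index], design,
                                  factors=factors.loc[pool.index])
        res = diffexp.adjust_and_select(res, gene_anno, alpha=config.alpha)
        up, down = diffexp.significant_genes(res)
        if not up and not down:
            return None
        # center within tumor type, pool the raw sums, classify by mixture
        pieces = []
        for t in qualifying:
            s = pool.index[pool["tumor_type"] == t]
            pieces.append(sig.mutation_signature_classify(
                norm_expr[s], up, down, cohort=t, seed=config.seed, cutoff=np.inf))
        pooled = pd.concat(pieces)
        cutoff, info = sig.fit_score_mixture(pooled["score"], seed=config.seed)
        pooled["cutoff"] = cutoff
        pooled["class"] = np.where(pooled["score"] >= cutoff, "positive", "negative")
        artifacts.append(_write(pooled.reset_index(), out / "mutation_scores.tsv"))
        return pooled

    @stage("survival")
    def survive():
        if not config.clinical:
            return None
        clin = bio.read_clinical(config.clinical).set_index("sample_id", drop=False)
        rows = []
        for ttype, sc in scores.items():
            if sc is None:
                continue
            sub = clin[clin["tumor_type"] == ttype]
            if len(sub) < 10:
                continue
            prepped = surv.prepare_survival(sub, ttype)
            prepped = prepped.join(sc["score"], how="inner")
            prepped["signature_class"] = np.where(prepped["score"] > 0,
                                                  "positive", "negative")
            if prepped["signature_class"].nunique() < 2:
                continue
            km = surv.km_logrank(prepped["PFI.time"], prepped["PFI"],
                                 prepped["signature_class"])
            try:
                cox = surv.cox_fit(prepped)
                hr = float(cox.loc[0, "hr"])
                plo, phi = float(cox.loc[0, "ci_low"]), float(cox.loc[0, "ci_high"])
                pval = float(cox.loc[0, "p"])
            except Exception:
                hr = plo = phi = pval = np.nan
            rows.append((ttype, km.logrank_p, hr, plo, phi, pval, len(prepped)))
        tab = pd.DataFrame(rows, columns=["tumor_type", "logrank_p", "hr",
                                          "hr_ci_low", "hr_ci_high", "cox_p", "n"])
        artifacts.append(_write(tab, out / "survival.tsv"))
        return tab

    manifest = {
        "version": bap1sig.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "funnel": funnel,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return out
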