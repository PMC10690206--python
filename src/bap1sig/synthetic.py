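"""Synthetic multi-cancer cohort with known BAP1-alteration truth.

Emulates the schemas and statistical structure of a TCGA-style study:
per-tumor-type negative-binomial RNA counts with alteration-dependent
expression shifts, caller-specific somatic variant call tables with decoy
artifacts, gene-level copy number with focal/arm-level loss segments, and
progression-free-interval survival with alteration-dependent hazards.

Every generator is deterministic given ``CohortConfig.seed``; each draws
from its own child stream so the pieces can be regenerated independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from bap1sig._exceptions import ConfigError

log = logging.getLogger(__name__)

BAP1 = "BAP1"
#: BAP1 locus, hg38-style 1-based inclusive coordinates.
BAP1_CHROM = "chr3"
BAP1_START = 52_300_003
BAP1_END = 52_511_030

LABELS = ("Unaltered", "MutOnly", "CNOnly", "CN+Mut")

#: MAF classifications used for true deleterious calls, with draw weights
#: approximating observed BAP1 mutation-type proportions (nonsense/frameshift
#: dominant, then missense).
_TRUE_CLASS = ("Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins",
               "Missense_Mutation", "Splice_Site")
_TRUE_CLASS_W = (0.30, 0.18, 0.09, 0.30, 0.13)

_STAGE_LABELS = {
    0: ("Stage 0",),
    1: ("Stage I", "Stage IA", "Stage IB"),
    2: ("Stage II", "Stage IIA", "Stage IIB"),
    3: ("Stage III", "Stage IIIA", "Stage IIIB", "Stage IIIC"),
    4: ("Stage IV", "Stage IVA"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Parameters
    ----------
    n_types, samples_per_type
        Cohort layout: ``n_types`` tumor types of equal size.
    alteration_fractions
        Per-type probabilities of (MutOnly, CNOnly, CN+Mut); must sum to
        at most 1, the remainder being Unaltered.  A list of per-type
        triples may be given instead of one shared triple.
    n_genes, n_signature_genes
        Total measured genes and the number of truly alteration-responsive
        ("signature") genes among them (always outside chr3p so that the
        arm-loss mask does not remove them).
    effect_lfc
        log2 fold-change magnitude applied to signature genes in altered
        samples (sign per gene, direction stored in the truth).
    nb_dispersion
        NB dispersion alpha with Var = mu + alpha * mu**2.
    purity_range
        Tumor purity ~ Uniform(range); purity scales the observed effect
        (observed LFC = purity x true LFC) so covariate adjustment in the
        DE model has something to recover.
    hazard_ratio_truth
        Multiplicative hazard for truth-positive (altered) samples.
    seed
        Master seed; all five generators derive child streams from it.
    """

    n_types: int = 2
    samples_per_type: int = 200
    alteration_fractions: tuple = (0.05, 0.30, 0.05)
    n_genes: int = 2000
    n_signature_genes: int = 100
    effect_lfc: float = 2.0
    nb_dispersion: float = 0.1
    purity_range: tuple = (0.6, 0.95)
    hazard_ratio_truth: float = 3.0
    seed: int = 0

    # chr3p co-loss structure
    chr3p_fraction: float = 0.05
    chr3p_coloss_factor: float = 0.5      # expression factor per lost 3p copy
    bap1_cn_factor: float = 0.5           # BAP1 expression factor per lost copy
    bap1_mut_factor: float = 0.25         # BAP1 expression factor if mutated

    # variant-call noise model
    n_callers: int = 2
    p_detect: float = 0.95
    decoy_rate: float = 0.15              # decoy artifact calls per sample (expected)
    indel_fraction: float = 0.20          # of true calls
    long_indel_fraction: float = 0.05     # of true calls, length >= 40
    depth_mean: float = 80.0
    vaf_sd: float = 0.05

    # copy-number segment width mixture (metres are base pairs)
    arm_fraction: tuple | None = None     # per-type P(arm-level); default alternates 0.8/0.2
    focal_logmean: float = float(np.log(8e6))
    focal_logsd: float = 0.5
    arm_logmean: float = float(np.log(60e6))
    arm_logsd: float = 0.25

    # survival model
    baseline_median_days: float = 1000.0
    censor_median_days: float = 1500.0
    stage_probs: tuple = (0.1, 0.3, 0.3, 0.2, 0.1)

    def __post_init__(self):
        if self.n_types <= 0 or self.samples_per_type <= 0 or self.n_genes <= 0:
            raise ConfigError("counts (n_types, samples_per_type, n_genes) must be positive")
        if not (0 < self.n_signature_genes < self.n_genes):
            raise ConfigError("n_signature_genes must be in (0, n_genes)")
        for frac in self.fractions_by_type():
            if len(frac) != 3 or any(f < 0 for f in frac) or sum(frac) > 1 + 1e-12:
                raise ConfigError(
                    f"alteration fractions {frac!r} must be 3 nonnegative values summing to <=1")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("purity_range must be an interval within [0, 1]")
        if self.nb_dispersion < 0 or self.effect_lfc < 0:
            raise ConfigError("nb_dispersion and effect_lfc must be nonnegative")
        if abs(sum(self.stage_probs) - 1) > 1e-9:
            raise ConfigError("stage_probs must sum to 1")

    def fractions_by_type(self) -> list[tuple]:
        f = self.alteration_fractions
        if f and isinstance(f[0], (tuple, list)):
            if len(f) != self.n_types:
                raise ConfigError("per-type alteration_fractions must have n_types entries")
            return [tuple(x) for x in f]
        return [tuple(f)] * self.n_types

    def arm_fraction_by_type(self) -> list[float]:
        if self.arm_fraction is None:
            return [0.8 if i % 2 == 0 else 0.2 for i in range(self.n_types)]
        af = self.arm_fraction
        if np.isscalar(af):
            return [float(af)] * self.n_types
        if len(af) != self.n_types:
            raise ConfigError("arm_fraction must be scalar or one value per type")
        return [float(x) for x in af]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stream])


@dataclass
class SyntheticTruth:
    """Ground truth planted in a synthetic cohort."""

    labels: pd.Series                 # sample_id -> alteration label
    genes: pd.DataFrame               # gene, chrom, arm, is_signature, direction
    signature_class: pd.Series        # sample_id -> {positive, negative}
    hazard_multiplier: pd.Series      # sample_id -> float
    seed: int

    @property
    def mutant_samples(self) -> pd.Index:
        return self.labels.index[self.labels.isin(["MutOnly", "CN+Mut"])]

    @property
    def cn_loss_samples(self) -> pd.Index:
        return self.labels.index[self.labels.isin(["CNOnly", "CN+Mut"])]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the sample table (type, purity, subtype, alteration truth).

    Returns a metadata table with one row per sample and the
    :class:`SyntheticTruth` used by every downstream generator.
    """
    rng = config.rng(0)
    rows = []
    for t in range(config.n_types):
        tname = f"TT{t + 1}"
        frac = config.fractions_by_type()[t]
        probs = [1 - sum(frac), *frac]
        for s in range(config.samples_per_type):
            label = rng.choice(LABELS, p=probs)
            purity = rng.uniform(*config.purity_range)
            subtype = f"S{rng.integers(1, 4)}"
            rows.append((f"{tname}-{s:04d}", tname, purity, subtype, label))
    meta = pd.DataFrame(rows, columns=["sample_id", "tumor_type", "purity",
                                       "subtype", "truth_label"])
    meta = meta.set_index("sample_id", drop=False)

    genes = _make_gene_table(config, rng)
    labels = meta["truth_label"].rename("label")
    positive = labels != "Unaltered"
    truth = SyntheticTruth(
        labels=labels,
        genes=genes,
        signature_class=pd.Series(np.where(positive, "positive", "negative"),
                                  index=labels.index, name="signature_class"),
        hazard_multiplier=pd.Series(np.where(positive, config.hazard_ratio_truth, 1.0),
                                    index=labels.index, name="hazard_multiplier"),
        seed=config.seed,
    )
    return meta.drop(columns="truth_label"), truth


def _make_gene_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    n_3p = max(1, int(round(config.chr3p_fraction * n)))
    ids = [BAP1] + [f"G{i:05d}" for i in range(1, n)]
    chrom = np.array(["chr%d" % (1 + i % 22) for i in range(n)], dtype=object)
    arm = np.array(["q"] * n, dtype=object)
    # BAP1 plus the first n_3p-1 other genes live on chr3p (arm co-loss block)
    chrom[:n_3p] = "chr3"
    arm[:n_3p] = "3p"
    is_sig = np.zeros(n, dtype=bool)
    direction = np.zeros(n, dtype=int)
    candidates = np.arange(n_3p, n)
    sig_idx = rng.choice(candidates, size=config.n_signature_genes, replace=False)
    is_sig[sig_idx] = True
    direction[sig_idx] = rng.choice([1, -1], size=config.n_signature_genes)
    return pd.DataFrame({"gene": ids, "chrom": chrom, "arm": arm,
                         "is_signature": is_sig, "direction": direction}
                        ).set_index("gene", drop=False)


def simulate_counts(meta: pd.DataFrame, truth: SyntheticTruth,
                    config: CohortConfig) -> pd.DataFrame:
    """Gene-by-sample integer NB counts with planted expression shifts.

    Mean model per gene g, sample s (log2 scale)::

        log2 mu_gs = log2(base_g * lib_s)
                     + direction_g * effect_lfc * purity_s * altered_s   (signature genes)
                     + log2(bap1 factors)                               (BAP1)
                     + log2(chr3p co-loss factor) * cn_lost_s           (chr3p genes)

    Counts ~ NB(mu, alpha) with Var = mu + alpha mu^2.
    """
    rng = config.rng(1)
    genes = truth.genes
    n_g, n_s = len(genes), len(meta)

    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_g)
    base[0] = 500.0  # BAP1 kept comfortably expressed so rank filters are meaningful
    lib = rng.lognormal(mean=0.0, sigma=0.2, size=n_s)

    altered = (truth.labels.loc[meta.index] != "Unaltered").to_numpy(float)
    cn_lost = truth.labels.loc[meta.index].isin(["CNOnly", "CN+Mut"]).to_numpy(float)
    mutant = truth.labels.loc[meta.index].isin(["MutOnly", "CN+Mut"]).to_numpy(float)
    purity = meta["purity"].to_numpy()

    log2mu = (np.log2(base)[:, None] + np.log2(lib)[None, :])
    shift = genes["direction"].to_numpy()[:, None] * (config.effect_lfc
                                                      * purity * altered)[None, :]
    log2mu += shift
    is_3p = (genes["arm"] == "3p").to_numpy()
    log2mu[is_3p, :] += np.log2(config.chr3p_coloss_factor) * (purity * cn_lost)[None, :]
    # BAP1 row: CN loss and mutation act multiplicatively, attenuated by purity
    bap1_shift = (np.log2(config.bap1_cn_factor) * cn_lost
                  + np.log2(config.bap1_mut_factor) * mutant) * purity
    log2mu[0, :] += bap1_shift - np.log2(config.chr3p_coloss_factor) * (purity * cn_lost)

    mu = np.exp2(log2mu)
    alpha = config.nb_dispersion
    if alpha <= 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / alpha
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    return pd.DataFrame(counts, index=genes.index, columns=meta.index)


def _draw_true_call(rng: np.random.Generator, sample: str, ttype: str,
                    purity: float, cn_lost: bool, config: CohortConfig) -> dict:
    u = rng.random()
    if u < config.long_indel_fraction:
        length = int(rng.integers(40, 81))
        classification = "Frame_Shift_Del"
    elif u < config.long_indel_fraction + config.indel_fraction:
        length = int(rng.integers(1, 15))
        classification = rng.choice(["Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del"],
                                    p=[0.5, 0.3, 0.2])
        if classification == "Frame_Shift_Ins":
            length = length if length % 3 else length + 1
    else:
        length = 0
        classification = rng.choice(_TRUE_CLASS, p=_TRUE_CLASS_W)
        if classification in ("Frame_Shift_Del", "Frame_Shift_Ins"):
            length = 1
    pos = int(rng.integers(BAP1_START + 100, BAP1_END - 200))
    bases = "ACGT"
    if classification.endswith("Ins") and length:
        ref, alt = "-", "".join(rng.choice(list(bases), size=length))
    elif length:
        ref, alt = "".join(rng.choice(list(bases), size=length)), "-"
    else:
        ref = rng.choice(list(bases))
        alt = rng.choice([b for b in bases if b != ref])
    # clonal mutation: heterozygous (purity/2), or hemizygous on the single
    # remaining copy when co-occurring with one-copy CN loss
    center = purity / (2.0 - purity) if cn_lost else purity * 0.5
    vaf = float(np.clip(rng.normal(center, config.vaf_sd), 0.05, 0.98))
    depth = max(10, int(rng.poisson(config.depth_mean)))
    t_alt = max(2, int(round(depth * vaf)))
    return dict(sample_id=sample, tumor_type=ttype, chrom=BAP1_CHROM, pos=pos,
                ref=ref, alt=alt, classification=classification,
                t_depth=depth, t_alt_count=t_alt, filter="PASS")


def _decoy_call(rng: np.random.Generator, sample: str, ttype: str) -> dict:
    pos = int(rng.integers(BAP1_START, BAP1_END))
    ref = rng.choice(list("ACGT"))
    alt = rng.choice([b for b in "ACGT" if b != ref])
    depth = max(10, int(rng.poisson(60)))
    mode = rng.choice(["fail_filter", "low_vaf", "noncoding", "low_alt"])
    classification, flt, vaf = "Missense_Mutation", "PASS", 0.4
    if mode == "fail_filter":
        flt = rng.choice(["germline_risk", "LowEVS", "StrandBias"])
    elif mode == "low_vaf":
        vaf = float(rng.uniform(0.03, 0.19))
    elif mode == "noncoding":
        classification = rng.choice(["Silent", "Intron", "3'UTR"])
    t_alt = 1 if mode == "low_alt" else max(2, int(round(depth * vaf)))
    if mode == "low_vaf":
        t_alt = max(1, min(t_alt, int(np.floor(depth * 0.199))))
    return dict(sample_id=sample, tumor_type=ttype, chrom=BAP1_CHROM, pos=pos,
                ref=ref, alt=alt, classification=classification,
                t_depth=depth, t_alt_count=t_alt, filter=flt)


_COLS = ["sample_id", "tumor_type", "chrom", "pos", "ref", "alt",
         "classification", "t_depth", "t_alt_count", "filter", "caller"]


def simulate_variant_calls(meta: pd.DataFrame, truth: SyntheticTruth,
                           config: CohortConfig) -> list[pd.DataFrame]:
    """Per-caller somatic call tables for the cohort.

    Every truly mutant sample carries one true BAP1 call; each of
    ``n_callers`` callers reports it independently with probability
    ``p_detect``.  Decoy artifact calls (non-PASS filter, sub-threshold
    VAF or alt count, or non-coding classification) are injected at rate
    ``decoy_rate`` per sample.  Odd-numbered callers emit indels in padded
    (VCF-style anchor-base) representation to exercise allele
    normalization downstream.
    """
    rng = config.rng(2)
    true_calls = []
    for sample_id, row in meta.iterrows():
        if truth.labels.loc[sample_id] in ("MutOnly", "CN+Mut"):
            true_calls.append(_draw_true_call(
                rng, sample_id, row["tumor_type"], row["purity"],
                truth.labels.loc[sample_id] == "CN+Mut", config))

    tables = []
    for k in range(config.n_callers):
        caller = f"caller{k + 1}"
        recs = []
        for call in true_calls:
            if rng.random() < config.p_detect:
                rec = dict(call)
                # small caller-specific depth jitter; same underlying variant
                rec["t_depth"] = max(rec["t_alt_count"],
                                     rec["t_depth"] + int(rng.integers(-5, 6)))
                if k % 2 == 1 and "-" in (rec["ref"], rec["alt"]):
                    rec["pos"], rec["ref"], rec["alt"] = _pad_indel(
                        rng, rec["pos"], rec["ref"], rec["alt"])
                rec["caller"] = caller
                recs.append(rec)
        n_decoys = rng.poisson(config.decoy_rate * len(meta))
        decoy_samples = rng.choice(meta.index.to_numpy(), size=n_decoys)
        for s in decoy_samples:
            rec = _decoy_call(rng, s, meta.loc[s, "tumor_type"])
            rec["caller"] = caller
            recs.append(rec)
        tables.append(pd.DataFrame(recs, columns=_COLS))
    return tables


def _pad_indel(rng, pos, ref, alt):
    """VCF-style padded representation: anchor base, position one left."""
    anchor = rng.choice(list("ACGT"))
    ref = anchor + ("" if ref == "-" else ref)
    alt = anchor + ("" if alt == "-" else alt)
    return pos - 1, ref, alt


def make_legacy_callset(meta: pd.DataFrame, truth: SyntheticTruth,
                        config: CohortConfig, detect: float = 0.7) -> pd.DataFrame:
    """A historical single-caller callset detecting each true call with
    probability ``detect`` (no long indels), for concordance analysis."""
    rng = config.rng(5)
    call_rng = config.rng(2)  # replay the true-call stream
    recs = []
    for sample_id, row in meta.iterrows():
        if truth.labels.loc[sample_id] in ("MutOnly", "CN+Mut"):
            call = _draw_true_call(call_rng, sample_id, row["tumor_type"],
                                   row["purity"],
                                   truth.labels.loc[sample_id] == "CN+Mut", config)
            long_indel = max(len(call["ref"].replace("-", "")),
                             len(call["alt"].replace("-", ""))) >= 40
            if not long_indel and rng.random() < detect:
                call["caller"] = "legacy"
                recs.append(call)
    return pd.DataFrame(recs, columns=_COLS)


def simulate_segments_and_cn(meta: pd.DataFrame, truth: SyntheticTruth,
                             config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level CN table and masked loss-segment table.

    CN-loss samples get BAP1 copy number 1 and one loss segment containing
    the BAP1 locus, its width drawn from a per-type lognormal mixture of
    focal and arm-level components.  Other samples get CN 2; some carry a
    neutral or off-locus segment so overlap logic is exercised.
    """
    rng = config.rng(3)
    arm_p = dict(zip([f"TT{t + 1}" for t in range(config.n_types)],
                     config.arm_fraction_by_type()))
    locus_len = BAP1_END - BAP1_START + 1
    cn_rows, seg_rows = [], []
    for sample_id, row in meta.iterrows():
        lost = truth.labels.loc[sample_id] in ("CNOnly", "CN+Mut")
        cn_rows.append((sample_id, BAP1, 1 if lost else 2))
        if lost:
            if rng.random() < arm_p[row["tumor_type"]]:
                width = rng.lognormal(config.arm_logmean, config.arm_logsd)
            else:
                width = rng.lognormal(config.focal_logmean, config.focal_logsd)
            width = int(max(width, locus_len))
            start = max(1, BAP1_START - int(rng.random() * (width - locus_len)))
            seg_rows.append((sample_id, BAP1_CHROM, start, start + width - 1, 1))
        elif rng.random() < 0.2:
            # off-locus deletion elsewhere on chr3 (never overlaps BAP1)
            start = int(rng.integers(60_000_000, 90_000_000))
            seg_rows.append((sample_id, BAP1_CHROM, start,
                             start + int(rng.integers(10_000, 2_000_000)), 1))
    gene_cn = pd.DataFrame(cn_rows, columns=["sample_id", "gene", "copy_number"])
    segments = pd.DataFrame(seg_rows,
                            columns=["sample_id", "chrom", "start", "end", "copy_number"])
    return gene_cn, segments


def mixture_median_width(config: CohortConfig, tumor_type_index: int) -> float:
    """Analytic median of the per-type segment-width mixture (before the
    locus-length floor), solved from the mixture CDF."""
    from scipy.optimize import brentq
    from scipy.stats import lognorm

    p_arm = config.arm_fraction_by_type()[tumor_type_index]
    arm = lognorm(s=config.arm_logsd, scale=np.exp(config.arm_logmean))
    focal = lognorm(s=config.focal_logsd, scale=np.exp(config.focal_logmean))

    def cdf(x):
        return p_arm * arm.cdf(x) + (1 - p_arm) * focal.cdf(x)

    return brentq(lambda x: cdf(x) - 0.5, 1e4, 1e10)


def simulate_survival(meta: pd.DataFrame, truth: SyntheticTruth,
                      config: CohortConfig) -> pd.DataFrame:
    """Clinical table with exponential PFI times and independent censoring.

    Event hazard is ``baseline * hazard_multiplier``; stage labels are
    drawn from ``stage_probs`` over stages 0-4 with AJCC-style roman
    numeral substage strings.
    """
    rng = config.rng(4)
    lam0 = np.log(2) / config.baseline_median_days
    lamc = np.log(2) / config.censor_median_days
    recs = []
    for sample_id, row in meta.iterrows():
        hr = truth.hazard_multiplier.loc[sample_id]
        t_event = rng.exponential(1.0 / (lam0 * hr))
        t_cens = rng.exponential(1.0 / lamc)
        obs = min(t_event, t_cens)
        event = int(t_event <= t_cens)
        stage_num = rng.choice(5, p=config.stage_probs)
        stage = rng.choice(_STAGE_LABELS[stage_num])
        recs.append((sample_id, row["tumor_type"], round(obs, 1), event,
                     stage, row["subtype"], round(obs, 1)))
    return pd.DataFrame(recs, columns=["sample_id", "tumor_type", "PFI.time",
                                       "PFI", "stage", "subtype", "last_followup"])


def simulate_all(config: CohortConfig) -> dict:
    """Run all five generators; returns a dict of every table plus truth."""
    meta, truth = generate_cohort(config)
    counts = simulate_counts(meta, truth, config)
    callsets = simulate_variant_calls(meta, truth, config)
    gene_cn, segments = simulate_segments_and_cn(meta, truth, config)
    clinical = simulate_survival(meta, truth, config)
    return dict(config=config, meta=meta, truth=truth, counts=counts,
                callsets=callsets, gene_cn=gene_cn, segments=segments,
                clinical=clinical, gene_anno=truth.genes[["gene", "chrom", "arm"]])
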