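# Methods

`bap1sig` implements a multi-omic analysis of BAP1 loss in tumor cohorts:
which samples are altered (by somatic mutation, gene-level copy-number
loss, or both), what the alteration does to the transcriptome, and
whether the resulting expression signature stratifies progression-free
survival. Every stage is exercised end to end on a synthetic multi-cancer
cohort with known truth; this note records the models, the defaults and
why, and what the synthetic validation does and does not show.

## Variant harmonization

Caller-specific MAF-dialect tables are merged on the normalized key
(sample, chromosome, position, ref, alt). Allele normalization trims the
shared prefix first (advancing the 1-based position), then the shared
suffix, treating `-` as the empty allele; prefix-first trimming maps a
VCF-style anchor-padded indel exactly onto its minimal MAF
representation, so the same event reported by different callers collapses
to one record without needing reference context. When a reference context
string is supplied, pure indels are additionally left-aligned within it.
Collapsed records take numeric fields from the caller with the highest
`t_depth`; classification conflicts keep the most deleterious label under
the documented severity order (nonsense > frameshift > splice > in-frame
> missense > other). A record is PASS only if every reporting caller
flagged it PASS.

Filters (all thresholds inclusive): `FILTER == PASS`, VAF ≥ 0.2,
`t_alt_count` ≥ 2, and classification outside the silent/intronic/UTR
set. The "low expression within tumor type" criterion is quantified as
BAP1 expression at or below the within-type quantile `quantile_cut`
(default 0.5, i.e. the median) of `log2(count/size_factor + 1)` values;
tumor types with fewer than 5 expressed samples skip the filter with a
warning. Manual read-level review is not implementable in software; in
its place the filter emits a review table (sample, expression, within-type
rank, decision) and accepts an optional exclusion list.

Concordance against a legacy callset partitions the union of keys into
new-only / concordant / legacy-only; same-sample pairs within a 10 bp
window are listed as near-misses (the typical signature of a
representation difference between pipelines) without being counted as
concordant.

## Alteration classification

Gene-level copy number below two is a loss (single-copy and homozygous
deletions alike); missing CN excludes a sample from CN-based calls with a
logged reason, negative CN is an input error. The four-way label is the
2×2 of (loss, mutant): Unaltered / MutOnly / CNOnly / CN+Mut. Mutant
samples absent from the CN table become MutOnly with a warning. Segment
extent per sample is the summed width of merged overlapping loss segments
(copy number < 2, closed-interval overlap with the BAP1 locus
chr3:52300003–52511030); one width per sample feeds per-type median/IQR
summaries, and samples with gene-level loss but no overlapping segment
are reported as discordant rather than silently given width 0.

## Differential expression

Size factors are plain median-of-ratios: the reference is the per-gene
geometric mean over samples restricted to genes with no zero count; the
fallback when no such gene exists is library-size ratios normalized to
geometric mean 1 (warned). Each gene is fit with a negative-binomial
log-linear model (Var = μ + αμ²), log size factors as offsets, and a
design of intercept + altered + covariates (numeric covariates as-is,
categorical as treatment-coded dummies; rank deficiency is an error
naming the collinear columns). Dispersion is estimated per gene by
maximizing the Cox–Reid adjusted profile likelihood (the ½·logdet(XᵀWX)
penalty removes the small-sample bias of plugging in fitted means),
bounded to [1e-8, 50], alternating twice with IRLS updates of the
coefficients. The Wald statistic for the alteration coefficient uses the
observed-information standard error and a standard-normal reference;
fold changes are reported in log2 units. All-zero genes get p = 1.

Before multiple-testing adjustment, chromosome-3p genes other than BAP1
are removed: arm-level loss co-deletes them, so their differential signal
reflects dosage of the whole arm, not the BAP1 response. Adjustment is
Benjamini–Hochberg; an optional covariate-weighted mode (genes binned by
mean count, per-bin weights from small-p enrichment, normalized to mean 1
with a 0.1 floor) captures the mechanism of covariate-weighted FDR
procedures in a testable form and is off by default. Effect-size
shrinkage is intentionally out of scope; raw MLE fold changes carry their
standard errors. The default significance rule for signature derivation
is padj < 0.05 with no fold-change cut (`lfc_cut = 0`); a 1.5 cut is a
display convention for volcano plots only.

Two cross-checks anchor the estimator: coefficients match statsmodels GLM
with the NB family at fixed dispersion, and Wald statistics rank-correlate
> 0.95 with pyDESeq2 on simulated data with matching directions for all
strongly significant genes. Note that exact invariance under count
rescaling holds only for the mean model; the NB likelihood is not
scale-equivariant, so refitted dispersions (and hence Wald statistics)
move slightly when all counts are multiplied by a constant.

## Signature scores

All scores operate on `log2(normalized count + 1)` within one tumor type
(raw-count sums would be dominated by the most highly expressed genes;
median centering is within-cohort by construction). The gene-set score is
the z-transform across samples of per-sample sums of median-centered
expression over set members; members absent from the matrix are dropped
with a logged count, an entirely absent set is an error. The alteration
signature score sums centered expression of upregulated genes with weight
+1 and downregulated genes with weight −1 before the z-transform; swapping
the sets negates every score, and an up-only signature reduces exactly to
the gene-set score. Zero spread yields all-zero scores rather than a
division by zero.

Cross-cohort transfer computes a reference-derived signature (e.g. from
the most extreme cohort) and each cohort's native signature on the same
samples and reports Spearman ρ over pairwise-complete observations (NaN
below 3 pairs).

The mutation signature (mutant-vs-CN-only contrast within altered
samples, derived only when enough mutant samples exist, default ≥ 5) is
kept on the raw-sum scale by default because published cutoffs for such
scores are stated on that scale; the z scale is a flag away. Samples are
classified positive/negative by a two-component univariate Gaussian
mixture (unequal variances, EM with 10 restarts, fixed seed); the cutoff
is the point between the two component means where the posterior
probabilities are equal, found by root bisection. Degenerate fits — all
scores identical, an empty component, or no posterior crossing between
the means — fall back to a median split with a warning (all-identical
scores classify everyone negative). A stored cutoff can be supplied to
reproduce a published classification. On the synthetic cohort the
mutant-vs-CN contrast has little planted signal beyond BAP1 itself (the
generator plants an alteration-level program, not a mutation-specific
one), so this stage demonstrates mechanics, not power.

## Enrichment

Preranked GSEA with the weighted Kolmogorov–Smirnov running sum: hits
increment by |stat|^p normalized over hits (p = 1 by default), misses
decrement by 1/(N − n_set); ES is the extremum of largest absolute value
with exact ±ties broken to the positive side; the leading edge is the set
members at or before a positive extremum (or at or after a negative one).
The null is gene-sampling: for each distinct set size, `n_perm` random
same-size sets (shared across sets of that size, drawn once per size from
the run's seed). P-values follow the sign-matched convention:
p = (1 + #{same-sign null beyond ES}) / (1 + #same-sign nulls) — the
convention under which null p-values are uniform — and
NES = ES / mean(|null ES| of the matching sign). The number of same-sign
nulls is reported (`n_null_side`), making the attainable p-value floor
explicit. BH adjustment runs across sets. The recurrent-pathway matrix
keeps pathways with padj < α in at least `min_types` cohorts (adjusted,
not nominal, p — the stricter reading) and orders cohorts by
average-linkage hierarchical clustering on Euclidean distance of NES
columns, with significance tiers at padj < 0.05 / < 0.1 / ≥ 0.1.

## Survival

Stage labels are parsed from AJCC-style strings (roman or arabic,
substage suffixes ignored): stages 0–2 → low, 3 → high, 4 → excluded
(dropped); unparseable labels are flagged and retained. The maximum-PFI
rule censors administratively at the within-tumor-type median follow-up
time, computed over all samples' follow-up (censored and uncensored)
before stage-4 exclusion is applied to the survival contrast; records
beyond the cutoff are truncated to it with the event cleared (truncation,
not removal, keeps their person-time). The operation is idempotent.

Kaplan–Meier curves, Greenwood intervals and the logrank test come from
lifelines; Cox proportional-hazards models are lifelines' Newton–Raphson
fit with Efron tie handling, reported as HR with Wald 95% CI. The primary
covariate is the binary signature class (score sign), per the design that
a positive score means "altered-like"; adjustment covariates enter as
dummies. Monotone likelihood (complete separation) is detected from
exploding coefficients/standard errors and reported as non-convergence
with no estimate. statsmodels PHReg provides the independent cross-check,
including Efron = Breslow equality in the absence of ties.

## Synthetic cohort: what it emulates and what it does not

The generator plants: per-type alteration fractions (default 5% MutOnly,
30% CNOnly, 5% CN+Mut — the profile of a highly altered tumor type);
NB counts with one global dispersion (default α = 0.1) and lognormal
library-size jitter; a signature of truly responsive genes (default 100
of 2000, ±2 log2 units, never on chr3p) whose observed effect is scaled
by tumor purity (Uniform(0.6, 0.95)) so the purity covariate has
something to recover; BAP1 expression reduced ×0.5 per lost copy and
×0.25 when mutated (purity-attenuated); a chr3p block (5% of genes)
co-shifted in CN-loss samples to emulate arm co-loss; per-caller
detection at p = 0.95 with decoy artifacts at 0.15 per sample, each decoy
failing exactly one quality filter; clonal VAFs at TruncNormal centers
purity/2 (heterozygous) or purity/(2 − purity) (hemizygous after one-copy
loss) with SD 0.05, giving mean VAF ≈ 0.5 and keeping true clonal calls
above the 0.2 filter as real clonal mutations are; loss-segment widths
from a per-type lognormal mixture of focal (median ≈ 8 Mb) and arm-level
(median ≈ 60 Mb) components; exponential PFI times (baseline median 1000
days, censoring median 1500 days) with hazard ratio 3 for altered
samples; and an AJCC stage distribution (0.1/0.3/0.3/0.2/0.1 over stages
0–4) exercising both reclassification and stage-4 exclusion.

It does not emulate: read-level data, mutational signatures or hotspot
structure, subclonal architecture, gene–gene correlation beyond the
planted blocks, per-gene dispersion trends, informative censoring, or a
mutation-specific expression program distinct from the alteration
program. Passing tests therefore show that the estimators recover what
was planted under the stated noise — not that real-cohort effect sizes
or confounding are handled; the covariate machinery is exercised, not
stress-tested.

## Numerical choices and problem sizes

Dispersion floor 1e-8, ceiling 50; IRLS linear predictor clipped to ±30;
z-score guard returns zeros below SD 1e-12; GSEA ES ties to the positive
side within 1e-12; mixture EM uses 10 restarts and a fixed seed; Cox
convergence failures and separation produce explicit non-converged rows.
Validation suites run at sizes chosen to keep the whole chain fast while
leaving comfortable statistical margins: 2 types × 200 samples for the
filter chain, 2000 genes × 100 samples for DE calibration (type-I band
checked against [0.035, 0.065]), 500 random sets × 1000 permutations for
GSEA null uniformity, 100 replicates × 600 subjects for Cox coverage,
and a 2 × 60-sample, 300-gene cohort run twice for the bit-reproducibility
contract (identical artifact checksums under a fixed seed).
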