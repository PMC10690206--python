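# bap1sig

Multi-omic analysis of **BAP1** loss in tumor cohorts. BAP1 is a tumor
suppressor whose inactivation — by somatic mutation, by gene-level
copy-number (CN) loss on chromosome 3p, or both — has tissue-specific
transcriptional and clinical consequences. Studies that only count
point mutations miss most altered samples: CN loss is far more common,
and long indels evade older calling pipelines. This package is for
computational biologists who want to classify alteration state from
heterogeneous variant/CN inputs and quantify its downstream effects,
with every stage validated on synthetic cohorts with known truth.

The chain:

1. **Harmonize** multi-caller somatic calls: normalize alleles (so
   VCF-padded and MAF-minimal indels merge), collapse on
   (sample, chrom, pos, ref, alt), then filter — `FILTER == PASS`,
   VAF ≥ 0.2, `t_alt_count` ≥ 2, non-synonymous/non-intronic, and low
   within-tumor-type BAP1 expression (≤ within-type median by default).
2. **Classify alteration**: gene CN < 2 is loss; the 2×2 of (loss,
   mutant) gives {Unaltered, MutOnly, CNOnly, CN+Mut}; merged
   loss-segment widths around chr3:52300003–52511030 separate focal from
   arm-level events.
3. **Differential expression** per tumor type: NB Wald tests
   (Var = μ + αμ², median-of-ratios offsets, per-gene Cox–Reid
   dispersion), covariate adjustment (purity, subtype), non-BAP1 chr3p
   genes masked before BH adjustment.
4. **Signature scores**: per-sample z-scores of sums of median-centered
   log2 expression; the alteration signature weighs up-genes +1 and
   down-genes −1, so positive ⇒ "altered-like". Mutation-vs-CN scores
   are classified positive/negative by a 2-component Gaussian mixture
   (cutoff at equal posterior odds).
5. **Enrichment**: preranked permutation GSEA (weighted KS running sum,
   gene-sampling null, sign-matched p and NES) and a cross-type
   recurrent-pathway NES matrix.
6. **Survival**: stage reclassification (0–2 low, 3 high, 4 excluded),
   administrative censoring at within-type median follow-up, KM/logrank,
   and Cox PH (Efron ties) for positive vs negative signature scores.

A synthetic-cohort generator (`bap1sig.synthetic`) plants all of the
above — alteration labels, responsive genes, caller noise and decoys,
focal/arm segments, hazard ratios — so the whole pipeline can be checked
against ground truth.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic cohort (2 tumor types × 200 samples, 2000 genes, seed 17) and
write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_harmonize.py
...
python analysis/07_survival.py
```

Step 02 prints the filter funnel and truth recovery:

```
funnel: 178 merged -> 51 quality -> 51 expression-filtered
recovery vs truth: sensitivity 1.000, specificity 1.000
deleterious fraction 0.88, 4 indels >= 40bp
vs legacy callset: 14 new, 37 concordant, 0 legacy-only (27% of current calls are new)
```

i.e. all 51 truly mutant samples survive the chain, no artifact call
does, and merging a second pipeline recovers calls a legacy single-caller
set missed (here 27% new — long indels are only in the new callers).
Step 03 classifies 165/400 samples as altered (41%), in exact agreement
with the planted labels, and separates the arm-level-dominant type
(median loss segment 57.2 Mb) from the focal one (9.6 Mb). Step 05 shows
100% of truly altered samples scoring positive on their own type's
DE-derived signature and a cross-type Spearman ρ = 0.97 between the
reference-derived and native signatures (the two types share the planted
response). Step 07 recovers the planted hazard ratio of 3 for
signature-positive samples (TT2: HR 3.48, 95% CI [2.06, 5.88], logrank
p = 6.8e-07; estimates are attenuated toward the within-type follow-up
cutoff, TT1: HR 2.25).

`bap1sig` is also an umbrella CLI over the same functions
(`bap1sig simulate|harmonize|alteration|diffexp|score|classify|gsea|survive|run`);
`bap1sig run --config run.yaml` chains every stage and writes a manifest
with artifact checksums — reruns with the same config and seed are
bit-identical.

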