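# concordia

Concordance analysis and ensemble filtering for multi-pipeline variant
calling.

Different whole-genome sequencing analysis pipelines — combinations of a
short-read aligner and a variant calling algorithm — disagree substantially
about which variants a genome contains, especially for rare and novel
variants and in difficult sequence context. `concordia` is a toolkit for
quantifying that disagreement across many pipelines and for exploiting it:
variants called by many pipelines are usually real, variants called by few
are usually artifacts, and covariates of the site (allele frequency class,
repeat context, GC bias, coverage, mapping quality) carry additional
information about which is which.

The package is aimed at anyone who runs the same sample through several
aligner+caller combinations and wants (a) to understand the structure of
the disagreement and (b) a principled consensus call set.

## What it computes

**Concordance analysis.** Per-pipeline VCFs are split into biallelic keys,
indels are left-normalized, and everything is merged into a variants x
pipelines genotype matrix (0 = hom variant, 1 = het, 2 = hom ref,
3 = no-call). From it: per-variant call concordance CC (the number of
pipelines calling the variant), Jaccard distances between call sets,
UPGMA clustering of pipelines on genotype profiles, concordant/discordant
locus classes, and depth / allelic-fraction contrasts (Welch's t).

**Factor regression.** CC is regressed on six site covariates (MAF class,
predicted impact, RepeatMasker class, GC bias, coverage, MAPQ) with
log-link count GLMs:

    log E[CC] = beta_0 + X beta,    CC ~ Poisson(mu)  or  NB2(mu, theta)

with the dispersion theta estimated by profile maximum likelihood and a
boundary-corrected likelihood-ratio test between the two families.
`exp(beta)` are concordance rate ratios against the reference levels
(common MAF, modifier impact, non-repetitive, unbiased GC, normal
coverage, good MAPQ).

**Ensemble filtering.** Two consensus filters over the merged matrix:

1. keep variants with CC at or above a cutoff;
2. a two-component mixture model over CC and the factor covariates,

       p(cc, f_1..f_k) = sum_i pi_i N(cc; mu_i, sigma_i^2) prod_j p_i(f_j),

   one component for true variants, one for calling errors, fitted by a
   penalized EM whose CC variance is floored (default 1.0) so a component
   cannot collapse onto a single CC value. Variables enter only if a
   logistic screen against a gold standard finds them associated (Wald
   p < 0.005). The posterior probability of the true-variant component
   ranks variants for filtering.

**Evaluation.** Any call set is scored against a gold standard inside its
callable regions as analytical PPV = TP/(TP+FP) and analytical
sensitivity = TP/(TP+FN), with cutoff sweeps producing performance curves.

**Simulation.** A fully seeded generator produces truth sets, factor
covariates, correlated per-pipeline call sets (caller-family effects
dominate aligner effects), aligner depth/MAPQ tracks, callable BEDs and a
synthetic reference, so the whole pipeline is testable without external
data.

## Worked example

```python
import numpy as np
from concordia import (SimulationConfig, simulate_bundle, merge_callsets,
                       restrict_to_regions, call_concordance, select_variables,
                       CallConcordanceMixture, score_callset)
from concordia.factors import FACTORS

bundle = simulate_bundle(SimulationConfig(), seed=17)
matrix = restrict_to_regions(merge_callsets(bundle.callsets), bundle.callable)

cc = call_concordance(matrix, "SNP")
print(f"{len(cc.cc)} SNPs across {cc.n_pipelines} pipelines, "
      f"mean concordance rate {cc.rate.mean():.3f}")

keys = matrix.keys()
idx = {(r.chrom, r.pos, r.ref, r.alt): i for i, r in bundle.candidates.iterrows()}
feats = bundle.candidates.iloc[
    [idx[(k.chrom, k.pos, k.ref, k.alt)] for k in keys]
].reset_index(drop=True)[FACTORS].copy()
feats.insert(0, "cc", matrix.called().sum(axis=1).astype(float))
labels = np.array([k in bundle.truth.variants for k in keys])

included = select_variables(feats, labels)
result = CallConcordanceMixture(feats, included=included).fit()
print(result.summary())

posterior = result.posterior(feats)
kept = {k for k, s in zip(keys, posterior) if s >= 0.5}
point = score_callset(kept, bundle.truth)
print(f"kept {len(kept)} variants: aPPV {point.appv:.3f}, "
      f"sensitivity {point.sensitivity:.3f}")
```

Output:

```
1241 SNPs across 6 pipelines, mean concordance rate 0.824
Two-component CC mixture, n = 1565, 13 EM iterations
included variables: cc, gc
true component: 1
  comp 1 (true ): pi = 0.8618, CC ~ N(5.454, 1.000)
  comp 2 (error): pi = 0.1382, CC ~ N(1.654, 1.000)
  gc | comp 1: unbiased=0.851, biased=0.149
  gc | comp 2: unbiased=0.627, biased=0.373
kept 1368 variants: aPPV 0.977, sensitivity 0.987
```

The mixture put 86 % of the weight on a high-concordance component (mean
CC 5.5 of 6 pipelines, variance clamped at the floor of 1.0) and learned
that GC-biased sites are over-represented among errors; filtering at
posterior 0.5 keeps a call set that recovers 98.7 % of the truth variants
at 97.7 % precision.

A thin CLI wraps the same steps:

```sh
concordia simulate --out fixtures/ --seed 17
concordia merge --vcf fixtures/ALN1_VCA1.vcf --vcf fixtures/ALN1_VCA2.vcf ... --out merged.tsv.gz
concordia concordance --merged merged.tsv.gz --type snp --out-prefix cc_snp
concordia regress --profiles fixtures/profiles.tsv --cc cc_snp.cc.tsv --family negbin --out effects.tsv
concordia ensemble --features features.tsv --mode mixture --gold fixtures/truth.vcf --out-prefix mix
concordia filter --merged merged.tsv.gz --scores mix.scores.tsv --cutoff 0.5 --out filtered.vcf
concordia evaluate --calls filtered.vcf --gold fixtures/truth.vcf --callable fixtures/callable.bed --out perf.tsv
```

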