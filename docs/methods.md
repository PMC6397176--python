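# Methods

## Variant identity and merging

A variant is the tuple (chrom, 1-based pos, ref, alt). Multiallelic VCF
records are split into one biallelic key per ALT at read time, with the
genotype recoded per alt (0 hom variant / 1 het / 2 hom ref / 3 no-call);
a genotype carrying a different alt than the key under consideration, or
any half-call such as `0/.`, is coded no-call, and haploid (hemizygous)
calls map onto the homozygous codes. Indels are left-normalized by the
standard shift: truncate shared trailing bases (extending left with the
reference base whenever an allele would empty), then trim shared leading
bases; SNPs pass through unchanged. Merging takes the union of keys called
(code 0/1) by at least one pipeline; a pipeline with no record at a key is
coded 3, and explicit hom-ref records are retained. Equivalent
representations of the same *complex* variant beyond indel normalization
are not reconciled — two complex representations remain two keys.

Coordinates: VCF positions are 1-based inclusive, BED intervals 0-based
half-open; all conversion happens inside `RegionSet`, which also sorts and
merges overlapping intervals.

## Concordance

Call concordance CC of a variant is the number of pipelines with genotype
code 0 or 1; explicit hom-ref counts as *not called*, consistently with
the concordant-locus definition below. The denominator for concordance
rates counts only pipelines supporting the variant's type (callers without
indel support are excluded for indels). A locus is concordant only when
*every* compared pipeline reports the identical non-reference genotype;
one no-call, hom-ref or genotype flip makes it discordant.

Jaccard distances 1 − |A∩B|/|A∪B| are computed on called-key sets
(presence/absence); pipeline clustering instead uses Euclidean distance
between genotype-code columns with average-linkage (UPGMA)
agglomeration. UPGMA is implemented directly so that ties have a defined
resolution — among minimum-distance pairs, the lexicographically smallest
label pair merges first — making dendrograms reproducible; it agrees with
scipy's average linkage on tie-free inputs. Distance matrices are emitted
raw and min–max rescaled into [0, 1] over off-diagonal entries (the scaled
form exists for visual comparison only).

Depth per locus is the mean DP over pipelines reporting one; the
alternative allelic fraction is AD[alt]/DP, averaged over heterozygous
cells that report both fields. Concordant/discordant contrasts use
two-sided Welch unequal-variance t-tests (Welch–Satterthwaite df); groups
with fewer than two observations report missing statistics.

## Factor covariates

Six categorical covariates per variant, with reference levels first:

| factor | levels (reference first) | rule |
|---|---|---|
| MAF | common, low, rare, not_reported | rare < 0.5 %, 0.5 % ≤ low < 5 %, common ≥ 5 %; missing = not reported |
| IMPACT | modifier, low, moderate, high | consumed from the annotation input |
| RMSK | non_repetitive + 10 repeat families | site inside an annotated interval; smallest interval wins overlaps, ties lexicographic |
| %GC | unbiased, biased | GC fraction of a window (default 1,000 bp; helper ≈ 2×(insert + 2×read length)) inside [0.25, 0.60] → unbiased |
| COV | normal, other | depth within the closed per-aligner [Q1, Q3] for > 80 % of aligners |
| MAPQ | good, other | mean MAPQ strictly above the per-aligner median for > 80 % of aligners |

Coverage quartiles and MAPQ medians default to being computed over the
analyzed loci per aligner (keeping the module self-contained); genome-wide
values can be supplied instead. The IQR bounds are taken inclusive and the
MAPQ comparison strict, choices that matter only at exact boundaries.

## Count regression

CC is modelled as an unbounded count with a log link on the dummy-coded
factors (19 non-reference indicator columns). The ceiling at the number of
pipelines is accepted as mild misspecification rather than switching to a
binomial model, since the quantity of interest is the multiplicative rate
ratio per level. Estimation is IRLS (weights mu for Poisson,
mu/(1 + mu/theta) for NB2); the NB dispersion theta alternates IRLS with
1-D profile maximization of the exact NB2 log-likelihood over log theta,
converging when the log-likelihood changes by < 1e-8 (relative), at most
100 outer rounds. Theta is capped at 1e8 — beyond that the model is
operationally Poisson. Coefficient covariance is (XᵀWX)⁻¹ at the optimum;
levels absent from the sample are dropped from the fit and reported NaN.
Wald CIs use ±1.96·SE and significance is flagged at p < 0.001 with no
multiplicity correction. The Poisson-vs-NB likelihood-ratio test is
boundary-corrected: under the null the statistic is a 50:50 mixture of a
point mass at 0 and chi-square(1), so p = ½·P(χ²₁ > stat).

## Mixture ensemble

The two-component model factorizes the joint density of CC and the
included categorical variables given the component; CC gets a Gaussian,
each factor a categorical table. Fitting is EM with two regularizations:

* **Variance floor.** The M-step clamps each component's CC variance at a
  floor (default 1.0). This is a constrained M-step, so EM ascent is
  preserved; it prevents a component from collapsing onto one CC value.
* **Table smoothing.** Categorical tables get +0.5 pseudo-counts per cell.
  This makes the M-step a MAP update under a symmetric Dirichlet prior;
  the objective EM ascends is therefore the log-likelihood plus that
  Dirichlet log-prior, which is what `penalized_path` records and what the
  ascent assertion tests (tolerance 1e-9 relative).

Initial responsibilities are cc/max(cc) for the first component and the
complement for the second — a deterministic, label-stable start that needs
no random restarts (seeded restarts are not implemented because the
deterministic start already identifies the high-CC component). Convergence
is a relative penalized-objective change below 1e-8, at most 500
iterations. After fitting, the *true* component is the one holding more
variants at the maximum CC value (hard-assigned by posterior). Degenerate
inputs (constant CC, or a component weight below 1e-6) return a fit
flagged `degenerate=True` with the variance floor engaged rather than
raising, so callers can inspect the result; `raise_on_collapse=True`
restores the strict behaviour.

Variable selection fits one logistic regression of gold-standard
membership on CC plus all dummy-coded factors and keeps a variable iff any
of its terms reaches Wald p < 0.005; CC is always retained. Perfect
separation (possible when CC alone splits the classes) falls back to an
L2-penalized fit whose Wald statistics come from the penalized information
matrix — conservative, which is the safe direction for a screen. SNPs and
indels are fitted separately; with uninformative impact annotations the
screen drops IMPACT, which is the expected indel behaviour.

## Evaluation

Matching is exact key equality after left-normalization; genotype
agreement is *not* required for a true positive by default (an optional
strict-genotype mode counts a genotype mismatch as both FP and FN). Gold
variants outside the callable regions are excluded at load and calls are
restricted symmetrically, so TP + FN equals the callable gold count by
construction (asserted on every call). aPPV and analytical sensitivity are
upper-bound estimates: the gold standard does not enumerate all variants
in the genome. Curve areas integrate aPPV over sensitivity by trapezoid
after collapsing equal-sensitivity points to their best aPPV and anchoring
at sensitivity 0 with constant interpolation, making sweeps with different
minimal kept sets comparable. Cutoff grids are user-supplied; the bundled
analyses sweep the distinct observed scores.

## Synthetic data generator

The generator emulates the statistical structure of a multi-pipeline
study without simulating reads. Defaults (the conditions all bundled
tests run under): 2,000 candidate loci on a 1 Mb random contig, 70 % true
variants / 30 % error-prone loci, 80 % SNPs, 6 pipelines (3 aligners × 2
callers), callable fraction 0.93 in 5 kb windows, truth call probability
0.95 and error-locus call probability 0.18 at reference factor levels,
depth means 40× (truth) vs 22× (error loci), het fraction 0.6, genotype
error rate 0.02.

Factor levels are sampled from class-conditional frequency tables: error
loci skew toward rare/not-reported MAF, repeats, biased GC, abnormal
coverage and poor MAPQ, while impact is sampled identically in both
classes (it carries no calling-error information, so the selection screen
drops it). Factor rate ratios (rare 0.40, not-reported 0.15, high impact
0.70, simple repeat 0.75, biased GC 0.85, abnormal coverage 0.85, poor
MAPQ 0.60, and milder values elsewhere) act **additively on the log-odds**
of a call rather than multiplying the probability: a mild ratio barely
moves an easy true variant (p near 1) but pushes an already-unlikely error
locus further down. Pooled over both classes this produces the observed
compositional effects — rare and novel variants concentrate at low CC —
without dragging easy truth into the middle of the CC histogram, which a
probability-scale multiplier does at a 6-pipeline scale.

Correlation between pipelines comes from shared per-variant random logit
effects: one per caller family (sd 1.8) and one per aligner (sd 0.7),
attenuated ×0.35 on true variants because pipelines agree on easy true
calls and diverge mostly at difficult loci. The caller effect dominating
the aligner effect makes same-caller call sets cluster together, and the
truth/error split plus attenuation yields a bimodal CC histogram — both
verified across seeds in the acceptance suite. GC-rich windows are planted
in the reference around loci labelled biased; aligner depth/MAPQ tracks
are drawn consistently with the sampled coverage/MAPQ classes.

Two exact-model generators serve parameter recovery: factor profiles with
CC drawn from the log-link NB/Poisson model itself (zero counts lifted to
1, mirroring the merge invariant that every merged variant has at least
one call; the lift shifts the smallest stratum means by well under one
standard error at the tested sizes), and draws from a known
Gaussian-categorical mixture (CC rounded and clipped into [1, 70]; the
truncation biases the recovered means by ≈0.1–0.2, inside the ±0.5
recovery tolerance).

What the generator does **not** emulate: read-level errors and alignment
(DP/AD/MAPQ are drawn, not measured), linkage or population structure
(MAF classes are labels, not allele-frequency draws), reference-genome
realism, structural variation, and complex-allele representation
ambiguity. Passing tests therefore demonstrate correctness of the
statistical machinery and qualitative reproduction of the structural
phenomena, not calling accuracy on real sequencing data.

## Problem sizes and numerical choices

Recovery experiments run at the sizes stated above (50,000 mixture draws;
100,000 regression rows × 20 seeds; 200 selection replicates at n = 2,000
with a single binary noise term, whose per-term nominal type-I rate is
0.005); the default bundle is desk-scale at 2,000 loci × 6 pipelines.
Degenerate and boundary cases are pinned by tests: MAF class boundaries
closed on the stated sides, GC band inclusive, the > 80 % aligner-majority
rules strict, empty region sets and empty kept sets permitted, and the
Jaccard distance of two empty sets defined as 0.

## Known limitations

* CC is bounded but modelled as unbounded; rate ratios near the ceiling
  compress toward 1.
* The variance penalty is a hard clamp; a smooth inverse-gamma prior on
  the variance would give the same floor behaviour with a proper MAP
  interpretation, at the cost of an extra hyperparameter.
* Key-level evaluation credits a call whose genotype is wrong (unless the
  strict mode is enabled), so aPPV is optimistic about genotype accuracy.
* The selection screen tests marginal terms jointly in one regression; it
  is a screen, not a causal decomposition of correlated factors.
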