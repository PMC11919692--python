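# Methods

`cnvburden` implements a case/control analysis of rare copy-number
variants (CNVs) called from genotype-array intensity data, together
with a synthetic-cohort generator that makes every stage testable
without access to protected individual-level data. This note describes
the statistical models, the defaults and why they were chosen, what the
generator does and does not emulate, and the numerical conventions.

## Pipeline model

The analysis chain is:

1. **Consensus calling.** Two per-sample callsets (a PennCNV-style
   rawcnv text file and a QuantiSNP-like TSV) are intersected: calls
   from the same sample with the same copy state are paired when their
   overlap is at least 50% of the shorter call (greedy, by descending
   overlap, deterministic coordinate tie-breaks), and the interval
   intersection is emitted with probe support recounted on the probe
   map. Single-caller calls are discarded. The 50%-of-shorter pairing
   rule is a symmetric, scale-free operationalization of "intersection
   of the callsets"; it is configurable.
2. **Sample QC.** Within each genotyping dataset, samples beyond
   mean ± 3 SD on LRRSD, absWF or BAF drift are removed in a single
   pass (zero-variance datasets flag nobody). Cohort-wide caps then
   remove samples with > 20 Mb of raw CNV basepairs or > 20 raw calls;
   "raw" means the consensus callset before size/probe qualification.
3. **Qualification.** Calls must span ≥ 30 kb and ≥ 15 probes.
4. **Filter cascade** (first triggered reason wins): exclusion-track
   overlap (> 30% of call bases for telomere/centromere margins, polyN,
   segmental duplications and repeats; any overlap for Ig/TCR genes and
   EBV-LCL artifact loci), then external SV frequency (≥ 50% reciprocal
   overlap, same state, any population at ≥ 1%), then cohort frequency
   (< 1% required both combined and within every input dataset; loci
   defined by ≥ 50% reciprocal overlap and same state, single linkage),
   then BAF validation. The final kept set is invariant to the order of
   the frequency and BAF steps for the default thresholds, and to input
   row order.
5. **Burden regressions, locus tests, downstream statistics** (below).

### BAF copy-state validation

Per-probe B-allele frequencies inside a call discriminate copy states:
a one-copy deletion has only homozygous bands near 0 and 1, while a
three-copy duplication shows bands near 1/3 and 2/3. The rule used
here: deletions are rejected when more than 10% of probes fall in the
heterozygous band [0.25, 0.75]; duplications are accepted when at least
half of the informative probes (BAF in (0.15, 0.85)) lie within ± 0.09
of 1/3 or 2/3; fewer than 5 informative probes is "insufficient" and
treated as accept. These thresholds are this package's concrete
interpretation of intensity-based call validation — they are exposed in
`FilterConfig`, and are not a reimplementation of any specific tool.
A four-copy duplication has bands at 1/4, 1/2, 3/4; its 1/4 and 3/4
bands fall inside the ± 0.09 windows, so typical CN = 4 calls still
validate, though with less margin.

## Global burden model

The primary model is a logistic regression

    case ~ pc1 + ... + pc5 + sex [+ screened covariates] + burden_metric

with exp(coef), Wald 95% CI and two-sided P reported for the metric
term; a linear variant regresses the metric on the covariates plus case
status. Candidate covariates (PC6–PC20, LRRSD) enter when their
marginal association P is below 0.05 (configurable) for **both** the
raw per-sample call count (linear screen) and case status (logistic
screen). Separation or non-convergence is flagged on the result, never
silently reported as an estimate; a metric with no variation raises.

Burden metrics are per-sample summaries of the filtered callset:
counts by state and by size bin ({30–100 kb, 100–500 kb, 500 kb–1 Mb,
> 1 Mb} — the fourth bin completes the partition), CNV-impacted
basepairs (odds ratios conventionally scaled per 100 kb), coding vs
noncoding (≥ 1 bp overlap with any gene interval), counts of CNVs
hitting ≥ 1 gene above a pLI cut (0.5 and 0.995), per-gene impacted
counts, geneset counts, cohort-singleton counts, and kilobases of
evolutionarily constrained sequence impacted per state. Constraint is a
per-window (default 1 kb) phyloP-like score; the default cuts {≥ 1,
≥ 2, ≥ 4} are stand-ins for unlabeled published bins and configurable.
The adjusted excess rate is the case-status coefficient of the linear
count model, with a seeded bootstrap percentile CI; country or sex
homogeneity of burden is tested with a metric × group interaction term.

## Exact stratified association (CMH)

Locus units are tested against the four country × sex strata with an
exact Cochran–Mantel–Haenszel test. Conditioning on all margins of the
per-stratum 2×2 tables, the total case-carrier count T is distributed
as the convolution of per-stratum hypergeometrics; coefficients are
computed from log-binomials (gammaln) and convolved with per-stratum
max-normalization, which is numerically safe because only ratios
matter. The two-sided P sums the probabilities of all T values whose
point probability does not exceed the observed one (relative tolerance
1e-12); a "double the smaller tail" alternative is available through
the mid-P machinery. The reported common odds ratio is the conditional
MLE, solved by Brent's method on the exponential-family mean identity;
observed T at the support boundary gives 0 or ∞, and all-zero carrier
counts give P = 1 with an undefined OR. With one stratum the test
reduces exactly to Fisher's exact test (verified to 1e-10 against
scipy), and with two tiny strata it matches brute-force enumeration of
outcome pairs aggregated by T.

### Clumping into units

Gene mode: genes are merged into one unit when over 50% of the CNVs
overlapping either gene overlap both (Jaccard of their call sets
> 0.5), iterated to a fixed point with coordinate-ordered deterministic
merging. Breakpoint mode: probe positions are merged into maximal runs
while adjacent probes' overlapping-call sets share > 50%; a probe with
no calls breaks a run. Deletions and duplications are clumped and
tested separately; BH-FDR (statsmodels step-up, monotone) is applied
within each family at 0.05 for locus tests and 0.1 for enrichment.

## Permutation inflation factor and its precision

Genomic inflation is estimated non-parametrically: case/control labels
are permuted within strata, per-unit exact P values are converted to
1-df chi-square quantiles, and

    lambda = median(observed chi2) / median(pooled permuted chi2).

Two choices matter for discrete exact tests:

* **mid-P conversion** (default, flag to disable): the point-probability
  two-sided P of a discrete test is a step function that equals 1 for
  most sparse tables; mid-P (half weight on the observed atom) restores
  an approximately uniform null and a meaningful median.
* **minimum carrier count** (default 2, flag): a single-carrier unit's
  two-sided exact P is essentially constant, contributing a degenerate
  atom that destabilizes the median ratio.

The estimator's Monte-Carlo precision is limited by the number of
units: the observed median over n units has sd ≈ 1/(2·f(m)·√n) around
the pooled-null median m, which for chi-square(1) and n ≈ 100 gives a
lambda sd of roughly 0.25. Per-replicate lambdas at the scales used
here are therefore noisy; calibration claims in the tests are made on
medians across replicate cohorts, which land within [0.9, 1.1] under
the null.

### Batch-artifact screening and exclusion

Dataset-specific pileups of small deletions mimic association signal.
The screen works on the 30–100 kb deletion size bin (breakpoint units)
in two phases. Phase 1 is a deterministic pileup screen that excludes
every unit whose carriers number ≥ 3, sit in ≤ 2 datasets, belong to
one phenotype class, and whose exact mid-P is below 0.1 — the signature
of a batch cluster, detectable regardless of the bin-level lambda,
which (see above) moves by less than its own Monte-Carlo spread when
only a few loci are contaminated. Phase 2 then applies a lambda-gated
greedy loop: while the bin lambda exceeds 1.05 and concentrated units
remain, the unit whose removal most reduces lambda is dropped; if
lambda stays high with no qualifying unit a warning is recorded. A
genuine case excess spread across datasets fails the concentration
condition and is never excluded. The phase-1 thresholds admit a small
false-positive rate (~1 balanced-background unit per cohort at the
default settings), which mirrors what a manual inspection would also
flag.

## Recurrence permutation test

The statistic is the number of deletion units with at least two case
carriers (a flag restricts to case-only units). The null permutes
labels within strata; empirical P = (1 + #{perm ≥ observed}) /
(1 + n_perm), so P ≥ 1/(n_perm + 1) and the test is conservative at
small n_perm. The statistic is informative only for units with few
carriers — a 6-carrier unit has ≥ 2 case carriers under almost every
permutation — which matches its purpose of detecting an excess of
rare recurrent case deletions.

## Power analysis

The power model is carrier-based: one observation per person, control
carrier frequency f, case carrier frequency f·RR/(1 + f·(RR − 1))
under multiplicative risk, and a two-sided two-proportion z-test at the
Bonferroni per-test alpha (0.05/20 000 by default). Power uses the
standard normal approximation with pooled SE under the null and
unpooled under the alternative; RR*(f) at 80% power is solved by
Brent's method to |power − target| < 1e-6, with unattainable targets
reported, not raised. The analytic curve matches Monte-Carlo simulation
of the same z-test within ± 0.02 when expected carrier counts are
roughly ≥ 20 (f ≈ 0.01 at these sample sizes); at much smaller f·n the
binomial skewness degrades both the formula and the z-test itself, and
the Monte-Carlo route should be preferred. Published detectable-RR
figures derived from allele-based (2N) models are systematically lower
than this carrier-based model's output; the model choice is
intentional (one carrier observation per person matches how CNV
carriers are counted) and flagged wherever curves are compared.

## Downstream statistics

* **Geneset enrichment**: logistic regression of case status on the
  per-sample count of impacted geneset genes, adjusting for burden
  covariates plus the total impacted genes (or total impacted
  intolerant genes in the subsetted mode); genesets with no impacted
  genes are skipped, near-collinear counts flagged. Concentration of
  significant results in brain-expression sets uses a two-sided Fisher
  exact test on the significant × brain table.
* **Exome-overlap**: one-sided upper-tail Poisson P, Pr(X ≥ observed),
  via the exact tail sum.
* **PRS comparison**: linear model of the normalized polygenic score on
  deleterious-carrier status plus burden covariates within cases;
  estimates are in SD units; < 2 carriers gives a flagged result.
* **Clinical comparisons**: comorbidity × carrier-class contingency
  tables with Pearson chi-square (df = 1, no continuity correction by
  default; Yates by flag) or Fisher's exact test when any expected cell
  is < 5 (a `force_chi2` flag reproduces published chi-squares computed
  on sparse tables); treatment response compares per-individual percent
  YBOCS improvement, 100·(pre − post)/pre, between carriers and
  non-carriers with a pooled-variance two-sided t-test. Per-individual
  averaging is the default (ratio-of-means available by flag).
* **Deleterious CNV classes**: pLI > 0.995, or membership in either
  neurodevelopmental geneset flag (`NDD_fu`, `NDD_kendall`).

## Synthetic cohort generator

The generator emulates a two-country array cohort: defaults of 2248
cases and 3608 controls in 4 datasets (the first ⌈0.7·k⌉ datasets are
Swedish), 63% female cases, 70% female controls, case/control
allocation to the four country × sex strata by largest-remainder
apportionment (a stratum left empty is a configuration error), and
dataset assignment with Dirichlet-weighted case/control mixes so that
dataset composition genuinely varies. PCs are standard normal with a
country mean-shift on PC5 and dataset shifts on PC7; LRRSD, absWF and
BAF drift are log-normal (the source cohort's QC-metric distributions
are not published, so these are plausible stand-ins); outlier samples
get inflated LRRSD/absWF and a Poisson(30) load of extra noise calls.

The genome is a scaled-down stand-in: six autosomes totalling 285 Mb,
~2 kb mean probe spacing (exponential gaps), 400 non-overlapping genes
with bimodal pLI, pNull concentrated in low-pLI genes, NDD flags drawn
pLI-weighted (⌈5%⌉ of genes), random pathway-style genesets, exclusion
tracks at chromosome ends/midpoints plus random segdup/repeat/polyN/
Ig-TCR/EBV intervals, a per-kb constraint track (Gaussian base plus a
pLI-weighted bonus inside genes), and a gnomAD-like external SV
frequency table.

Background CNV loci are drawn until their expected per-sample rate
reaches `background_cnv_rate` (default 1.3, giving ~1.2–1.4 consensus
calls and ~0.5–0.6 filtered calls per sample, matching the target
study's scale); carrier frequencies follow the configured spectrum
(singletons, < 0.1%, 0.1–1%, ≥ 1%) and realized frequencies of
non-common classes are capped below 1%. Planted risk loci wrap pLI>0.5
genes (deletions, default per-carrier odds ratio 4.0, in line with
published deletion burden in intolerant genes) or any gene
(duplications, default 1.3); the case carrier probability satisfies
odds_case = OR · odds_control. Background call rates are modulated by
exp(0.1·PC7 + 1.5·(log LRRSD − μ)), normalized to mean 1, so covariate
screening has genuine structure to discover; planted loci are left
unmodulated so their odds ratio is a clean estimand. Each true CNV is
emitted by both callers with independent Gaussian boundary jitter
(SD 4 kb), 5% dropout per caller, and per-caller false positives that
can never reach consensus; per-probe BAF values follow the copy-state
band model (noise SD 0.03) and LRR values are shifted by state with
per-sample noise. Artifact clusters are 30–100 kb deletions confined to
the largest dataset (big batches show batch effects), all carriers of
one phenotype class.

`null_sim_config` defines the strict null used for type-I calibration:
planted ORs 1, artifact clusters off, and the LRRSD case shift zeroed —
with the call-rate/LRRSD coupling active, a case-shifted LRRSD would be
a mediated case effect on call counts, not a null.

**What the generator does not emulate**, hence what passing tests do
not show about real data: raw IDAT intensities and genome-wide
per-probe tracks (probe values exist only within call regions), GC
waves and genotyping-chemistry batch structure beyond the injected
pileups, linkage between loci, overlapping genes and realistic gene
density, sex chromosomes, relatedness and fine-scale ancestry beyond
two point-mass countries, and real external SV frequencies.

## Numerical conventions and problem sizes

All coordinates are 0-based half-open internally (caller files are
1-based inclusive and converted at the boundary); autosomes only.
Every stochastic component draws from `numpy.random.default_rng`
seeded through per-stage `SeedSequence` children, so identical configs
reproduce byte-identical output files. Equality tolerances: 1e-12
relative for exact-test point-probability ties; 12 significant digits
for results round trips. Degenerate inputs are explicit: empty call
lists return empty frames, zero-probe BAF queries raise, zero-variance
metrics are skipped (QC) or raised (burden), lambda over an empty unit
set is NaN with a note.

Replicate-based checks in the test suite run at reduced but honest
scales chosen to keep the whole suite in a few minutes on one CPU:
null calibration uses 50 cohorts of 1000/1000 with 100 lambda
permutations and 199 recurrence permutations; parameter recovery uses
50 cohorts of 2000/2000; the artifact screen uses 10 cohorts of
2000/2000. The acceptance script reruns the same analyses at 20/20/10
replicates. The artifact screen runs at 2000/2000 rather than
1000/1000 because a 19-call/3-locus cluster inside a ≤ 600-sample
dataset exceeds the 1% in-dataset frequency filter and is (correctly)
removed before any inflation screen could see it.

## Known limitations

* The exact CMH conditional-MLE OR is reported without a confidence
  interval (the exact conditional CI is not implemented).
* The median-ratio lambda is a noisy statistic below a few hundred
  units; treat single-cohort values within ± 0.25 of 1 as
  uninformative at these scales.
* Firth or penalized regression is not provided; separation is flagged,
  not corrected.
* The analytic power formula loses accuracy for expected carrier
  counts below ~20; use the Monte-Carlo routine there.
* Frequency clustering uses single-linkage reciprocal overlap, which
  can chain long calls at complex loci into one locus.
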