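# Methods

## The composite-population model

The simulator reproduces a classic quantitative-genetics yardstick: a
*second-generation composite* of two source populations in linkage
equilibrium.  Each parental population is fixed for one allele per locus
(which parent carries the dosage-coded alternate allele is randomized per
locus, so no genome-wide haplotype orientation survives into the
composite).  The F1 is heterozygous everywhere; random union of F1 gametes
yields the generation-2 composite of census size N.  Counting the F1 as
generation 1 is a modeling choice — the design does not fix it — and only
shifts the generation label, not any statistic.

Two properties make this design a useful reference:

* every locus starts at expected frequency 0.5, so gene diversity starts at
  the biallelic maximum (sample expectation `0.5·(1 − 1/(2·2N))`);
* gametic LD exists *only* between linked loci, with the closed form
  `E[D] = (1−2c)/4 · δ_A δ_B` at founding (δ = parental frequency
  difference, here ±1) and `D_t = D_0 (1−c)^t` under subsequent random
  mating.  Both closed forms are enforced by oracle tests.

Random mating uses *equal parental contributions*: the 2N gamete slots are
tiled over the N parents (each parent exactly twice when offspring count
equals parent count; contributions differ by at most one otherwise) and
shuffled into random pairs.  This halves the variance of family size and
gives Ne ≈ 2N − 1, so breeding sizes 100 and 300 realize effective sizes
near 200 and 600.  The alternative reading — census 200/600 with genotyping
samples of 100/300 — would add binomial sampling variance on top of the
same drift and was not adopted.  The He-decay test checks the realized rate
against `(1 − 1/(2Ne))^t`.

### Genome and map function

Nine chromosomes with maize-like physical lengths (301…157 Mb) carry a
1,170-SNP grid (130 per chromosome) into which the packaged 94-SNP
simulated panel is embedded; those 94 clustered SNPs are the analysis set.
Physical distance converts to recombination fraction by Haldane's map at a
uniform **2 cM/Mb**.  The rate is the one genuinely free knob in the model:
with founding LD `(1−2c)/4`, a rate m satisfies the reference decay profile
(|D| > 0.10 below 10 Mb *and* < 0.05 beyond 50 Mb) only for
1.61 < m < 4.6 cM/Mb at the far end and m small enough at the near end;
2 cM/Mb sits comfortably inside that window and is of the order of maize
genome-wide averages.  It is exposed as `SimConfig.cm_per_mb`.

Meiosis is simulated as the exact Markov consequence of Haldane's
no-interference model: a gamete's parental-strand indicator starts
Bernoulli(½) per chromosome and switches between adjacent loci with
probability c(gap), vectorized over all gametes.

### Trait architecture and heritability

One hundred causal loci (19 QTLs + 81 minor genes) are placed uniformly at
random (probability ∝ chromosome length, never colliding with an analysis
SNP).  Locus genotype values are −a, d, +a for dosages 0, 1, 2, with d/a
drawn uniformly on [−1.2, 1.2] (bidirectional dominance).  Scaling follows
a strict priority:

1. each QTL's expected genetic variance at p = 0.5 under Hardy–Weinberg and
   linkage equilibrium (`a²/2 + d²/4`) is pinned to 2.4% of phenotypic
   variance;
2. minor-gene effects are scaled jointly so the total expected genotypic
   variance equals h²·V_P (h² = 0.5), leaving the minors 4.4% in aggregate
   (≈0.054% each);
3. all effects are rescaled linearly — and the intercept set — so the two
   extreme multilocus homozygotes sit at 5 and 50 mL/g.

Step 3 multiplies every variance component by one factor, so steps 1–2
survive exactly; no residual discrepancy needs logging.  The environmental
variance is `V_e = V_G(1−h²)/h²` with V_G the *expected* founding value;
realized heritability then fluctuates around 0.5 with the founding sample
(the calibration test checks R² = 0.50 ± 0.05 at N = 300).  Realized
founding LD between causal loci perturbs realized V_G slightly; because
allele orientations are randomized, these covariance terms are zero-mean.

All randomness flows from a single integer seed through named substreams
(effects, founding, meiosis, error, sampling), so stages are reproducible
in isolation.

### Truncation selection

Progeny-based half-sib/full-sib/selfed recurrent selection schemes are
deliberately simplified to truncation selection on the individual
phenotype: it produces the same qualitative footprint (response in the
mean, hitchhiking-driven SNP frequency change, F_ST against the base
population) without modeling trial designs.

## Statistics chain

* **Gates.** A SNP is non-polymorphic when maf < 1% (the boundary value
  0.01 counts as polymorphic).  HWE is tested by a 1-df chi-square against
  (q², 2pq, p²) expectations, no continuity correction, α = 0.05;
  monomorphic SNPs are untestable and drop out of HWE-gated analyses.
* **EM haplotypes.** The two-locus EM treats the double heterozygote as the
  only hidden-phase class; convergence at max frequency change < 1e-8 or
  1,000 iterations (non-convergence is flagged, not raised).  The
  log-likelihood is non-decreasing per iteration and the estimate preserves
  the single-locus frequencies; when every individual is a double
  heterozygote the likelihood is flat in phase and the uninformative
  stationary point (all 0.25) is returned with a ridge flag.  Individuals
  missing either genotype of a pair are dropped pairwise.
* **D′ sign.** D′ is reported unsigned (|D|/D_max), matching the use of
  average absolute LD values in summaries; D keeps its sign in pair tables.
* **Summaries.** Within-chromosome ("linked") means per chromosome and
  pooled, plus an all-pairs mean including inter-chromosome pairs, are
  reported side by side; inter-chromosome pairs carry no distance and never
  enter decay profiles.
* **Temporal test.** `Fc = (x−y)²/(z−xy)` over `E[Fc] = 1/(2S0) + 1/(2St)`
  on 1 chi-square df; the drift term `t/(2Ne)` is off by default — the
  sampling-only null reproduces the reference significance thresholds
  (|Δp| ≈ 0.10 at S = 300, ≈ 0.17 at S = 100) — and available as an option.
  SNPs fixed for the same allele in both samples are excluded, not counted.
  Because drift is real but unmodeled by the default null, a small number
  of drift-only significances is *expected*: at Ne = 200 and t = 10 the
  drift sd of Δp is ≈0.079 against a 0.177 threshold, i.e. ≈2–3 significant
  SNPs per 94 rather than zero; with the drift term enabled the count falls
  to ≈α·n.  Summary blocks report the min/mean/max |Δp| both over
  significant SNPs and over all SNPs, since either convention appears in
  published tables.
* **F_ST.** Nei-style (H_T − H_S)/H_T with unweighted population means;
  AMOVA-flavored estimators are out of scope.  Loci with H_T = 0 are
  excluded from the average.
* **Association.** Default least-squares model is the genotype-class ANOVA
  (up to 3 classes, 2 df), with 1-df dosage regression as an option; BH
  step-up at FDR 5% (10% available).  The Bayesian route is a per-SNP
  normal regression on dosage with flat coefficient priors and Jeffreys
  error-variance prior, Gibbs-sampled with run lengths 50,000 burn-in /
  100,000 iterations / thinning 5 by default and a scaled profile
  (500/2,000/2) for fast runs; significance is the 95% HPD excluding zero,
  with **no multiplicity control** — so with ~94 SNPs a handful of chance
  HPD flags is expected under the null, and HPD-only hits on chromosomes
  without QTLs should be read in that light.  Minor genes are real causal
  signal too: with founding LD reaching tens of Mb, several minor genes on
  a QTL-free chromosome can aggregate into a detectable association, which
  is a property of the design rather than a false positive.  No
  population-structure or kinship covariates are fitted (within-population
  GWAS); that is a known limitation.
* **HPD.** Shortest contiguous window containing ⌈level·n⌉ sorted draws.
* **Imputation.** Modal-dosage imputation (ties to the lower code) is a
  deliberately simple, documented default; haplotype-aware phasing or
  imputation is out of scope, and every analysis can instead drop missing
  calls pairwise.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: panel positions and
clustering, composite founding, drift at stated effective sizes, the QTL /
minor-gene architecture, heritability, and the genotypic range.  It does
not emulate genotyping error, missing-data patterns, population structure
or admixture, assortative mating, selfing rates, or the progeny-trial
selection schemes of real breeding programs.  Passing tests therefore
validate the statistics chain and the stated simulation design — they do
not certify behavior on structured or error-prone real panels (the real
popcorn genotypes behind the original study are not publicly deposited, so
its field-data numbers are not reproducible here).

## Numerical choices and problem sizes

EM runs vectorized across all SNP pairs; the Gibbs sampler reduces each
iteration to O(1) scalar updates via precomputed sufficient statistics.
Replicate-based checks use 20 seeds for diversity/temporal/calibration
quantities and 10 paired seeds for the GWAS behavior checks, with the
scaled MCMC profile; these sizes put Monte-Carlo error comfortably inside
the stated tolerances while keeping a full run in minutes on one core.
Degenerate inputs follow explicit conventions: constant phenotype → p = 1;
perfect class separation → p = 0; monomorphic marginals are errors for LD;
fixed-in-both loci are excluded from temporal scans.

## Known limitations

Single trait, biallelic SNPs only; no mutation or migration; no interference
in recombination; the uniform cM/Mb map ignores recombination hot/cold
regions; the Bayesian model is univariate per SNP (no multi-SNP or kinship
models); modal counts of rare events (e.g. temporal significances at small
sample sizes) have genuinely broad sampling distributions across replicate
sets, and single published realizations can sit off the modal value.
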