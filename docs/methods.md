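# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic cohorts they are validated on, and
the design choices made where the underlying methods left room.

## Scope and model overview

The package chains six analyses that together connect genetic variants to
cell-type-resolved expression and on to donor-level traits in a
single-nucleus RNA-seq cohort with paired genotypes:

1. **Cell QC** — rule-based nucleus filtering with a data-driven total-UMI
   window derived from a sigmoid fit.
2. **Pseudobulk cis-eQTL mapping** — library-size normalization, per-donor
   mean aggregation within a cell type, variant QC (MAF, missingness,
   Hardy–Weinberg), greedy LD pruning, OLS association with covariates and
   expression PCs, and conditional-FDR significance calling against an
   auxiliary study.
3. **ABF colocalization** — five-hypothesis Bayesian comparison of two
   summary-statistic tracks over one region.
4. **Causal inference test (CIT)** — a four-condition intersection–union
   test for whether a mediator gene transmits a locus effect onto a trait,
   with permutation FDR over collections of trios.
5. **Differential abundance (DA)** — multiscale kNN neighborhood
   composition scores, a logistic DA measure in [−1, 1], fixed symmetric
   selection thresholds, and community detection over the selected cells.
6. **Trait enrichment** — donor-collapsed cluster–trait association
   (Fisher exact for categorical traits, permutation z-scores for
   quantitative ones), generic set-overlap tests, windowed antemortem
   measurement selection, and genotype–trait regression with
   neuropathology interactions.

Everything is exercised end-to-end on synthetic cohorts with planted
effects; no external data are required.

## Cell QC

A nucleus is removed when it fails any of, in order: detected genes below
`min_genes` (default 200); mitochondrial, ribosomal, or hemoglobin read
fraction above 5%, 5%, and 0.1% respectively; log10(genes)/log10(UMI)
below 0.8 (the standard library-complexity metric); or total UMI outside
the sigmoid window. The first failing rule claims the cell in the report,
so per-rule counts partition the removed set.

**Sigmoid window.** A logistic CDF `F(x) = 1/(1+exp(−(x−mu)/s))` is fitted
to the empirical CDF of log10 UMI by least squares (trust-region, bounded
`s > 0`; initial location the median, initial scale IQR/(2 ln 3), the
logistic's IQR relation). Cutoffs sit at `mu ± ln(4)·s`, i.e. exactly at
the fitted curve's 0.2 and 0.8 points. Fitting the CDF rather than a
density makes the inflection the distribution's median and needs no
binning; the choice is recorded in the filter report. If the optimizer
fails, the 1st/99th percentiles stand in and `converged=False` is
reported. Consequence worth knowing: for a population whose log10 UMI is
genuinely logistic-shaped, this window removes the outer ~40% of cells —
the rule is a *window around the inflection*, not an outlier clip, so on
unimodal data it trims shoulders aggressively. Tests that require planted
violations to be exactly the removed set therefore supply a fixed wide
`SigmoidFit`, which the API supports precisely so a fit frozen on one
population can be re-applied (this also makes filtering idempotent).

## Normalization and pseudobulk

Per-cell size factors are total counts divided by the mean total
(unit-mean factors); the normalized value is `log1p(count/size_factor)`.
This is a deliberate, fully specified replacement for pooling-based
deconvolution normalization: at pseudobulk resolution the dominant
correction is library depth, and the simple scheme is exactly testable.
Note the unit-mean definition makes the factors invariant to global
sequencing-depth rescaling (the normalized linear values scale with
depth). Pseudobulk is the per-donor mean of normalized expression over
that donor's cells of one annotated type; donors without such cells are
excluded and listed, never imputed.

## Variant QC, LD pruning, and the association model

Variants pass QC at sample MAF ≥ 0.05, missing call rate ≤ 0.1, and
Hardy–Weinberg exact p ≥ 1e−6. The HWE test is the exact conditional
test: given the allele counts, the p-value sums the probabilities of all
heterozygote counts no more probable than the observed one (log-factorial
arithmetic; verified against full enumeration for every configuration up
to 30 donors).

LD pruning is greedy and position-ordered: scanning along the chromosome,
a variant is dropped when its dosage r² with any already-kept variant
within 250 kb exceeds 0.8 (threshold configurable). The first variant of
a correlated pair by position is kept, making the output deterministic.

The cis window is inclusive: a variant is tested for a gene when its
position is within 250,000 bp of either end of the transcribed span
(1-based). The association model is OLS of pseudobulk expression on
alt-allele dosage plus fixed covariates (age, sex, ancestry, disease
status by default) plus the top expression PCs (default 20; computed from
the centered, unit-variance-scaled pseudobulk matrix with a deterministic
sign convention). Expression PCs were chosen over genotype PCs because
they absorb the dominant technical variation in aggregated expression;
externally computed PCs can be supplied instead. Missing dosages are
handled per-pair by complete-case analysis; singular designs (e.g.
constant dosage) are skipped with a reason code. A separate interaction
test adds diagnosis and diagnosis×dosage terms and reports the
interaction coefficient.

**Conditional FDR.** For aligned primary/auxiliary p-value pairs,

    cfdr_i = p_i · #{j: aux_j ≤ aux_i} / #{j: p_j ≤ p_i and aux_j ≤ aux_i},

clipped at 1 — the empirical conditional-CDF estimator with the null
fraction conservatively set to 1. Monotonization (non-decreasing in p) is
applied within groups of equal auxiliary p-value, which is a no-op for
continuous auxiliaries; this keeps the estimator's direct evaluation
intact while guarding against inversions when auxiliaries are tied. With
an uninformative (constant) auxiliary the estimator reduces to
p/ecdf(p), the unconditional analog. Under a global null the fraction of
pairs called at cfdr ≤ 0.05 is far below 0.05 (the estimator behaves like
an adjusted p-value), verified over 500 replicates.

## Colocalization

Per variant, the Wakefield log approximate Bayes factor is

    lABF = 0.5·[ln(V/(V+W)) + z²·W/(V+W)],

with `z = beta/se` and `V = se²` when standard errors are present, else
|z| from the two-sided p-value and `V = 1/(2·N·f·(1−f))` (additionally
divided by `s(1−s)` for a case-control trait with case fraction `s`).
Prior effect variances default to `0.15²` (quantitative) and `0.2²`
(case-control). Five hypothesis weights are accumulated entirely in log
space with log-sum-exp — h3 uses `log1p(−exp(logS12 − logS1 − logS2))`,
clipped to zero if rounding makes S12 exceed S1·S2 — so thousand-variant
regions with |z| in the tens do not overflow. Posteriors are the
softmax of the weights; the per-variant shared-causal posterior is the
softmax of `lABF1 + lABF2`. When both (beta, se) and (p, maf, N) are
available, se is used; a flag forces the sample-size approximation, and
the CLI can source MAF from either track. Caveat: with a single assumed
causal variant and extremely peaked likelihoods (|z| ≳ 25), the posterior
becomes sensitive to which LD partner is the realized lead variant in
each track; planted-simulation checks therefore run in the strong-but-
finite |z| ≈ 10–15 regime.

## Causal inference test

For a trio (L dosage, G mediator expression, T trait), four conditions
must hold: (1) L–G association, (2) L–T association, (3) L–G association
given T, (4) L independent of T given G. Conditions 1–3 are nested-model
F-tests (L enters as a 1-df numeric dosage by default; a flag switches to
a 2-df genotype factor). Condition 4 is an equivalence-type test: the
observed F for L in `T ~ G + L` is compared against a non-central F whose
noncentrality is the conditional-model F *implied by the marginal L–T
association under no mediation*. If the marginal effect were direct, the
G–T correlation it induces is `r_GT = r_LT·r_LG`, so the population
partial correlation given G is

    pr0² = r_LT²(1−r_LG²)/(1−r_LT²·r_LG²),  ncp = df2·pr0²/(1−pr0²).

A small p4 = Pr(F_ncp ≤ F_obs) means conditioning on G removed more of
the L–T association than collinearity alone could — evidence for
mediation. The attenuation correction matters: comparing against the raw
marginal F (no correction) is anti-conservative under pleiotropy, where
conditioning on a mediator correlated with L attenuates the F even though
nothing is mediated; simulations showed ~36% false causal calls in the
pleiotropic scenario without the correction and ~0% with it. The omnibus
p-value is the intersection–union max of the four. Degenerate trios
(|corr(G,T)| = 1, constant L, fewer than 10 complete cases) raise typed
errors; the noise-free chain T = G = L is such a case by construction.

**Permutation FDR.** For each trio the locus L is permuted across donors
B times (default 1000), which nulls all four component tests while
preserving the G–T relationship. Each component's pooled permutation
distribution gives

    q_j(p) = π0 · [mean_b #{p*_j,b ≤ p}] / max(1, #{p_j,obs ≤ p}),

clipped at 1 and monotonized by the standard running minimum from the
largest p downward; the omnibus q is the max of the four component
q-values (the intersection–union logic carried to the FDR level), and
trios with q < 0.05 are called causal. π0 is the Storey estimate
#{p_obs > 1/2}/(N/2) clipped to [0, 1] — without it the estimator is
conservative by 1/π0 exactly when a collection is mostly true positives.
Two designs were evaluated and rejected: permuting T leaves condition 1
non-null, and pooling the *omnibus* max-p over permutations is degenerate
because under any full-null permutation the marginal (p2) and
equivalence (p4) p-values are intrinsically anti-correlated
(p2* + p4* ≈ 1), bounding the permuted omnibus away from small values so
that q(p) ≈ 0 for every p below ~0.4. Componentwise pooling with the
omnibus max avoids both failure modes. At the reference operating point
(n = 500 donors, standardized effects 0.5, noise 1, dosage MAF 0.3,
200 trios per scenario, B = 1000), causal recall is ~0.9 and the
reactive/pleiotropic/pure-null false-call rates are ~0.

The downstream-network screen prefilters candidate genes by |correlation|
with the mediator (default 0.3), submits each survivor as the trait T,
runs the permutation FDR across all tested candidates, and returns the
q < 0.05 set; the mediator submitted as its own candidate is rejected by
the collinearity guard.

## Differential abundance

Cells are compared between two conditions in a given embedding (by
convention the top 40 PCs of normalized log expression; this module does
not recompute integration). For each cell and each k in a grid (default
100–4000 in steps of 500, capped below the cell count; a 100–1000 step
100 preset mirrors reduced-burden runs), the score is the fraction of the
cell's k nearest Euclidean neighbors (self excluded, distance ties broken
by cell index for determinism) carrying condition A. An L2-regularized
logistic model predicts the condition from the multiscale score vector,
and the DA measure is the predicted probability rescaled to [−1, 1]
(2q̂ − 1). Regularization is deliberately weak (C = 100, near-MLE): with
at most a dozen bounded features and thousands of cells there is nothing
to regularize against, and shrinkage toward the base rate matters because
selection uses *fixed absolute* thresholds (±0.8 by default; a ±0.5
preset exists). The measure's ceiling for an enriched subpopulation is
2·P(A | subpopulation neighborhood) − 1: with subpopulation frequencies
0.3 vs 0.05 and the default 65:35 condition composition, the ceiling is
≈ 0.84, only just above the 0.8 threshold — planted-recovery checks are
therefore fixture properties at fixed seeds, and real analyses should
prefer the permutation-null thresholding the measure's null distribution
supports (under random labels the 99th percentile of |measure| stays far
below 0.8, so the fixed thresholds select essentially no cells).

Selected cells are partitioned by community detection on a symmetrized
20-NN graph using the Leiden algorithm (the seeded successor of Louvain)
with the RB resolution parameter at 0.01; singleton communities merge
into the community with the nearest centroid. The neighbor ordering is
exact (blocked O(n²) distances with stable tie-breaking), intended for
cohort-scale embeddings up to a few tens of thousands of cells.

## Trait enrichment

Nuclei collapse to donors: a donor belongs to a cluster when it
contributes at least `min_cells` nuclei (default 1). Categorical traits
use the two-sided Fisher exact test on the member × trait table (sample
odds ratio with Haldane 0.5 correction at zero cells; BH FDR across all
clusters in a call; all-member or empty clusters are flagged degenerate
with p = 1). Quantitative traits use a permutation scheme that resamples
*membership*, not trait values: the observed statistic is the member mean,
the null is the means of random same-size donor subsets drawn without
replacement from the cohort, and z = (obs − mean)/sd of that null.
Enumeration replaces sampling when the subset space is at most the
permutation budget (default 10,000); the empirical two-sided p uses the
add-one estimator on the sampled path and the exact tail proportion on
the exhaustive path (an exact enumeration is not a Monte-Carlo estimate).
A z-derived normal p is emitted alongside the empirical one. The null z
is unbiased (measured E[z] = 0.008 ± 0.011 over 8000 replicates) with
unit-ish variance.

Windowed antemortem selection takes, per donor, the measurement closest
to death among those at most 1095 days before death (the three-year
boundary is inclusive); donors with no qualifying measurement are absent
from the result. Genotype–trait association is OLS of the trait on allele
dosage plus covariates, optionally adding a pathology main effect and a
dosage×pathology interaction; quantitative burden variables take a
log(x+1) transform (chosen over log(x) to admit zero burdens) while
semiquantitative stages enter as numeric. Singular designs raise an error
naming the most collinear column pair.

## Synthetic cohorts

The generators define the conditions every validation runs under:

* **Genotypes** — haplotypes follow a first-order Markov chain: each
  allele copies its left neighbor with probability `ld_decay` (default
  0.6) or is drawn fresh from the variant's frequency (uniform on the
  configured MAF range, default [0.05, 0.5], mirroring the post-QC
  spectrum). Adjacent-genotype correlation therefore decays geometrically
  with marker distance, giving LD pruning and colocalization something
  real to resolve. Dosages are alt-allele counts over two independent
  haplotypes; optional missingness is uniform.
* **Cells** — negative-binomial counts (gene dispersions log-normal
  around size 10) with per-cell log-normal library factors (sd 0.3).
  Roughly 65% of donors carry the disease condition, matching the
  primary cohort's composition; this ratio is load-bearing for the DA
  measure's ceiling (see above) and was fixed up front. A designated
  subpopulation shifts a random fifth of non-housekeeping genes four-fold
  up or down and appears at condition-dependent frequency. Housekeeping
  sets are pinned at ~2% mitochondrial, ~2% ribosomal, and ~0.001%
  hemoglobin content so healthy cells clear the QC thresholds with margin.
  Planted QC violators are half low-complexity cells (25 genes retained)
  and half dying cells (mitochondrial reads boosted to ~20–25% of the
  library). Cis-eQTL effects multiply a donor's gene mean by
  `exp(beta·(dosage−1))`. The generator does not model ambient RNA,
  doublets, or realistic co-expression structure, so passing tests
  certify the statistical machinery, not robustness to those artifacts.
* **Trios** — `G = β_LG·L + ε` and `T = β_GT·G + ε` (causal), with the
  reactive, pleiotropic-independent, and confounded wirings analogous; L
  is a binomial dosage at MAF 0.3, noise is Gaussian. Defaults (effects
  0.5, noise 1, n = 500) are chosen for test power, not effect-size
  realism, since plausible per-gene effect distributions are not
  identifiable from summary descriptions.
* **Summary-track pairs** — a quantitative trait fit by per-variant OLS
  and a case-control trait built by thresholding a Gaussian liability at
  the case fraction (default 0.087) and fit by per-variant logistic
  regression, over a shared simulated panel; one causal variant shared,
  or two distinct ones half a region apart.
* **Donor traits** — trait = covariate effects + main·dosage +
  interaction·dosage·pathology + noise, with age/sex/education covariates
  and either a gamma-distributed quantitative burden (15% exact zeros) or
  an integer 0–6 stage; each donor gets 1–4 timestamped measurements for
  the windowing operation.

All generators are fully determined by their seed; identical
configurations produce byte-identical outputs, and the file writers
(VCF v4.2 with GT fields, Matrix Market + TSV sidecars, plain TSV,
YAML manifests) round-trip losslessly.

## Problem sizes used in validation

The default test and acceptance runs use: the full HWE enumeration sweep
to 30 donors (~5.5k configurations); 500-replicate conditional-FDR null
calibration at 200 pairs; colocalization oracles on ≤50-variant regions
and planted simulations on 1500–2000-donor panels; 200 trios per CIT
scenario at n = 500 with B = 1000 permutations; a ~3000-cell DA cohort
with a 100-replicate random-label null; and 1000–4000 replicate
enrichment nulls on a 50-donor cohort. These sizes make the Monte-Carlo
error small relative to every acceptance band while keeping a full run in
tens of seconds.

## Known limitations

* OLS with fixed covariates, not a mixed model: no kinship or repeated-
  measures random effects, consistent with unrelated donors.
* Single-causal-variant colocalization; no multi-signal decomposition.
* The CIT condition-4 calibration is verified by simulation against its
  own generative scenarios, not by equivalence to any external package.
* The DA neighbor search is exact and quadratic; very large atlases would
  need an approximate backend.
* cis boundaries, window boundaries (3 years), and HWE thresholds are
  inclusive by convention; coordinates are 1-based throughout.
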