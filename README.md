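# cellink

Linking genetic variants to cell-type expression and downstream traits in
single-nucleus RNA-seq cohorts.

`cellink` implements, as one tested pipeline, the statistical chain used to
connect common variants with cell-type-resolved gene regulation and
donor-level phenotypes in postmortem brain cohorts: bespoke nucleus-level
QC (including a sigmoid-inflection total-UMI window), per-cell-type
pseudobulk cis-eQTL mapping with conditional-FDR significance calling,
approximate-Bayes-factor colocalization of eQTL and GWAS signals, a
four-condition causal inference test with permutation FDR for building
gene regulatory neighborhoods around a mediator, multiscale kNN
differential-abundance detection of disease-enriched cell subpopulations,
and donor-collapsed cluster–trait enrichment with windowed antemortem
measurements. It is written for statistical geneticists and computational
biologists who want each of those steps as an inspectable, unit-tested
primitive rather than a black box, and it ships a synthetic-cohort
generator with planted effects so the whole chain is verifiable without
any data download.

## The statistics at the core

* **cis-eQTL**: for gene *g* and variant *v* within 250 kb of its
  transcribed span, OLS of pseudobulk expression on dosage,
  `y_g = α + β·x_v + Cγ + PCδ + ε`, after MAF/missingness/HWE variant QC
  and greedy LD pruning at r² > 0.8. Significance via the conditional
  FDR, `cfdr_i = p_i·#{aux_j ≤ aux_i}/#{p_j ≤ p_i ∧ aux_j ≤ aux_i}`,
  which borrows power from an auxiliary study's p-values for the same
  pairs.
* **Colocalization**: per-variant Wakefield log-ABFs,
  `lABF = ½[ln(V/(V+W)) + z²W/(V+W)]`, combined in log space into the
  posteriors PP0–PP4 of the five standard hypotheses with priors
  p1 = p2 = 1e-4, p12 = 1e-5; PP4 is the shared-causal-variant posterior
  and a per-variant posterior identifies the likely shared variant.
* **CIT**: a trio (L, G, T) is called causal (G mediates L→T) only if
  L–G, L–T, and L–G|T associations all hold *and* an equivalence test
  shows the conditional L–T|G association is significantly smaller than
  the marginal effect could explain; the omnibus p is the max of the four
  and FDR comes from 1000 locus permutations (componentwise pooled
  q-values, omnibus q = their max).
* **Differential abundance**: per cell, the fraction of its k nearest
  neighbors in condition A across k = 100…4000 (step 500); a logistic
  model maps the multiscale score vector to a DA measure 2q̂−1 ∈ [−1, 1];
  cells beyond ±0.8 are selected and partitioned by seeded community
  detection at resolution 0.01.
* **Cluster–trait enrichment**: donors (not nuclei) are the unit; Fisher
  exact tests for categorical traits, and for quantitative traits a
  z-score against the null distribution of member-mean values over
  10,000 random same-size donor subsets.

`docs/methods.md` derives each piece, states the assumptions, and records
every design decision.

## Worked example

The `analysis/` directory is a numbered narrative over one synthetic
cohort (80 donors, 65% disease; 120 variants with LD; ~8k nuclei with a
planted disease-enriched subpopulation, five planted cis-eQTLs, and 5%
planted QC violations). Running the scripts in order:

```
$ python analysis/01_simulate_cohort.py
cohort: 80 donors (52 AD / 28 CT), 120 variants, 8166 nuclei
planted: 5 cis-eQTL effects (beta 0.6 on log scale), subpopulation at 30% vs 5%
frequency, 388 QC-violating nuclei

$ python analysis/02_qc_cells.py
sigmoid fit: inflection at log10 UMI = 3.594, scale 0.082 -> window [3.480, 3.708]
planted violations caught: 388/388

$ python analysis/03_map_eqtl.py
variants: 120 -> 120 after QC -> 70 after LD pruning
17780 cis pairs tested; 20 significant at cFDR <= 0.05 across 10 genes
planted eGenes recovered: 5/5 (['G0001', 'G0002', 'G0003', 'G0004', 'G0005'])

$ python analysis/04_colocalize.py
shared causal variant: PP0=0.0000 PP1=0.0000 PP2=0.0000 PP3=0.0000 PP4=1.0000
  top per-variant H4 posterior: v00031 (1.000); truth: v00031
distinct causal variants: PP0=0.0000 PP1=0.0000 PP2=0.0000 PP3=1.0000 PP4=0.0000

$ python analysis/05_cit_network.py
        causal: called causal in 100% of trios
      reactive: called causal in 0% of trios
   independent: called causal in 0% of trios
    confounded: called causal in 0% of trios

$ python analysis/06_da_subpopulations.py
1062 DA nuclei selected beyond +/-0.8 (1 subpopulation(s) at resolution 0.01)
recovery of the planted subpopulation: precision 1.000, recall 1.000

$ python analysis/07_trait_enrichment.py
cluster 0 vs condition: OR = 571.67, p = 1.26e-16, FDR = 1.26e-16 (56/80 donors)
dosage -> windowed trait (raw pathology): beta = 0.663 (p = 0.174); dosage x
pathology interaction beta = -0.346 (p = 0.00629); planted: main 0.4,
interaction -0.15
```

Reading the outputs: QC caught every planted violation (the UMI window
additionally trims distribution shoulders, by design of the ln 4 rule);
the eQTL scan recovered all five planted eGenes at cFDR ≤ 0.05; the
colocalization put all posterior mass on the correct hypothesis in both
regimes and ranked the true causal variant first; the CIT called every
causal trio and none of the reactive/pleiotropic/confounded ones; the DA
stage recovered the planted subpopulation exactly; and the donor-level
enrichment tied that subpopulation to the disease condition while the
interaction regression recovered the planted sign and magnitude within
sampling error. Each script writes its tables under `results/`.

A `cellink` CLI exposes the same stages (`simulate`, `qc`, `eqtl`,
`cfdr`, `coloc`, `cit run`, `da run`, `enrich quant`, `enrich
trait-assoc`, `run-all`); `cellink run-all --seed 3 --outdir out/` runs
the full chain from a YAML config and writes a manifest with per-stage
seeds and output checksums.

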