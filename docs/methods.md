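# Methods

`resqtl` implements a multi-resolution GWAS–eQTL integration pipeline:
cis-eQTL mapping of RNA-Seq expression quantified at gene, transcript,
exon, junction and intron level; Regulatory Trait Concordance (RTC)
colocalization of GWAS lead SNPs with those eQTLs inside
recombination-hotspot intervals; a mixed-model likelihood-ratio test
separating systematic from heterogeneous eQTL effects; and a local
shift-permutation test of chromatin-annotation enrichment. A synthetic
cohort generator provides the testbed for every stage. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic data does and does not emulate.

## Cis-eQTL mapping

Each SNP–target association is an ordinary least squares fit of
inverse-normal-transformed expression on allele dosage with an intercept
and covariates (by default the first three genotype principal components;
an imputation-status indicator can be supplied as an extra covariate),
with a two-sided t-test on the dosage slope. The batch scanner
residualizes both sides on the covariates once (Frisch–Waugh–Lovell) and
fits each simple regression on residuals with the full-model degrees of
freedom; this is algebraically identical to the multiple regression and
is verified against a closed-form normal-equations oracle (slope to
1e-10, P to 1e-8 relative) and against `statsmodels.OLS` in the unit
tests. Underflowing P-values are floored at the smallest positive float
so that log-space work and step-up FDR stay defined.

The GWAS-anchored scan tests a (SNP, target) pair when the SNP lies
within 100 kb of a GWAS lead and the target's TSS within ±500 kb of it;
a lead–target association is *eligible* when at least one SNP in the lead
window reaches nominal P < 0.01. Eligible lead-vs-target associations are
Bonferroni-corrected per disease and per quantification type (m = number
of such associations in the scope); the genome-wide variant of the scan
uses Benjamini–Hochberg FDR per quantification type instead.

## RTC colocalization

SNPs are assigned to the interval between the two recombination-hotspot
summits flanking the GWAS lead. A lead inside a hotspot defines both an
*upper* interval (back to the previous summit) and a *lower* interval
(forward to the next); both are scored and the maximum RTC is reported.
A lead beyond the first or last summit is bounded by the region edge and
flagged.

Within an interval of N SNPs, the best eQTL SNP is the one with the
smallest association P for the target (covariates included). For each
interval SNP k, expression is residualized on SNP k (plus covariates)
and the best eQTL SNP is re-tested against those residuals: removing a
SNP that tags the causal variant destroys the eQTL (residual P near 1),
removing an unrelated SNP leaves it intact. SNPs are ranked by
descending residual P (rank 0 = removal most destructive) and

    RTC = (N − Rank_GWAS) / N

with the 0-based rank, so RTC = 1.0 exactly when removing the GWAS lead
extinguishes the signal better than removing any other SNP. A 1-based
rank could never reach 1.0 and would make a fixed 0.95 threshold depend
pathologically on N. Tied residual P-values (1e-12 relative tolerance)
share the minimal rank of the tie group — the favourable assignment when
the GWAS SNP is in the group. Covariates enter both stages so the two
regressions share one model. An association is called a **causal
cis-eQTL** when its Bonferroni-adjusted eQTL P < 0.05 *and* RTC ≥ 0.95.

The ranking is verified against a brute-force enumeration of every
interval regression on 50 synthetic loci, and discrimination is measured
on 200 loci (half shared-causal, half with an independent causal variant
at r² < 0.3 to the lead): the RTC ≥ 0.95 call reaches sensitivity ≈ 0.9
and specificity ≈ 1.0 at n = 373 with a 0.7-SD effect.

## Heterogeneity mixed model

For a gene with T expression elements in n individuals, the
*systematic* model is

    y_st = β0 + β1·dosage_s + u_s + v_t + ε_st,
    u_s ~ N(0, σ_u²), v_t ~ N(0, σ_v²), ε ~ N(0, σ_e²)

with crossed random intercepts per individual and per element; the
*heterogeneous* model adds T − 1 fixed dosage × element interaction
terms (dosage kept on its raw 0/1/2 scale). Both are fitted by maximum
likelihood — not REML, because the likelihood-ratio test compares models
differing in fixed effects — and compared with χ² on T − 1 degrees of
freedom. Genes with one element are untestable. P-values are Bonferroni
corrected across all testable results of the run (m recomputed per run,
never a hard-coded count); p_bf < 0.05 labels the pair heterogeneous.

**Fitting.** On a complete samples × elements grid the marginal
covariance is diagonal in the Kronecker product of orthonormal bases
whose first vectors are constant, with eigenvalues
σ_e² + T·σ_u²·[j=0] + n·σ_v²·[i=0]. The profiled log-likelihood over the
two variance ratios (σ_e² profiled out) is maximised by L-BFGS-B from
four starts with non-negativity enforced on the log scale; each
evaluation is a weighted least-squares solve, so a fit costs
milliseconds. The fit reproduces `lme4::lmer(..., REML = FALSE)`
log-likelihoods to ~1e-5 (cross-checked via Rscript in the test suite),
and recovers planted variance components within ±30% (median over 50
replicates at n = 373, 8 elements). Samples missing any element are
dropped before fitting; convergence and boundary flags are attached to
every result.

**Known limitation — small element counts.** With raw-dosage
interactions the interaction columns overlap the per-element intercept
directions, and with only a handful of elements the element-intercept
variance is estimated from very few draws; the heterogeneous model can
then absorb part of the realized intercepts, inflating the LRT. Measured
null rejection at α = 0.05 is ≈ 0.08–0.12 for T = 4 elements at n = 200,
decaying to ≈ 0.05 by T = 8 or n ≈ 1000. Centered-dosage interactions or
fixed element main effects reduce but do not remove the effect at T = 4.
Heterogeneity calls on genes with few elements should therefore be read
as anticonservative at the margin; the Bonferroni correction applied in
the pipeline pushes decisions far from the nominal 5% boundary, where
the inflation is immaterial.

## Shift-permutation enrichment

Each causal SNP is expanded to all panel SNPs with r² > 0.8 against it
(genotypic correlation on dosages). The observed statistic is the
proportion of loci with at least one LD-set SNP inside an annotation
interval (point in 0-based half-open interval). The null keeps SNPs
fixed and circularly shifts the annotation intervals inside each locus
window — the LD span padded by the largest annotation width — by one
uniform offset per locus per permutation, with an independent random
substream per locus so loci stay decoupled. The P-value is the
proportion of permutations with overlap ≥ observed; the
(k + 1)/(n + 1) estimate is also reported for users needing a nonzero
bound, but the proportion definition drives significance. Because ties
between the observed and permuted counts are counted in the numerator,
the P-value is conservatively biased when few loci are tested; the null
calibration check therefore uses hundreds of loci with mid-range overlap
probability, where the achievable grid is dense. NarrowPeak inputs can
be pre-filtered on their q-value column (e.g. ≥ 2 for FDR ≤ 0.01) and
harmonized to fixed 200-bp intervals centred on the peak summit (missing
summits fall back to the interval midpoint, flagged; intervals near the
chromosome start are shifted to keep their length).

## Quality control and normalization

* **SNPs**: MAF > 0.05 (strict), exact-test Hardy–Weinberg P > 1e-4 on
  hard-call counts (fractional dosages rounded for the test only; the
  Levene–Haldane exact test without mid-P, matching common practice),
  call rate ≥ 0.7. Exclusions are tallied per filter; an empty result
  warns rather than raises.
* **Expression**: targets detected (nonzero) in strictly more than 50%
  of individuals are kept; each surviving target is mapped to standard
  normal by the rank-based transform Φ⁻¹((rank − 0.5)/n) with average
  ranks for ties. The 0.5/n offset is one documented choice among the
  admissible monotone variants.
* **Covariates**: principal components of the standardized dosage matrix
  (SVD), sign fixed by making each component's largest-magnitude loading
  positive; the SNP subset is configurable (a single-chromosome subset
  mirrors common practice; the default uses all QC-passing SNPs).
* **Lead pruning**: greedy scan over position-sorted leads with a 100-kb
  window and r² > 0.8; within a conflicting pair the smaller GWAS P is
  retained (ties: leftmost). A P-based retention rule is used because
  PLINK's own missingness-based rule is meaningless for lead lists; the
  rule is documented so locus counts are reproducible.

## Synthetic cohort generator

The generator emulates a Geuvadis-style LCL cohort (a few hundred
individuals, block-LD common variants, PEER-residualized expression) so
that every stage has a ground truth:

* **Genotypes** — exchangeable-copy haplotypes: each block has a core
  allele per haplotype and every SNP copies it with probability √r, so
  same-frequency SNPs have pairwise genotype correlation ≈ r; blocks are
  independent. Within a block, allele frequencies are a single base
  frequency plus jitter scaled by (1 − r), because binary variables with
  very different frequencies cannot reach high phi correlation — true of
  real LD blocks as well. Genotype frequencies are HWE-consistent by
  construction; dosages are hard calls.
* **Expression** — emitted already residualized (≈ standard normal), as
  the pipeline consumes PEER residuals; latent-factor estimation is not
  modelled. Transcript signal is primary: a gene's value is the exact
  sum of its transcript values before noise; exons and junctions inherit
  the summed signal of the transcripts containing them; introns vary
  independently. Residual structure is crossed Gaussian intercepts (per
  sample within gene, sd 0.3; per element, sd 0.3) plus i.i.d. noise
  (sd 1). These variance defaults are calibration choices for a
  residualized cohort, not published values.
* **Planted eQTLs** — systematic truths add β·dosage to every transcript
  and intron (derived elements inherit); heterogeneous truths add the
  effect directly to an explicit element subset, modelling
  element-specific regulation that does not propagate to the gene total.
  Under a null truth the SNP–target P-values are uniform, and planted
  slopes are recovered by OLS within 3 SE at n = 373 (tested).
* **Study bundles** — `simulate_study` lays one LD block per locus along
  a chromosome, a hotspot summit at every block boundary (each locus is
  one hotspot interval), one gene per locus with its TSS at the locus
  centre, and a GWAS lead at each block's central SNP; a chosen subset
  of loci carries the eQTL at the lead itself (shared-causal
  architecture). Annotation tracks can be enriched by centring a stated
  fraction of intervals within 1 kb of the causal SNPs, close enough to
  guarantee overlap.

What the generator does **not** emulate: read-level sampling,
library-size/RPKM scale, population structure beyond optional divergent
subpopulations, haplotype-panel LD decay (block correlation is
exchangeable, not distance-decaying), or missing genotypes/expression
unless injected. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to
real-data artefacts such as unmodelled confounders or quantification
error.

## Problem sizes and determinism

The verification suite and `scripts/acceptance.py` use desk-scale sizes
chosen to keep the whole run in minutes on one CPU while preserving the
study's sampling regime: 100 random OLS fixtures; 50 brute-force RTC
loci (n = 150); 200 discrimination loci at n = 373; 500 null LRT fits
(4 elements, n = 200) and 100 power replicates at n = 373; 200
permutation-null runs of 300 single-SNP loci at 300 permutations, plus
one planted-enrichment run at 1000 permutations. All randomness flows
through explicit seeds (the CLI and acceptance script derive per-stage
substreams from one `--seed`); a fixed seed reproduces every output
table byte for byte.
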