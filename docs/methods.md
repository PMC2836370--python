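# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `methcna`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A cohort consists of a β matrix (CpG loci × samples, methylation
fractions in [0,1]), an integer copy-number-state matrix (SNP loci ×
tumors, diploid = 2), BED-like locus annotations (0-based coordinates
internally, half-open; chromosome, position, gene, upstream-of-TSS flag
for CpGs), sample metadata, and a LINE-1 pyrosequencing table. Missing
values are written as `NA`, kept as NaN, and handled by
pairwise-complete deletion everywhere; nothing is imputed, because no
principled imputation rule exists for these assays at this cohort size.

β is computed from methylated/unmethylated fluorescence as
β = max(M, 0) / (|U| + |M| + 100). The +100 offset regularizes
low-intensity probes and the clamp/absolute values absorb
background-subtracted negative signals; the estimate is bounded in
[0, 1) and monotone in M.

## Copy-number HMM

States s ∈ {0,…,4} emit log2 ratios N(log2(max(s, 0.5)/2), σ). The 0.5
floor keeps the homozygous-deletion mean finite (standard practice for
log-ratio models). Transitions keep the current state with probability
p_stay (default 0.98) and spread the remainder uniformly over the other
four states — the simplest defensible transition model; a
distance-decayed alternative would need parameters the data here cannot
identify. Defaults σ = 0.2, uniform initial distribution. Chromosomes
are decoded independently by Viterbi; ties in the dynamic program are
broken toward the state closer to diploid, then the lower state, so
decoding is deterministic. No pre-smoothing of ratios is applied;
per-tumor median-centering is available but off by default. Per-tumor
burden is mean |CNS − 2| over observed loci: 0 iff fully diploid, ≤ 2
for this state space.

## RPMM methylation classing

Each node of a binary tree models its samples with a 2-component
mixture; component k has independent Beta(a_jk, b_jk) emissions per CpG
j. Samples enter a node with a weight (the product of responsibilities
along the path) and the node's EM maximizes the weighted observed-data
log-likelihood.

Numerics:

* β is clamped to [1e-6, 1−1e-6] (the beta log-likelihood diverges at
  the endpoints).
* Weighted beta MLEs solve the digamma score equations by damped Newton
  steps in (a, b) from a weighted method-of-moments start; steps are
  bounded multiplicatively (×10 per iteration) so parameters stay
  positive, and the solver falls back to the moments estimate if Newton
  leaves [1e-4, 1e4].
* EM initialization: the first restart splits samples at the weighted
  median of the first principal component of the logit-β profiles
  (deterministic and order-invariant); four further restarts use random
  Dirichlet responsibilities; the best final likelihood wins. Node
  seeds derive from the root seed plus the node's tree path, so subtree
  refits reproduce.
* A split is accepted iff BIC(2 components) < BIC(1 component) at the
  node — the penalty counts 2 parameters per CpG per extra component
  plus one mixing weight, with n = the node's effective (weighted)
  sample size — and both children keep effective weight ≥
  min_node_weight (default 2). Maximum depth 3.
* Leaves are numbered left to right; "left" is canonically the child
  with the smaller fitted mean methylation. Hard class labels are
  argmax leaf weights; the root-side label (left/right grouping used by
  the stratified analyses) is the argmax of the root responsibilities,
  ties to the left.

A consequence worth stating: because the BIC penalty scales with the
total CpG count while the likelihood gain scales with the number of
CpGs that actually discriminate a split, a split at n samples is
accepted only when roughly (ln n / gain-per-sample-per-CpG) × p CpGs
discriminate it — at 19 tumors and 1,500 CpGs that is on the order of
10% of the panel per split. Small cohorts therefore support only the
top of the class hierarchy (typically the root split), which is why
classing at scale was historically done on larger cohorts and carried
over. The recovery tests run 4-class cohorts at 40 samples, 200 CpGs
and beta precision 100, where all three splits are decisively
BIC-favored.

## Global association test

Kruskal–Wallis H on per-tumor burden grouped by class, midrank ties
correction, with p from permuting class labels over tumors (equivalent
to permuting burden under exchangeability; label permutation keeps the
bookkeeping trivial). The add-one estimator
p = (1 + #{H_perm ≥ H_obs}) / (n_perm + 1) never returns 0; with the
default 10,000 permutations the resolution floor is ≈ 1e-4. Covariate
checks mirror the companion clinical analysis: Fisher exact for
dichotomized stage (I/II vs III/IV) and HPV16, Monte-Carlo Fisher
(fixed-margin table sampling, default 100,000 draws) for the
multi-level site variable, Wilcoxon rank-sum for age.

## Local correlation screen

Each CpG is matched to the nearest same-chromosome SNP (ties to the
lower coordinate; no distance cutoff by default, and unmatched CpGs are
reported with a reason). Gene-level units average β over the gene's
upstream-of-TSS CpGs and copy-number states over the gene's SNPs; genes
lacking promoter CpGs or SNPs are excluded with a flag. Per unit the
tumor-level Pearson r is tested two-sided via |r| with 5,000
permutations of the methylation vector (copy number held fixed); one
permutation schedule is shared across units per run so results are
seed-stable and comparable between units. Pearson rather than a rank
correlation because the copy-number side is a discrete state average.
Units with fewer than 3 complete pairs or zero variance are excluded
with flags.

Storey q-values: π₀ is estimated on the grid λ = 0.05…0.95 (step 0.05)
as #{p > λ}/(m(1−λ)), a cubic polynomial is fit over the grid and
evaluated at λ → 1, and the estimate is clamped to [1/m, 1]; q is the
step-up minimum of π₀·m·p/rank, monotone in p. With fewer than 10
p-values π₀ falls back to 1, which makes q exactly Benjamini–Hochberg.

## Alteration tests

Welch (unequal-variance, Satterthwaite df) two-sample t for tumor vs
normal methylation per unit; one-sample t against 2 for gene copy
number. Zero-variance units: equal means give t = 0, p = 1; unequal
means with zero variance are excluded as degenerate rather than
assigned p = 0. One multiple-testing family per (alteration type ×
stratum) — the narrowest defensible family definition, since the
q < 0.05 rule is applied per analysis. Strata are {all, left, right}
from the root split; strata with fewer than 2 tumors are skipped.

## Clustering and LINE-1

Hamming distance between tumors counts loci with differing integer
states, pairwise-complete and rescaled to the full locus count so pairs
with missing data remain comparable. Ward clustering applies the
Lance–Williams recurrence to squared input distances and reports
heights on the original scale (the "ward.D2" convention; the raw-
distance "ward.D" variant is available behind a flag). Tie-breaking
picks the smallest pair of cluster indices, making the merge sequence
deterministic. The high/low CNA grouping cuts the tumor dendrogram into
two clusters and labels the one with larger mean burden "high"; an
exact tie labels the larger cluster "low" with a warning. The LINE-1
comparison is mean(high) − mean(low) in percentage points with a Welch
95% CI; a group with fewer than 2 values yields a point estimate only.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: 19 tumors
+ 11 normals, 1,500 CpGs over 800 genes, 5,000 autosomal SNP loci
(a reduced-scale stand-in for a 500k array), K = 5 latent classes.
Defaults are the study conditions; the important ones, with rationale:

* **Class structure.** A fraction (default 0.2) of CpGs is
  class-informative. At each such CpG the K class means are laid out by
  recursive bisection of [0.15, 0.85]: the contiguous super-groups
  {1..⌈K/2⌉} and the rest occupy the outer 35% of their interval and
  each half is subdivided the same way. Every informative CpG therefore
  separates every level of a nested class hierarchy — the structure a
  recursive splitter should find — and super-group separation dominates
  within-group separation. Orientation flips at random per CpG (so
  classes are not globally ordered by mean methylation). Emissions are
  Beta with (mean, precision) parameterization, precision 30 (β sd
  ≈ 0.08 at mean 0.5, a realistic array-replicate spread).
* **Normals** draw per-CpG means from Beta(2, 6) (mostly unmethylated
  promoters); 20% of CpGs are differentially methylated in tumors by
  ±0.25, giving the tumor-vs-normal tests true positives.
* **Copy number.** Per chromosome, segments of geometric length (mean
  50 loci — both focal and arm-scale events arise; the alteration-size
  distribution is a modeling choice, not a claim about any dataset);
  a segment is altered with probability chosen so the expected burden
  matches the class's target, scaled by the coupling κ ∈ [0, 1]
  (κ = 0 ⇒ identical burden law across classes; infeasible targets
  > 1.3 per altered locus raise an error). Altered states come from
  {0,1,3,4} with probabilities {0.15,0.35,0.35,0.15}. Default targets
  put two classes at burden 0.5 and three at 0.05. A share (default
  0.6) of each tumor's alteration budget comes from a recurrent-segment
  template shared by all tumors on the same burden tier — recurrent
  arm-level events are a property of the unstable phenotype — so
  same-tier tumors resemble each other in Hamming distance without
  being identical. Normals are diploid everywhere (tumors are assumed
  normalized against matched blood).
* **Local coupling.** `plant_local_coupling` draws a tumor-level latent
  normal variable per gene, discretizes it into states 0–4 for the
  gene's SNPs, and sets the gene's promoter-CpG β to
  0.5 + A(sgn·ρ·z + √(1−ρ²)·ε) (A = 0.18), giving an expected
  gene-level Pearson correlation of target sign and ≈ magnitude.
  target_r = 0 is a no-op.
* **LINE-1.** Eleven of the tumors carry pyrosequencing values: three
  replicates of four CpGs, N(group mean, 8), with group means 52%
  (high-burden tier) and 65.2% (low) — a planted difference of −13.2
  percentage points.
* **Metadata** frequencies (sex, site, stage, HPV16, age) mirror a
  typical head-and-neck case series.

What the generator does **not** model: tumor purity/stromal dilution,
bead-level replicate noise, copy-number bias of β measurements,
CNV polymorphism in normals, chromosome-arm boundary effects, and any
dependence of methylation class on clinical covariates. Passing tests
therefore demonstrate that the statistical machinery recovers planted
structure under clean assay noise, not that it would under these
real-data complications.

## Operating characteristics and problem sizes

The reference experiments (`methcna.experiments`) use scales chosen so
the whole battery runs in about a minute while keeping every Monte-Carlo
estimate's standard error well inside the margins being checked:

* Headline global test: one cohort, 5,000 SNP loci, 10,000
  permutations.
* Null calibration: 1,000 cohorts at 500 SNP loci with κ = 0 and 499
  permutations each (rejection at p ≤ 0.05 has null probability
  exactly 25/500 absent ties).
* Local-screen specificity/power: 12 cohorts × 200 genes at 5,000 SNP
  loci and 5,000 permutations; specificity cohorts use fully private
  alterations (recurrent share 0), because tier-shared recurrent
  segments consistently alter the same genes in high-burden classes —
  that is a local mechanism, and including it would conflate genuine
  couplings with leakage of the global association. Power cohorts plant
  10 genes at r = 0.95.
* RPMM recovery: three 4-class cohorts (40 samples, 200 CpGs,
  precision 100). HMM accuracy: one 19 × 5,000 cohort at σ = 0.2.
  LINE-1 CI coverage: 2,000 Welch replicates at n = (6, 5), sd 8.

## Known limitations

* The RPMM here fits fresh on each cohort; it does not reproduce any
  particular published class solution, and at 19 samples the BIC rule
  yields coarse (usually 2-class) solutions by design.
* The 5-state HMM is a generic stand-in for vendor copy-number callers;
  it has no genotype information, no transition decay, and no
  pre-smoothing, so its calls are not comparable to any specific
  commercial pipeline.
* Storey's π₀ estimate is noisy below a few hundred p-values; under
  strong inter-unit dependence (genes sharing an altered segment) the
  realized false-discovery proportion fluctuates in bursts even though
  the estimator is marginally calibrated.
* Permutation p-values have resolution 1/(n_perm + 1); q-value
  thresholds near that floor are quantized accordingly.
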