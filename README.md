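# methcna

Integrative analysis of DNA-methylation classes and copy-number
alteration (CNA) burden in small tumor cohorts, with a synthetic-cohort
generator that carries full ground truth.

## The scientific question

In many solid tumors (the motivating setting is head and neck squamous
cell carcinoma), promoter CpG hypermethylation and chromosomal
copy-number alteration are the two major somatic routes to gene
dysregulation. Two competing pictures exist:

* **local "two-hit" targeting** — the same gene loses one allele and is
  silenced by methylation of the remaining promoter, so methylation and
  copy number should correlate gene by gene;
* **global coordination** — tumors with aberrant methylation *profiles*
  also tend to carry more allelic imbalance genome-wide, without any
  gene-level coupling.

This package implements the statistical machinery to distinguish the
two on a cohort of tumors profiled for methylation (β values at ~1,500
promoter CpGs) and copy number (integer states at thousands of SNP
loci), plus matched normal tissues and LINE-1 pyrosequencing as a
global-methylation surrogate:

* **β preprocessing** — β = max(M, 0) / (|U| + |M| + 100) from
  methylated/unmethylated fluorescence, and two-level LINE-1 averaging
  (4 CpGs per replicate, mean over replicates).
* **Copy-number states** — a 5-state Gaussian HMM over log2
  tumor/normal ratios (states 0–4, emission means log2(max(s,½)/2)),
  decoded by Viterbi per chromosome; per-tumor burden = mean |CNS − 2|.
* **Methylation classes** — a recursively partitioned beta-mixture
  model (RPMM): recursive 2-component weighted EM with per-CpG
  Beta(a, b) emissions, split acceptance by BIC; leaves are methylation
  classes and the root split defines the left/right class groups.
* **Global test** — Kruskal–Wallis H of burden across classes with a
  10,000-iteration label-permutation p-value.
* **Local screen** — each CpG matched to its nearest same-chromosome
  SNP; Pearson r per locus and per promoter-averaged gene, two-sided
  permutation p (5,000 permutations), Storey q-values
  (cubic-smoother π₀ estimate), significance at q < 0.05.
* **Alteration tests** — Welch t (tumor vs normal methylation) and
  one-sample t (gene copy number vs 2), overall and stratified by the
  left/right grouping, as volcano tables.
* **Grouping & LINE-1** — Ward clustering of tumors on Hamming
  distances between state profiles ("ward.D2" Lance–Williams update),
  high/low CNA dichotomization by the 2-cut, and the high-minus-low
  LINE-1 difference with a Welch 95% CI.

The generator (`methcna.simulate`) plants all of this structure — K
latent classes on a nested beta-mean grid, class-coupled segmental CNA
with tier-shared recurrent events, optional gene-level "two-hit"
couplings at a target correlation, LINE-1 group means — and records the
truth, so every stage can be validated by recovery.

## Worked example

The numbered scripts under `analysis/` run the full story on the
reference cohort (seed 1); each prints its findings and writes tables
under `results/`. For example:

```
$ python analysis/04_global_association.py
planted classes: H = 15.008, permutation p = 0.0001 (10000 permutations, 5000 SNP loci)
fitted RPMM classes: H = 10.176, permutation p = 0.0009
```

Burden differs strongly by methylation class: the observed H sits far
in the tail of the label-permutation distribution (p ≈ 1e-4 with the
planted 5-class labels, p ≈ 9e-4 with the RPMM-fitted grouping — both
comfortably below the p < 0.002 benchmark for this design).

```
$ python analysis/05_local_correlation.py
1500 of 1500 CpGs matched to a same-chromosome SNP (median distance 3332 bp)
101 units at q < 0.05 (10/10 planted genes recovered; 32 non-planted genes flagged)
```

All ten genes planted at r = 0.95 are recovered; the extra hits are
genes inside recurrent alteration segments whose promoter CpGs are
class-informative — genuine couplings created by the generator, not
false positives.

```
$ python analysis/07_cna_groups_line1.py
high/low CNA groups: {'low': 11, 'high': 8}
LINE-1 difference (high - low): -12.0 percentage points, 95% CI (-16.5, -7.6); n = 2 high, 9 low
```

Tumors in the high-CNA cluster are globally hypomethylated relative to
the low-CNA cluster, as planted (−13.2 points between group means).

`analysis/08_operating_characteristics.py` measures the method's
operating characteristics over many seeded cohorts: type-I error of the
global test ≈ 0.057 at nominal 0.05, local-screen false-positive rate
≈ 0% under pure global coupling with power 100% at r = 0.95, RPMM
adjusted Rand index 1.0 on well-separated 4-class cohorts, HMM state
accuracy 99.9%, LINE-1 CI coverage ≈ 96%.

A `methcna` command-line interface wraps the same stages
(`methcna simulate|beta|hmm|rpmm|global-test|local-corr|alteration|cluster|run-all`).

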