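"""Synthetic tumor cohorts with the joint methylation/copy-number
structure the analysis assumes.

The generator emulates a small head-and-neck-style case series: 19 tumors
and 11 normal tissues measured at ~1,500 promoter-region CpGs (beta
values) across ~800 genes, and tumors additionally profiled at several
thousand autosomal SNP loci for integer copy-number states (the real
platform has 500k loci; the default here is a reduced-scale 5,000).

Structure planted by the generator:

* K latent methylation classes. At every class-informative CpG the K
  class means are laid out by recursive bisection of the interval
  [class_mean_low, class_mean_high]: the contiguous super-groups
  {1..ceil(K/2)} vs the rest sit in the outer thirds of the interval and
  each half is subdivided the same way, so the class hierarchy is nested
  — exactly the structure the recursive root split should find — and
  every informative CpG separates every level. Orientation is flipped at
  random per CpG. Beta emissions use a (mean, precision)
  parameterization.
* Normals draw from a separate "normal epithelium" beta law; a fraction
  of CpGs is differentially methylated in tumors.
* Copy-number profiles are segmental: per chromosome, segments of
  geometric length (mean 50 loci) are altered with a probability chosen
  so the expected burden mean|CNS-2| matches the class's target, scaled
  by the global coupling kappa. Altered segments draw states from
  {0,1,3,4} with probabilities {0.15,0.35,0.35,0.15}; normals are diploid
  everywhere. kappa=0 makes burden identical in law across classes.
  A share of each tumor's alteration budget (``recurrent_share``) comes
  from a class-level template of recurrent segments, mimicking the
  recurrent arm-level events of real tumors; the rest is private, so
  same-class tumors resemble each other without being identical.
* Optional locally coupled ("two-hit") genes: a tumor-level latent
  variable shifts both a gene's promoter methylation and its SNP states
  to a target Pearson correlation.
* LINE-1 percent methylation drawn around a group mean determined by the
  tumor's burden tier (high burden -> hypomethylated), three replicates
  of four CpGs each.

Everything planted is recorded in :class:`SimulationTruth`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stage_rng

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Cohort",
    "simulate_cohort",
    "plant_local_coupling",
    "synthesize_signals",
]

ALTERED_STATES = np.array([0, 1, 3, 4])
ALTERED_PROBS = np.array([0.15, 0.35, 0.35, 0.15])
#: expected |state-2| over an altered locus
ALTERED_MEAN_DEV = float(np.abs(ALTERED_STATES - 2) @ ALTERED_PROBS)  # 1.3


@dataclasses.dataclass
class SimulationConfig:
    n_tumors: int = 19
    n_normals: int = 11
    n_cpg: int = 1500
    n_genes: int = 800
    n_snp: int = 5000
    n_chromosomes: int = 22
    n_classes: int = 5
    informative_fraction: float = 0.2
    class_mean_low: float = 0.15
    class_mean_high: float = 0.85
    beta_precision: float = 30.0
    #: per-class expected burden targets (length n_classes); default puts
    #: two classes on a high tier (0.5) and the rest on a low tier (0.05)
    class_burden_targets: Sequence[float] | None = None
    kappa: float = 1.0
    segment_mean_len: float = 50.0
    recurrent_share: float = 0.6
    log_ratio_sd: float = 0.2
    frac_differential: float = 0.2
    differential_shift: float = 0.25
    line1_mean_high: float = 52.0
    line1_mean_low: float = 65.2
    line1_sd: float = 8.0
    n_line1: int = 11
    line1_replicates: int = 3
    seed: int = 0

    def resolved_burden_targets(self) -> np.ndarray:
        if self.class_burden_targets is None:
            t = np.full(self.n_classes, 0.05)
            t[: min(2, self.n_classes)] = 0.5
        else:
            t = np.asarray(self.class_burden_targets, dtype=float)
            if t.size != self.n_classes:
                raise ValueError("class_burden_targets length must equal n_classes")
        return t

    def validate(self) -> "SimulationConfig":
        if self.n_cpg < self.n_genes:
            raise ValueError("n_cpg must be >= n_genes")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must be in [0,1]")
        t = self.resolved_burden_targets()
        mean_t = t.mean()
        effective = mean_t + self.kappa * (t - mean_t)
        if np.any(effective / ALTERED_MEAN_DEV > 1.0):
            raise ValueError(
                "infeasible coupling: burden target exceeds the maximum "
                f"achievable ({ALTERED_MEAN_DEV}) with states 0..4"
            )
        return self


@dataclasses.dataclass
class SimulationTruth:
    class_labels: pd.Series  # tumors -> 1..K
    true_burden: pd.Series  # recomputed from the emitted state matrix
    burden_targets: np.ndarray  # per-class kappa-scaled expected burden
    segments: pd.DataFrame  # tumor, chrom, start_idx, end_idx, state
    coupled_genes: pd.DataFrame  # gene, target_r
    line1_group_means: dict
    line1_groups: pd.Series  # tumor -> "high"/"low" burden tier
    class_mean_matrix: pd.DataFrame  # informative CpG x class beta means


@dataclasses.dataclass
class Cohort:
    beta: pd.DataFrame  # CpG loci x (tumors + normals)
    cn_states: pd.DataFrame  # SNP loci x tumors (integer states)
    log_ratios: pd.DataFrame  # SNP loci x tumors
    cpg_annotation: pd.DataFrame
    snp_annotation: pd.DataFrame
    metadata: pd.DataFrame  # sample x (group, age, sex, site, stage, hpv16)
    line1: pd.DataFrame  # long replicate table
    truth: SimulationTruth

    @property
    def tumors(self) -> pd.Index:
        return self.metadata.index[self.metadata["group"] == "tumor"]

    @property
    def normals(self) -> pd.Index:
        return self.metadata.index[self.metadata["group"] == "normal"]


def _beta_draw(rng, mean, precision, size=None):
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    a = mean * precision
    b = (1.0 - mean) * precision
    return rng.beta(a, b, size=size)


def _nested_grid(K: int, lo: float, hi: float) -> np.ndarray:
    """Class means by recursive bisection: halves occupy the outer 35% of
    their interval, so super-group separation dominates within-group."""
    out = np.empty(K)

    def fill(classes, a, b):
        if len(classes) == 1:
            out[classes[0]] = (a + b) / 2.0
            return
        half = int(np.ceil(len(classes) / 2))
        span = b - a
        fill(classes[:half], a, a + 0.35 * span)
        fill(classes[half:], b - 0.35 * span, b)

    fill(list(range(K)), lo, hi)
    return out


def _make_annotations(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    chroms = [f"chr{i+1}" for i in range(cfg.n_chromosomes)]
    gene_chrom = rng.integers(0, cfg.n_chromosomes, size=cfg.n_genes)
    tss = rng.integers(1_000_000, 99_000_000, size=cfg.n_genes)
    strand = rng.choice([1, -1], size=cfg.n_genes)
    genes = pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in range(cfg.n_genes)],
            "chrom": [chroms[c] for c in gene_chrom],
            "tss": tss,
            "strand": strand,
        }
    )

    # CpGs: every gene gets one, extras go to random genes; ~80% upstream
    owner = np.concatenate(
        [np.arange(cfg.n_genes), rng.integers(0, cfg.n_genes, size=cfg.n_cpg - cfg.n_genes)]
    )
    upstream = rng.random(cfg.n_cpg) < 0.8
    offset = rng.integers(100, 1500, size=cfg.n_cpg)
    sign = np.where(upstream, -1, 1) * genes["strand"].to_numpy()[owner]
    coord = np.maximum(genes["tss"].to_numpy()[owner] + sign * offset, 0)
    cpg_annot = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy()[owner],
            "start": coord,
            "locus": [f"cg{i:05d}" for i in range(cfg.n_cpg)],
            "gene": genes["gene"].to_numpy()[owner],
            "upstream": upstream.astype(float),
        }
    )

    # SNPs: 1 + Poisson(1) per gene near the TSS, remainder intergenic
    per_gene = 1 + rng.poisson(1.0, size=cfg.n_genes)
    total_gene_snps = int(per_gene.sum())
    if total_gene_snps > cfg.n_snp:
        per_gene = np.ones(cfg.n_genes, dtype=int)
        total_gene_snps = cfg.n_genes
    owner_snp = np.repeat(np.arange(cfg.n_genes), per_gene)
    snp_coord = genes["tss"].to_numpy()[owner_snp] + rng.integers(
        -10_000, 10_000, size=total_gene_snps
    )
    n_inter = cfg.n_snp - total_gene_snps
    inter_chrom = rng.integers(0, cfg.n_chromosomes, size=n_inter)
    snp_annot = pd.DataFrame(
        {
            "chrom": np.concatenate(
                [genes["chrom"].to_numpy()[owner_snp],
                 np.array(chroms)[inter_chrom]]
            ),
            "start": np.concatenate(
                [np.maximum(snp_coord, 0),
                 rng.integers(0, 100_000_000, size=n_inter)]
            ),
            "gene": np.concatenate(
                [genes["gene"].to_numpy()[owner_snp],
                 np.full(n_inter, None)]
            ),
        }
    )
    snp_annot = snp_annot.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    snp_annot["locus"] = [f"snp{i:05d}" for i in range(len(snp_annot))]
    snp_annot["upstream"] = np.nan
    snp_annot = snp_annot[["chrom", "start", "locus", "gene", "upstream"]]
    cpg_annot = cpg_annot.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return cpg_annot, snp_annot


def _simulate_cn(cfg, rng, snp_annot, burden_target):
    """Segmental states for one tumor across all chromosomes."""
    rho = burden_target / ALTERED_MEAN_DEV
    states = np.full(len(snp_annot), 2, dtype=int)
    segs = []
    for chrom, idx in snp_annot.groupby("chrom", sort=False).groups.items():
        n = len(idx)
        pos = 0
        while pos < n:
            length = min(n - pos, rng.geometric(1.0 / cfg.segment_mean_len))
            if rng.random() < rho:
                s = int(rng.choice(ALTERED_STATES, p=ALTERED_PROBS))
            else:
                s = 2
            states[idx[pos : pos + length]] = s
            if s != 2:
                segs.append((chrom, pos, pos + length, s))
            pos += length
    return states, segs


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate one full synthetic cohort with ground truth."""
    cfg.validate()
    rng_annot = stage_rng(cfg.seed, "simulate/annotation")
    rng_meth = stage_rng(cfg.seed, "simulate/methylation")
    rng_cn = stage_rng(cfg.seed, "simulate/copy_number")
    rng_meta = stage_rng(cfg.seed, "simulate/metadata")
    rng_line1 = stage_rng(cfg.seed, "simulate/line1")

    tumors = [f"T{i+1:02d}" for i in range(cfg.n_tumors)]
    normals = [f"N{i+1:02d}" for i in range(cfg.n_normals)]
    cpg_annot, snp_annot = _make_annotations(cfg, rng_annot)
    K = cfg.n_classes

    # --- class labels: balanced sizes, shuffled assignment
    labels = np.array([(i % K) + 1 for i in range(cfg.n_tumors)])
    rng_meth.shuffle(labels)
    class_labels = pd.Series(labels, index=tumors, name="class")

    # --- methylation
    n_inf = int(round(cfg.informative_fraction * cfg.n_cpg))
    inf_idx = rng_meth.choice(cfg.n_cpg, size=n_inf, replace=False)

    normal_mean = rng_meth.beta(2.0, 6.0, size=cfg.n_cpg)
    tumor_base_mean = normal_mean.copy()
    is_dm = rng_meth.random(cfg.n_cpg) < cfg.frac_differential
    shift_sign = rng_meth.choice([-1.0, 1.0], size=cfg.n_cpg)
    tumor_base_mean = np.clip(
        tumor_base_mean + is_dm * shift_sign * cfg.differential_shift, 0.02, 0.98
    )

    # per-CpG per-class means: base for uninformative; for informative
    # CpGs an evenly spaced grid over classes, randomly oriented
    class_means = np.tile(tumor_base_mean[:, None], (1, K))
    grid = _nested_grid(K, cfg.class_mean_low, cfg.class_mean_high)
    flip = rng_meth.random(n_inf) < 0.5
    for j, cpg in enumerate(inf_idx):
        class_means[cpg, :] = grid[::-1] if flip[j] else grid

    beta_t = np.empty((cfg.n_cpg, cfg.n_tumors))
    for s, t in enumerate(tumors):
        k = class_labels[t] - 1
        beta_t[:, s] = _beta_draw(rng_meth, class_means[:, k], cfg.beta_precision)
    beta_n = np.empty((cfg.n_cpg, cfg.n_normals))
    for s in range(cfg.n_normals):
        beta_n[:, s] = _beta_draw(rng_meth, normal_mean, cfg.beta_precision)
    beta = pd.DataFrame(
        np.concatenate([beta_t, beta_n], axis=1),
        index=cpg_annot["locus"].to_numpy(),
        columns=tumors + normals,
    )
    # annotations were sorted by coordinate; align beta row order to them
    beta = beta.loc[cpg_annot["locus"]]

    # --- copy number
    targets = cfg.resolved_burden_targets()
    mean_t = targets.mean()
    eff_targets = mean_t + cfg.kappa * (targets - mean_t)
    states = np.empty((len(snp_annot), cfg.n_tumors), dtype=int)
    seg_rows = []
    share = cfg.recurrent_share
    # one recurrent-segment template per burden tier: instability-driven
    # recurrent events are a property of the CNA phenotype, so classes on
    # the same tier share them
    templates = {}
    for k in range(K):
        tier_key = round(float(eff_targets[k]), 12)
        if tier_key not in templates:
            templates[tier_key], segs = _simulate_cn(
                cfg, rng_cn, snp_annot, share * eff_targets[k]
            )
            for chrom, a, b, st in segs:
                seg_rows.append((f"tier-{tier_key}-template", chrom, a, b, st))
    for s, t in enumerate(tumors):
        k = class_labels[t] - 1
        private, segs = _simulate_cn(cfg, rng_cn, snp_annot,
                                     (1.0 - share) * eff_targets[k])
        combined = np.where(private != 2, private,
                            templates[round(float(eff_targets[k]), 12)])
        states[:, s] = combined
        for chrom, a, b, st in segs:
            seg_rows.append((t, chrom, a, b, st))
    cn = pd.DataFrame(states, index=snp_annot["locus"].to_numpy(), columns=tumors)
    log_ratios = pd.DataFrame(
        np.log2(np.maximum(states, 0.5) / 2.0)
        + rng_cn.normal(0.0, cfg.log_ratio_sd, size=states.shape),
        index=cn.index,
        columns=tumors,
    )

    # --- metadata (frequencies mirror the cohort being emulated)
    ages_t = np.clip(np.round(rng_meta.normal(59, 15.1, cfg.n_tumors)), 25, 85)
    ages_n = np.clip(np.round(rng_meta.normal(55, 12, cfg.n_normals)), 25, 85)
    sites = ["oral", "pharynx", "larynx"]
    meta = pd.DataFrame(
        {
            "group": ["tumor"] * cfg.n_tumors + ["normal"] * cfg.n_normals,
            "age": np.concatenate([ages_t, ages_n]),
            "sex": rng_meta.choice(["M", "F"], p=[0.79, 0.21],
                                   size=cfg.n_tumors + cfg.n_normals),
            "site": rng_meta.choice(sites, p=[0.79, 0.105, 0.105],
                                    size=cfg.n_tumors + cfg.n_normals),
            "stage": list(
                rng_meta.choice(["I", "II", "III", "IV"],
                                p=[0.11, 0.11, 0.28, 0.50], size=cfg.n_tumors)
            ) + [""] * cfg.n_normals,
            "hpv16": np.concatenate(
                [(rng_meta.random(cfg.n_tumors) < 0.16).astype(int),
                 np.zeros(cfg.n_normals, dtype=int)]
            ),
        },
        index=tumors + normals,
    )
    meta.index.name = "sample"

    # --- LINE-1, coupled to the burden tier
    tier_cut = 0.5 * (eff_targets.min() + eff_targets.max())
    tier = pd.Series(
        np.where(eff_targets[class_labels.to_numpy() - 1] > tier_cut,
                 "high", "low"),
        index=tumors,
        name="line1_group",
    )
    chosen = list(rng_line1.choice(tumors, size=min(cfg.n_line1, cfg.n_tumors),
                                   replace=False))
    line1_rows = []
    for t in chosen:
        mu = cfg.line1_mean_high if tier[t] == "high" else cfg.line1_mean_low
        for rep in range(1, cfg.line1_replicates + 1):
            vals = np.clip(rng_line1.normal(mu, cfg.line1_sd, size=4), 0, 100)
            line1_rows.append([t, rep, *vals])
    line1 = pd.DataFrame(
        line1_rows, columns=["sample", "replicate", "cpg1", "cpg2", "cpg3", "cpg4"]
    )

    from .hmm import burden as _burden

    truth = SimulationTruth(
        class_labels=class_labels,
        true_burden=_burden(cn),
        burden_targets=eff_targets,
        segments=pd.DataFrame(
            seg_rows, columns=["tumor", "chrom", "start_idx", "end_idx", "state"]
        ),
        coupled_genes=pd.DataFrame(columns=["gene", "target_r"]),
        line1_group_means={"high": cfg.line1_mean_high, "low": cfg.line1_mean_low},
        line1_groups=tier,
        class_mean_matrix=pd.DataFrame(
            class_means[inf_idx],
            index=cpg_annot["locus"].to_numpy()[inf_idx],
            columns=[f"class{k+1}" for k in range(K)],
        ),
    )
    return Cohort(
        beta=beta,
        cn_states=cn,
        log_ratios=log_ratios,
        cpg_annotation=cpg_annot,
        snp_annotation=snp_annot,
        metadata=meta,
        line1=line1,
        truth=truth,
    )


def plant_local_coupling(
    cohort: Cohort,
    genes: Sequence[str],
    target_r: float,
    beta_amplitude: float = 0.18,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Plant a tumor-level methylation/copy-number coupling at given genes.

    For each gene a latent standard-normal tumor variable drives both the
    gene's promoter-CpG beta values and its SNP states so the expected
    gene-level Pearson correlation is ``target_r`` in sign and approximate
    magnitude. ``target_r=0`` is a no-op. Modifies the cohort in place and
    records the planted genes in the truth; returns the cohort.
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    if target_r != 0 and beta_amplitude <= 0:
        raise ValueError("coupling needs a positive beta variance budget")
    if target_r == 0:
        return cohort
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    known = set(cohort.cpg_annotation["gene"].dropna())
    missing = [g for g in genes if g not in known]
    if missing:
        raise ValueError(f"genes not in annotation: {missing}")
    tumors = list(cohort.tumors)
    n = len(tumors)
    rho = abs(target_r)
    sgn = np.sign(target_r)
    rows = []
    for g in genes:
        u = rng.normal(size=n)
        c = np.clip(np.round(2 + 1.2 * u), 0, 4).astype(int)
        z = (c - c.mean()) / max(c.std(), 1e-9)
        eps = rng.normal(size=n)
        b = 0.5 + beta_amplitude * (sgn * rho * z + np.sqrt(1 - rho**2) * eps)
        b = np.clip(b, 0.01, 0.99)
        cpgs = cohort.cpg_annotation.query("gene == @g and upstream == 1")["locus"]
        if len(cpgs) == 0:  # ensure the gene has a promoter CpG to carry the signal
            cpgs = cohort.cpg_annotation.query("gene == @g")["locus"].iloc[:1]
            cohort.cpg_annotation.loc[
                cohort.cpg_annotation["locus"].isin(cpgs), "upstream"
            ] = 1.0
        for cpg in cpgs:
            jitter = rng.normal(0, 0.01, size=n)
            cohort.beta.loc[cpg, tumors] = np.clip(b + jitter, 0.005, 0.995)
        snps = cohort.snp_annotation.query("gene == @g")["locus"]
        for snp in snps:
            cohort.cn_states.loc[snp, tumors] = c
            cohort.log_ratios.loc[snp, tumors] = np.log2(
                np.maximum(c, 0.5) / 2.0
            ) + rng.normal(0, 0.2, size=n)
        rows.append((g, target_r))
    new = pd.DataFrame(rows, columns=["gene", "target_r"])
    old = cohort.truth.coupled_genes
    cohort.truth.coupled_genes = (
        new if old.empty else pd.concat([old, new], ignore_index=True)
    )
    # planted states changed the emitted matrix; keep truth burden consistent
    from .hmm import burden as _burden

    cohort.truth.true_burden = _burden(cohort.cn_states)
    return cohort


def synthesize_signals(beta: pd.DataFrame, total_intensity: float = 2000.0) -> pd.DataFrame:
    """Long M/U signal-pair table whose beta recomputation round-trips.

    Inverts beta = M/(M + U + 100) under M + U = ``total_intensity``:
    M = beta (total + 100), U = total - M. Betas too large to represent
    at this intensity (beta > total/(total+100)) are clamped with a
    warning.
    """
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    b = beta.to_numpy(dtype=float)
    bmax = total_intensity / (total_intensity + 100.0)
    if np.any(b > bmax):
        import warnings

        warnings.warn("beta values above the representable maximum were clamped")
        b = np.minimum(b, bmax)
    M = b * (total_intensity + 100.0)
    U = total_intensity - M
    loci = np.repeat(beta.index.to_numpy(), beta.shape[1])
    samples = np.tile(beta.columns.to_numpy(), beta.shape[0])
    return pd.DataFrame(
        {"locus": loci, "sample": samples, "M": M.ravel(), "U": U.ravel()}
    )
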