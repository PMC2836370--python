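#!/usr/bin/env python
"""Per-gene alteration tests and volcano tables, stratified by the
left/right methylation grouping.

Methylation alteration: Welch t of tumor vs normal promoter methylation.
Copy-number alteration: one-sample t of gene-averaged state against the
diploid expectation 2. The two high-burden classes fall on one side of
the root split, so copy-number significants concentrate in that stratum
(which side is called "left" is an arbitrary orientation of the tree).
A volcano figure goes to scratch/ (binary); tables and counts to
results/.
"""

from pathlib import Path

from methcna.alteration import stratified_volcano
from methcna.local import gene_aggregate
from methcna.rpmm import rpmm_fit
from methcna.simulate import SimulationConfig, simulate_cohort

SEED = 1
OUT = Path("results")


def main() -> None:
    cohort = simulate_cohort(SimulationConfig(seed=SEED))
    tumors = list(cohort.tumors)
    normals = list(cohort.normals)
    gb, gc = gene_aggregate(cohort.beta, cohort.cn_states,
                            cohort.cpg_annotation, cohort.snp_annotation)
    classing = rpmm_fit(cohort.beta[tumors].T, seed=SEED)
    volcano = stratified_volcano(
        gb[tumors], gb[[n for n in normals if n in gb.columns]],
        gc[[t for t in tumors if t in gc.columns]],
        classing.root_side,
    )
    OUT.mkdir(exist_ok=True)
    volcano.to_csv(OUT / "alteration_volcano.tsv", sep="\t", index=False, na_rep="NA")
    counts = (
        volcano[volcano["significant"]]
        .groupby(["type", "stratum"])["unit"]
        .count()
        .rename("n_significant")
    )
    print("significant alterations (q < 0.05) by type and stratum:")
    print(counts.to_string())

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharey="row")
        for col, stratum in enumerate(["all", "left", "right"]):
            for row, typ in enumerate(["methylation", "copy_number"]):
                sub = volcano.query("type == @typ and stratum == @stratum")
                ax = axes[row][col]
                ax.scatter(sub["mean_alteration"], sub["neg_log10_p"], s=6,
                           c=["tab:red" if s else "grey" for s in sub["significant"]])
                ax.axhline(-__import__("numpy").log10(0.05), ls=":", c="k", lw=0.8)
                ax.set_title(f"{typ} / {stratum}")
        fig.tight_layout()
        Path("scratch").mkdir(exist_ok=True)
        fig.savefig("scratch/volcano.png", dpi=120)
        print("figure: scratch/volcano.png")
    except ImportError:
        print("matplotlib unavailable; skipped the figure")


if __name__ == "__main__":
    main()
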