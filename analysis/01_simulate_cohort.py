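#!/usr/bin/env python
"""Generate the reference synthetic cohort and summarize its structure.

Emulates the study design: 19 tumors and 11 normal tissues, ~1,500
promoter-region CpGs over ~800 genes, 5,000 autosomal SNP loci (reduced
from the 500k array), five latent methylation classes of which two carry
a high copy-number burden (target mean|CNS-2| = 0.5) and three a low one
(0.05). Full matrices go to scratch/cohort/ (they are large); a compact
per-class summary is written to results/.
"""

from pathlib import Path

import pandas as pd

from methcna.io import write_annotation, write_matrix
from methcna.simulate import SimulationConfig, plant_local_coupling, simulate_cohort

SEED = 1
OUT = Path("results")
SCRATCH = Path("scratch/cohort")


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    cohort = simulate_cohort(cfg)
    planted = list(cohort.cpg_annotation["gene"].dropna().unique()[:10])
    plant_local_coupling(cohort, planted, target_r=0.95, seed=SEED)

    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.beta, SCRATCH / "beta.tsv")
    write_matrix(cohort.cn_states, SCRATCH / "cn_states.tsv")
    write_matrix(cohort.log_ratios, SCRATCH / "log_ratios.tsv")
    write_annotation(cohort.cpg_annotation, SCRATCH / "cpg_annotation.tsv")
    write_annotation(cohort.snp_annotation, SCRATCH / "snp_annotation.tsv")
    cohort.metadata.to_csv(SCRATCH / "metadata.tsv", sep="\t")
    cohort.line1.to_csv(SCRATCH / "line1.tsv", sep="\t", index=False)

    summary = (
        pd.DataFrame(
            {
                "class": cohort.truth.class_labels,
                "burden": cohort.truth.true_burden,
            }
        )
        .groupby("class")["burden"]
        .agg(["count", "mean", "min", "max"])
        .round(4)
    )
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "cohort_class_summary.tsv", sep="\t")
    print(f"cohort written to {SCRATCH} (planted genes: {', '.join(planted)})")
    print("per-class copy-number burden (mean |CNS-2|):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
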