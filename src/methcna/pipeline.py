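"""End-to-end pipeline: chain all analysis stages over one cohort.

Stage order: preprocess -> copy-number HMM (if log-ratios are the input)
-> burden -> RPMM classing -> global class/burden permutation test ->
local correlation screen (locus and gene level) -> alteration tests
(overall and stratified by the root split) -> CN clustering, high/low
grouping, covariate tests and the LINE-1 comparison. Every stage writes a
TSV into the output directory and the run ends with a JSON manifest
recording the seed and parameters, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import stage_rng
from .alteration import stratified_volcano
from .cluster import (
    dichotomize_cna,
    export_orderings,
    hamming_matrix,
    line1_group_difference,
    ward_cluster,
)
from .global_test import covariate_tests, permutation_test_global
from .hmm import CNHmmModel, burden, call_state_matrix
from .io import FLOAT_FORMAT, AnalysisConfig, read_annotation, read_matrix, write_matrix
from .local import correlation_screen, flag_significant, gene_aggregate, match_loci
from .preprocess import line1_summary
from .rpmm import rpmm_fit

__all__ = ["run_pipeline", "PipelineResult"]


@dataclasses.dataclass
class PipelineResult:
    classes: pd.DataFrame
    burden: pd.Series
    global_test: pd.DataFrame
    covariates: pd.DataFrame
    local_locus: pd.DataFrame
    local_gene: pd.DataFrame
    significant_local: pd.DataFrame
    volcano: pd.DataFrame
    cna_groups: pd.Series
    line1_difference: dict | None
    manifest: dict


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FORMAT)


def run_pipeline(
    config: AnalysisConfig,
    out_dir,
    cohort=None,
) -> PipelineResult:
    """Run every stage and write result tables plus a manifest.

    Inputs come either from the file paths in ``config`` or from an
    in-memory :class:`~methcna.simulate.Cohort`. A stage failure aborts
    the run with the stage name in the error message.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if cohort is not None:
            beta = cohort.beta
            cpg_annot = cohort.cpg_annotation
            snp_annot = cohort.snp_annotation
            meta = cohort.metadata
            log_ratios = cohort.log_ratios
            cn = None
            line1 = cohort.line1
        else:
            beta = read_matrix(config.beta_path, "beta")
            cpg_annot = read_annotation(config.cpg_annotation_path)
            snp_annot = read_annotation(config.snp_annotation_path)
            meta = pd.read_csv(config.metadata_path, sep="\t", index_col=0,
                               na_values=["NA"], keep_default_na=False)
            log_ratios = (
                read_matrix(config.log_ratio_path, "log_ratio")
                if config.log_ratio_path
                else None
            )
            cn = (
                read_matrix(config.cn_path, "cn_state") if config.cn_path else None
            )
            line1 = (
                pd.read_csv(config.line1_path, sep="\t")
                if config.line1_path
                else None
            )
        tumors = meta.index[meta["group"] == "tumor"]
        normals = meta.index[meta["group"] == "normal"]

        stage = "cn_hmm"
        if cn is None:
            if log_ratios is None:
                raise ValueError("need either copy-number states or log-ratios")
            model = CNHmmModel(
                emission_sd=config.hmm_emission_sd, p_stay=config.hmm_stay_prob
            )
            cn = call_state_matrix(log_ratios, snp_annot, model)
            write_matrix(cn, out / "cn_states.tsv")
        burden_vec = burden(cn[tumors])
        burden_vec.rename_axis("tumor").reset_index().pipe(
            _write, out / "burden.tsv"
        )

        stage = "rpmm"
        classing = rpmm_fit(
            beta[tumors].T,
            max_depth=config.rpmm_max_depth,
            min_node_weight=config.rpmm_min_node_weight,
            seed=config.seed,
            tol=config.rpmm_em_tol,
        )
        classes = classing.to_frame()
        classes.rename_axis("sample").reset_index().pipe(_write, out / "classes.tsv")
        (out / "rpmm_tree.json").write_text(
            json.dumps(classing.root.to_dict(), indent=1, default=float)
        )

        stage = "global_association"
        gres = permutation_test_global(
            burden_vec,
            classes.loc[tumors, "leaf_class"],
            n_perm=config.n_perm_global,
            seed=stage_rng(config.seed, "global_test"),
        )
        _write(gres.to_frame(), out / "global_test.tsv")

        stage = "local_integration"
        pairs = match_loci(cpg_annot, snp_annot, config.match_max_distance)
        matched = pairs[pairs["snp"].notna()]
        _write(pairs, out / "matched_pairs.tsv")
        locus_res = correlation_screen(
            beta.loc[matched["cpg"], tumors],
            cn.loc[matched["snp"], tumors].set_axis(matched["cpg"], axis=0),
            n_perm=config.n_perm_local,
            seed=stage_rng(config.seed, "local_corr/locus"),
            level="locus",
        )
        gene_beta, gene_cn = gene_aggregate(beta, cn, cpg_annot, snp_annot)
        shared_genes = gene_beta.index.intersection(gene_cn.index)
        gene_res = correlation_screen(
            gene_beta.loc[shared_genes, tumors],
            gene_cn.loc[shared_genes, tumors],
            n_perm=config.n_perm_local,
            seed=stage_rng(config.seed, "local_corr/gene"),
            level="gene",
        )
        _write(locus_res, out / "local_locus.tsv")
        _write(gene_res, out / "local_gene.tsv")
        sig = flag_significant(
            pd.concat([locus_res, gene_res], ignore_index=True),
            config.q_threshold,
        )
        _write(sig, out / "significant_local.tsv")

        stage = "alteration_stats"
        volcano = stratified_volcano(
            gene_beta[tumors],
            gene_beta[normals.intersection(gene_beta.columns)],
            gene_cn[tumors.intersection(gene_cn.columns)],
            classes.loc[tumors, "root_side"],
            q_threshold=config.q_threshold,
        )
        _write(volcano, out / "alteration_volcano.tsv")

        stage = "cluster_groups"
        D = hamming_matrix(cn[tumors])
        dend = ward_cluster(D, metric="hamming")
        (out / "cn_dendrogram.nwk").write_text(dend.to_newick() + "\n")
        groups = dichotomize_cna(dend, burden_vec)
        groups.rename_axis("tumor").reset_index().pipe(_write, out / "cna_groups.tsv")
        covs = covariate_tests(
            groups, meta.loc[tumors], seed=stage_rng(config.seed, "covariates")
        )
        _write(covs, out / "covariate_tests.tsv")
        orderings = export_orderings(classes.loc[tumors], beta[tumors], dend)
        pd.DataFrame(
            {
                "rank": range(1, len(tumors) + 1),
                "methylation_order": orderings["methylation"],
                "copy_number_order": orderings["copy_number"],
            }
        ).pipe(_write, out / "sample_orderings.tsv")

        line1_diff = None
        if line1 is not None and len(line1):
            summary = line1_summary(line1)
            line1_diff = line1_group_difference(summary, groups)
            (out / "line1_difference.json").write_text(
                json.dumps(line1_diff, indent=1, default=float)
            )

        stage = "manifest"
        manifest = {
            "package": "methcna",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                k: (v if np.isfinite(v) else "inf") if isinstance(v, float) else v
                for k, v in dataclasses.asdict(config).items()
            },
            "stages": [
                "preprocess", "cn_hmm", "rpmm", "global_association",
                "local_integration", "alteration_stats", "cluster_groups",
            ],
            "n_tumors": int(len(tumors)),
            "n_normals": int(len(normals)),
            "n_cpg": int(beta.shape[0]),
            "n_snp": int(cn.shape[0]),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        classes=classes,
        burden=burden_vec,
        global_test=gres.to_frame(),
        covariates=covs,
        local_locus=locus_res,
        local_gene=gene_res,
        significant_local=sig,
        volcano=volcano,
        cna_groups=groups,
        line1_difference=line1_diff,
        manifest=manifest,
    )
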