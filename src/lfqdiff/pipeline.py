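"""End-to-end orchestration: simulate/load -> preprocess -> explore -> test -> classify -> enrich.

Every stage writes plain TSV outputs into the run directory, and a JSON
manifest records package version, seeds and every stage parameter so a run
can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .classify import RfeParams, RfeSvmModel
from .diffstat import DifferentialAbundanceModel, ModeratedTestParams, summarize_significant
from .enrich import interaction_enrichment, overrepresentation_test
from .exploratory import hierarchical_cluster, pca, replicate_shift_and_subtract, technical_pair_concordance
from .preprocess import ImputationParams, filter_by_detection, impute_downshifted, log2_transform, zscore_rows
from .simulate import SimulationConfig, generate_study

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "filter": {"min_fraction": 0.5},
    "impute": {"width": 0.3, "shift": 1.8, "per_sample": True},
    "diffstat": {"s0": 0.05, "n_permutations": 5000, "alpha_p": 0.05, "alpha_fdr": 0.05},
    "classify": {"rank_cost": 100.0, "cv_cost": 10.0, "reduction_factor": 1.414},
    "enrich": {"n_random": 1000},
    "simulate": {},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "lfqdiff_run",
    matrix: io.IntensityMatrix | None = None,
    design: io.StudyDesign | None = None,
    gene_sets: io.GeneSetCollection | None = None,
    network=None,
) -> dict:
    """Run every stage and write results under ``outdir``.

    Without an input matrix the simulate block generates one.  Returns a
    dict of in-memory stage results (also all written as TSV/JSON files).
    """
    cfg = merge_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    stage = "simulate"
    try:
        if matrix is None:
            sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": seed})
            matrix, design, truth = generate_study(sim_cfg)
            results["truth"] = truth
            io.write_intensity_table(matrix, out / "intensities.tsv")
            io.write_design(design, out / "design.tsv")
        if design is None:
            raise ValueError("a design is required when a matrix is supplied")

        stage = "preprocess"
        filtered = filter_by_detection(matrix, cfg["filter"]["min_fraction"])
        logger.info("detection filter: %d of %d proteins retained", filtered.n_proteins, matrix.n_proteins)
        logged = log2_transform(filtered)
        imp = ImputationParams(seed=seed, **cfg["impute"])
        logger.info("imputation width=%s shift=%s per_sample=%s", imp.width, imp.shift, imp.per_sample)
        imputed = impute_downshifted(logged, imp)
        results["imputed"] = imputed

        stage = "explore"
        z = zscore_rows(imputed)
        dend = hierarchical_cluster(z)
        (out / "dendrogram.newick").write_text(dend.to_newick() + "\n")
        pca_res = pca(z)
        pca_res.scores_frame().to_csv(out / "pca_scores.tsv", sep="\t")
        explore: dict = {
            "explained_variance_ratio": pca_res.explained_variance_ratio[:5].tolist()
        }
        if all(len(design.samples_of(p)) == 2 for p in design.patients):
            frac, flags = technical_pair_concordance(dend, design)
            shift = replicate_shift_and_subtract(pca_res, design, component=0)
            explore.update(
                concordance=frac,
                intra_inter_before=shift.intra_inter_ratio_before,
                intra_inter_after=shift.intra_inter_ratio_after,
            )
        results["explore"] = explore

        stage = "difftest"
        params = ModeratedTestParams(seed=seed, **cfg["diffstat"])
        logger.info("diffstat s0=%s permutations=%d", params.s0, params.n_permutations)
        fit = DifferentialAbundanceModel(imputed, design, params=params).fit()
        io.write_results_table(fit.frame, out / "differential.tsv")
        results["diffstat"] = fit
        summary = summarize_significant(fit.significant)
        summary.to_csv(out / "significant_summary.tsv", sep="\t", index=False)

        stage = "classify"
        rfe_params = RfeParams(seed=seed, **cfg["classify"])
        logger.info("classify c=%s/%s reduction=%s", rfe_params.rank_cost, rfe_params.cv_cost, rfe_params.reduction_factor)
        patient_matrix, groups = fit.model.patient_matrix, fit.model.groups
        rfe = RfeSvmModel(
            patient_matrix.values.T, groups, patient_matrix.protein_ids, rfe_params
        ).fit()
        rfe.ranking_frame().to_csv(out / "ranking.tsv", sep="\t", index=False)
        rfe.error_curve.to_frame().to_csv(out / "error_curve.tsv", sep="\t", index=False)
        pd.Series(rfe.selected, name="protein").to_csv(out / "selected_panel.tsv", sep="\t", index=False)
        results["classify"] = rfe

        stage = "enrich"
        if gene_sets is not None or network is not None:
            gene_of = dict(zip(patient_matrix.protein_ids, patient_matrix.primary_gene_symbols()))
            background = sorted({g for g in gene_of.values() if g})
            sig_genes = sorted(
                {gene_of[p] for p in fit.significant["protein_id"] if gene_of.get(p)}
            )
            if gene_sets is not None and sig_genes:
                ora = overrepresentation_test(sig_genes, gene_sets, background)
                ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                results["enrichment"] = ora
            if network is not None and len(sig_genes) >= 2:
                ie = interaction_enrichment(
                    sig_genes, network, n_random=cfg["enrich"]["n_random"], seed=seed
                )
                results["interaction"] = ie
                (out / "interaction.json").write_text(
                    json.dumps(dataclasses.asdict(ie), indent=2) + "\n"
                )
    except Exception as exc:  # noqa: BLE001 - reported with the failing stage
        raise PipelineError(stage, exc) from exc

    manifest = {
        "package": "lfqdiff",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "n_proteins_input": matrix.n_proteins,
        "n_proteins_tested": len(results["diffstat"].frame),
        "n_significant": results["diffstat"].n_significant,
        "selected_panel_size": results["classify"].selected_size,
        "min_loo_error": results["classify"].min_error,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
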