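"""End-to-end orchestration: simulate -> QC -> signature -> deconvolve ->
composition tests -> differential expression -> enrichment.

A single config seed fans out to per-stage seeds (stage-name hashed) so any
stage can be re-run independently and byte-identically.  Every stage writes
plain tab-delimited tables into the run directory plus a YAML manifest that
echoes versions, seeds and parameters.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import paired_score_test, total_score_test
from .containers import BulkExperiment
from .deconvolve import deconvolve_experiment
from .dge import (
    collate_celltype_results,
    run_adjusted,
    run_interaction_lrt,
    run_unadjusted,
)
from .enrichment import MarkerSets, enrichment_table, overlap_table
from .io import dump_yaml, write_marker_sets, write_matrix, write_signature
from .reference import normalize_reference, qc_filter_cells
from .signature import SignatureConfig, build_signature
from .simulate import SimulationConfig, simulate_paired_bulk, simulate_reference

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (int(base_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    strata: tuple = ("all", "left", "right")
    fdr_alpha: float = 0.1
    deconv_method: str = "svr"
    n_permutations: int = 0
    qc_min_genes: int = 250
    qc_max_mito: float = 0.15


def _stratum_samples(experiment: BulkExperiment, stratum: str) -> list:
    md = experiment.metadata
    if stratum == "all":
        return list(md.index)
    if stratum in ("left", "right"):
        return list(md.index[md["location"] == stratum])
    if stratum in ("male", "female"):
        return list(md.index[md["sex"] == stratum[0].upper()])
    raise ValueError(f"unknown stratum {stratum!r}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a synthetic experiment and write all result tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in
             ("simulate", "signature", "deconvolve", "dge")}

    # --- simulate ---------------------------------------------------------
    sim = SimulationConfig(**{**config.simulation.__dict__, "seed": seeds["simulate"]})
    ref, ref_truth = simulate_reference(sim)
    experiment, truth = simulate_paired_bulk(sim, ref_truth.profiles)
    write_matrix(experiment.counts, outdir / "bulk_counts.tsv")
    write_matrix(experiment.tpm, outdir / "bulk_tpm.tsv")
    experiment.metadata.rename_axis("sample").to_csv(outdir / "bulk_metadata.tsv", sep="\t")
    truth.proportions.rename_axis("sample").to_csv(
        outdir / "truth_proportions.tsv", sep="\t", float_format="%.10g"
    )
    write_marker_sets(truth.markers, outdir / "truth_markers.tsv")

    # --- reference QC -----------------------------------------------------
    ref = qc_filter_cells(ref, min_genes=config.qc_min_genes, max_mito=config.qc_max_mito)
    pd.Series(ref.uns["qc_report"]).rename("value").rename_axis("metric").to_csv(
        outdir / "qc_report.tsv", sep="\t"
    )
    ref = normalize_reference(ref)

    # --- signature --------------------------------------------------------
    sig_cfg = SignatureConfig(**{**config.signature.__dict__, "seed": seeds["signature"]})
    signature = build_signature(ref, sig_cfg)
    write_signature(signature.basis, outdir / "signature.tsv")
    logger.info(
        "signature: %d genes, chosen_g=%d, condition number %.3f",
        len(signature.genes), signature.chosen_g, signature.condition_number,
    )

    # --- per-stratum deconvolution, composition tests and DE --------------
    marker_sets = MarkerSets(
        sets=truth.markers, universe=frozenset(experiment.counts.index)
    )
    collected_scores, interaction_tables = {}, {}
    for stratum in config.strata:
        samples = _stratum_samples(experiment, stratum)
        if not samples:
            raise ValueError(f"stratum {stratum!r} selects no samples")
        sub = experiment.subset(samples)
        scores = deconvolve_experiment(
            sub,
            signature,
            method=config.deconv_method,
            n_permutations=config.n_permutations,
            seed=seeds["deconvolve"],
        )
        collected_scores[stratum] = scores
        tag = f"_{stratum}"
        pd.concat(
            {
                "fraction": scores.fractions,
                "absolute": scores.absolute,
                "scaled": scores.scaled,
            },
            axis=1,
        ).rename_axis("sample").to_csv(
            outdir / f"cell_scores{tag}.tsv", sep="\t", float_format="%.10g"
        )

        comp = paired_score_test(scores, sub.metadata)
        comp.loc["total"] = total_score_test(scores, sub.metadata).drop("cell_type")
        comp.to_csv(outdir / f"composition_tests{tag}.tsv", sep="\t", float_format="%.10g")

        de_un = run_unadjusted(sub, config.fdr_alpha)
        de_un.to_csv(outdir / f"de_unadjusted{tag}.tsv", sep="\t", float_format="%.10g")
        de_adj = run_adjusted(sub, scores, config.fdr_alpha)
        de_adj.to_csv(outdir / f"de_adjusted{tag}.tsv", sep="\t", float_format="%.10g")

        grid = overlap_table(de_un, marker_sets)
        grid.to_csv(outdir / f"marker_overlap{tag}.tsv", sep="\t")
        enr = enrichment_table(set(de_un.index[de_un["significant"]]), marker_sets)
        enr.to_csv(outdir / f"marker_enrichment{tag}.tsv", sep="\t", float_format="%.10g")

        if stratum == "all":
            for ct in scores.cell_types:
                interaction_tables[ct] = run_interaction_lrt(
                    sub, scores, ct, config.fdr_alpha
                )
                interaction_tables[ct].to_csv(
                    outdir / f"de_interaction_{ct}.tsv", sep="\t", float_format="%.10g"
                )
            collate_celltype_results(interaction_tables).to_csv(
                outdir / "de_interaction_collated.tsv", sep="\t", float_format="%.10g"
            )

    manifest = {
        "compdecon_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "simulation": sim,
        "signature_config": sig_cfg,
        "signature_chosen_g": signature.chosen_g,
        "signature_condition_number": signature.condition_number,
        "strata": list(config.strata),
        "fdr_alpha": config.fdr_alpha,
        "deconv_method": config.deconv_method,
        "n_permutations": config.n_permutations,
    }
    dump_yaml(manifest, outdir / "manifest.yaml")
    return outdir
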