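"""End-to-end analysis pipeline on synthetic cohorts.

Mirrors the study's analysis sequence: simulate a sorted cohort plus a
control-HSC reference, gate divided vs undivided cells on dye dilution,
correct confounders, run the hurdle differential-expression contrast,
score and call cell-cycle phases against the reference calibration, and
quantify population separation by consensus k-means.  A single top-level
seed drives per-stage derived substreams, so any stage can be rerun in
isolation reproducibly and the whole run is byte-identical given the seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell_cycle, division, hurdle, population
from .datatypes import ExpressionMatrix, GenePanel, concat_matrices
from .io_preprocess import correct_confounders, subset_panel, write_annotation, write_matrix
from .stats import ttest_unpaired  # noqa: F401  (re-exported pipeline utility)
from .synthetic import SyntheticConfig, generate_cells, generate_dye_intensities

logger = logging.getLogger("scfate")


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage child seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for one synthetic end-to-end run."""

    seed: int = 0
    outdir: str | Path = "scfate_run"
    # simulate
    simulate: bool = True
    matrix_path: str | Path | None = None       # used when simulate=False
    annotation_path: str | Path | None = None
    n_reference: int = 1000
    divided_fraction: float = 0.3
    base_log2: float = 10.0
    synthetic_overrides: dict = field(default_factory=dict)
    # stages
    run_division: bool = True
    division_mode: str = "standard"
    run_de: bool = True
    de_groups: tuple[str, str] = ("HSC", "PreMeg")
    de_adjust: str = "benjamini_hochberg"
    run_cellcycle: bool = True
    reference_fraction: float = cell_cycle.DEFAULT_REFERENCE_FRACTION
    run_cluster: bool = True
    cluster_categories: tuple[str, ...] = ("mep_platelet",)
    kmeans_restarts: int = 50
    run_tsne: bool = True
    tsne_perplexity: float = 8.0

    def validate(self) -> None:
        if not self.simulate and (
            self.matrix_path is None or self.annotation_path is None
        ):
            raise ValueError(
                "simulate=False requires matrix_path and annotation_path"
            )
        if not 0.0 <= self.divided_fraction <= 1.0:
            raise ValueError("divided_fraction must be in [0, 1]")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the machine-readable summary.

    All stage tables are written under ``config.outdir`` as TSV, the
    summary as ``summary.json``.  Any stage failure aborts with the stage
    name; outputs of completed stages are retained on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = GenePanel.default()
    summary: dict = {"seed": config.seed}

    # ---- simulate ----------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            cohort_cfg = SyntheticConfig.default(
                seed=derive_seed(config.seed, "cohort"),
                **config.synthetic_overrides,
            )
            matrix, annotation = generate_cells(cohort_cfg)
            ref_cfg = SyntheticConfig.reference_hsc(
                config.n_reference, seed=derive_seed(config.seed, "reference")
            )
            ref_matrix, ref_annotation = generate_cells(
                ref_cfg, is_reference=True
            )
            ref_annotation.index = "ref_" + ref_annotation.index
            ref_matrix.values.index = ref_annotation.index

            gen_rng = np.random.default_rng(
                derive_seed(config.seed, "generations")
            )
            generations = (
                gen_rng.random(matrix.n_cells) < config.divided_fraction
            ).astype(int)
            annotation["true_generation"] = generations
            annotation["dye_intensity"] = generate_dye_intensities(
                generations, config.base_log2, cohort_cfg.dye_sigma,
                derive_seed(config.seed, "dye_cohort"),
            )
            ref_annotation["true_generation"] = 0
            ref_annotation["dye_intensity"] = generate_dye_intensities(
                np.zeros(ref_matrix.n_cells, dtype=int), config.base_log2,
                ref_cfg.dye_sigma, derive_seed(config.seed, "dye_reference"),
            )
            panel = cohort_cfg.panel()
            cohort_cfg.to_json(outdir / "config.json")
        else:
            from .io_preprocess import read_annotation, read_matrix

            matrix = read_matrix(config.matrix_path)
            annotation = read_annotation(config.annotation_path)
            ref_mask = annotation.get("is_reference", pd.Series(False, annotation.index))
            ref_matrix = matrix.subset_cells(list(annotation.index[ref_mask]))
            ref_annotation = annotation.loc[ref_mask]
            matrix = matrix.subset_cells(list(annotation.index[~ref_mask]))
            annotation = annotation.loc[~ref_mask]

        write_matrix(matrix, outdir / "matrix.tsv")
        write_annotation(annotation, outdir / "annotation.tsv")
        write_matrix(ref_matrix, outdir / "reference_matrix.tsv")
        write_annotation(ref_annotation, outdir / "reference_annotation.tsv")
        logger.info("simulate: %d cohort cells, %d reference cells, %d genes",
                    matrix.n_cells, ref_matrix.n_cells, matrix.n_genes)

        # confounder correction (no-op for single-batch defaults)
        if annotation["batch"].nunique() >= 2:
            matrix = correct_confounders(matrix, annotation, ["batch"])

        # ---- division gating -----------------------------------------
        if config.run_division and "dye_intensity" in annotation.columns:
            stage = "division"
            calls = division.undivided_gate(
                annotation["dye_intensity"],
                ref_annotation["dye_intensity"],
                mode=config.division_mode,
            )
            calls.to_csv(outdir / "division_calls.tsv", sep="\t")
            frac = division.progenitor_fractions(annotation, calls)
            summary["progenitor_fractions"] = _jsonable(frac["fractions"])
            summary["division_counts"] = _jsonable(
                calls["call"].value_counts().to_dict()
            )

        # ---- differential expression ---------------------------------
        if config.run_de:
            stage = "de"
            de = hurdle.test_all_genes(
                matrix, annotation, "population",
                config.de_groups[0], config.de_groups[1],
                adjust=config.de_adjust,
            )
            de.to_csv(outdir / "hurdle_de.tsv", sep="\t")
            summary["hurdle_de"] = _jsonable(
                de[["lrt_total", "df", "p_value", "p_adjusted", "status"]]
            )

        # ---- cell cycle ----------------------------------------------
        if config.run_cellcycle:
            stage = "cellcycle"
            combined = concat_matrices(matrix, ref_matrix)
            scores = cell_cycle.phase_scores(combined, panel)
            ref_scores = scores.loc[ref_annotation.index]
            threshold = cell_cycle.calibrate_threshold(
                ref_scores, config.reference_fraction
            )
            called = cell_cycle.classify_phase(scores, threshold)
            called.to_csv(outdir / "phase_calls.tsv", sep="\t")
            (outdir / "phase_threshold.json").write_text(
                json.dumps(
                    {
                        "sg2m_cutoff": threshold.sg2m_cutoff,
                        "reference_fraction": threshold.reference_fraction,
                        "reference_n": threshold.reference_n,
                    },
                    sort_keys=True,
                )
            )
            ref_called = called.loc[ref_annotation.index]
            summary["phase_threshold"] = _jsonable(vars(threshold))
            summary["reference_g0g1_fraction"] = float(
                (ref_called["call"] == cell_cycle.G0G1).mean()
            )
            summary["phase_calls"] = _jsonable(
                called.loc[annotation.index, "call"].value_counts().to_dict()
            )
            fold = cell_cycle.phase_foldchange(
                matrix, annotation, called, panel,
                gene_category="mep_platelet",
            )
            summary["mep_platelet_foldchange"] = _jsonable(fold)

        # ---- population structure ------------------------------------
        if config.run_cluster:
            stage = "cluster"
            sub = subset_panel(matrix, panel, list(config.cluster_categories))
            pair = annotation["population"].isin(config.de_groups)
            pair_cells = list(annotation.index[pair])
            result = population.kmeans_reproducible(
                sub.subset_cells(pair_cells), k=2,
                restarts=config.kmeans_restarts,
                seed=derive_seed(config.seed, "kmeans"),
            )
            result.labels.to_csv(outdir / "clusters.tsv", sep="\t")
            agreement = population.cluster_agreement(
                result.labels,
                annotation.loc[pair_cells, "population"],
            )
            summary["cluster_agreement"] = _jsonable(agreement)
            summary["cluster_stability"] = result.stability
            if config.run_tsne:
                coords = population.embed_tsne(
                    matrix,
                    perplexity=min(
                        config.tsne_perplexity, (matrix.n_cells - 1) / 3
                    ),
                    seed=derive_seed(config.seed, "tsne"),
                )
                coords.to_csv(outdir / "tsne.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(summary), sort_keys=True, indent=1)
    )
    logger.info("pipeline complete; summary written to %s",
                outdir / "summary.json")
    return summary
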