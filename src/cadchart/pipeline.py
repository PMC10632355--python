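"""End-to-end orchestration: fixtures in, charted/annotated artifacts out.

The pipeline sequences the analysis exactly as the processing chain is
designed: replicate peak merging -> background shuffling -> fragment
counting and RPKM -> empirical-FDR threshold calibration -> binarization ->
module charting -> nearest-gene annotation -> shared-open selection ->
differential expression -> discordance calling -> profile building, mark
comparison and clustering. Every intermediate is written as TSV/BED and a
JSON manifest records the stages, parameters, seed and a checksum per file,
so identical config and seed reproduce identical output byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cad import annotate_peaks, chart_modules
from .discordance import differential_expression, find_discordant, shared_open_peaks
from .occupancy import binarize_states, calibrate_threshold, stage_means
from .profiles import build_profile_matrix, cluster_profiles, compare_marks
from .quant import (
    PeakSet,
    compute_rpkm,
    count_reads_in_intervals,
    merge_replicate_peaks,
    shuffle_background,
)
from .synthetic import MARKS

logger = logging.getLogger(__name__)

PIPELINE_STAGES = [
    "merge_replicate_peaks",
    "shuffle_background",
    "compute_rpkm",
    "calibrate_threshold",
    "binarize_states",
    "chart_modules",
    "annotate_peaks",
    "shared_open_peaks",
    "differential_expression",
    "find_discordant",
    "profiles",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the fixture files."""

    fixture_dir: str
    out_dir: str
    target_fdr: float = 0.01
    grid_step: float = 0.01
    min_support: int = 2
    day8_index: int = 1
    promoter_window: int = 2000
    atac_fc_max: float = 0.5
    rna_fc_min: float = 1.0
    q_max: float = 0.05
    profile_window: int = 3000
    profile_bin: int = 50
    kmeans_k: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_fdr < 1:
            raise ValueError("target_fdr must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest that is also written to disk."""
    fixtures = Path(config.fixture_dir)
    out = io.ensure_dir(config.out_dir)
    design_df = pd.read_csv(fixtures / "stage_design.tsv", sep="\t")
    design = dict(zip(design_df["sample"], design_df["stage"]))
    stage_order = list(dict.fromkeys(design_df["stage"]))
    chrom_sizes = io.read_chrom_sizes(fixtures / "chrom.sizes")
    genes = io.read_gene_table(fixtures / "genes.tsv")

    stages_run: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)
        stages_run.append(name)

    try:
        # 1: per-stage replicate merge, then union across stages
        stage("merge_replicate_peaks")
        per_stage_sets = []
        for st in stage_order:
            reps = [
                PeakSet.from_bed(fixtures / "replicate_peaks" / f"{s}.bed")
                for s, lab in design.items()
                if lab == st
            ]
            per_stage_sets.append(merge_replicate_peaks(reps, config.min_support))
        union = merge_replicate_peaks(per_stage_sets, 1)
        union.to_bed(out / "union_peaks.bed")

        # 2: length-matched background avoiding the union peaks
        stage("shuffle_background")
        background = shuffle_background(union, chrom_sizes, union, seed=config.seed)
        background.to_bed(out / "background.bed")

        # 3: fragment counting and RPKM over peaks and background
        stage("compute_rpkm")
        peak_cols, bg_cols = {}, {}
        for sample in design:
            frags = pd.read_csv(
                fixtures / "fragments" / f"{sample}.bed",
                sep="\t",
                header=None,
                names=["chrom", "start", "end"],
            )
            library = len(frags)
            peak_cols[sample] = compute_rpkm(
                count_reads_in_intervals(frags, union), union.lengths, library
            )
            bg_cols[sample] = compute_rpkm(
                count_reads_in_intervals(frags, background), background.lengths, library
            )
        peak_rpkm = pd.DataFrame(peak_cols, index=pd.Index(union.ids, name="peak_id"))
        bg_rpkm = pd.DataFrame(bg_cols, index=pd.Index(background.ids, name="region_id"))
        io.write_matrix(peak_rpkm, out / "peak_rpkm.tsv")
        io.write_matrix(bg_rpkm, out / "background_rpkm.tsv")

        # 4: global threshold by empirical FDR
        stage("calibrate_threshold")
        threshold, curve = calibrate_threshold(
            peak_rpkm, bg_rpkm, target_fdr=config.target_fdr, grid_step=config.grid_step
        )
        curve_frame = curve.to_frame()
        thin = max(len(curve_frame) // 5000, 1)  # cap the written diagnostic curve
        curve_frame.iloc[::thin].to_csv(out / "fdr_curve.tsv", sep="\t", index=False)

        # 5: binary states at stage level
        stage("binarize_states")
        stage_signal = stage_means(peak_rpkm, design, stage_order)
        states = binarize_states(stage_signal, threshold)
        states.states.to_csv(out / "states.tsv", sep="\t")

        # 6: module charting
        stage("chart_modules")
        assignment = chart_modules(states, day8_index=config.day8_index)
        assignment.to_frame().to_csv(out / "modules.tsv", sep="\t")
        assignment.summary_frame().to_csv(out / "module_summary.tsv", sep="\t")
        assignment.per_stage_open.to_csv(out / "open_peaks_per_stage.tsv", sep="\t")

        # 7: nearest-gene annotation
        stage("annotate_peaks")
        annotation = annotate_peaks(union, genes, promoter_window=config.promoter_window)
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)

        # 8: peaks open in both day-8 populations
        stage("shared_open_peaks")
        stage_neg = stage_order[config.day8_index]
        stage_pos = stage_order[config.day8_index + 1]
        shared = shared_open_peaks(states, stage_neg, stage_pos)
        union.subset(shared).to_bed(out / "shared_open_peaks.bed")

        # 9: differential expression, RFP-positive vs RFP-negative
        stage("differential_expression")
        fpkm = io.read_matrix(fixtures / "expression_fpkm.tsv")
        group_pos = [s for s, lab in design.items() if lab == stage_pos]
        group_neg = [s for s, lab in design.items() if lab == stage_neg]
        de = differential_expression(fpkm, group_pos, group_neg)
        de.to_csv(out / "de_results.tsv", sep="\t")

        # 10: discordant genes
        stage("find_discordant")
        result = find_discordant(
            shared,
            stage_signal,
            de,
            annotation,
            stage_pos=stage_pos,
            stage_neg=stage_neg,
            atac_fc_max=config.atac_fc_max,
            rna_fc_min=config.rna_fc_min,
            q_max=config.q_max,
        )
        result.table.to_csv(out / "discordance_table.tsv", sep="\t")
        io.write_json(
            {"up_genes": list(result.up_genes), "down_genes": list(result.down_genes)},
            out / "discordant_genes.json",
        )

        # 11: histone-mark profiles over discordant loci
        stage("profiles")
        discordant = set(result.up_genes) | set(result.down_genes)
        loci_ids = annotation.loc[
            annotation["nearest_gene"].isin(discordant), "peak_id"
        ].unique()
        if len(loci_ids) == 0:
            loci_ids = np.asarray(shared)
        loci = union.subset(loci_ids)
        prof_dir = io.ensure_dir(out / "profiles")
        prof_map = {}
        for mark in MARKS:
            for st in (stage_neg, stage_pos):
                track_path = fixtures / "tracks" / f"{mark}_{st}.bedgraph"
                if not track_path.exists():
                    continue
                pm = build_profile_matrix(
                    io.read_bedgraph(track_path),
                    loci,
                    window=config.profile_window,
                    bin_width=config.profile_bin,
                )
                prof_map[(mark, st)] = pm
                pm.to_frame().to_csv(prof_dir / f"{mark}_{st}.tsv", sep="\t")
        if prof_map:
            comparison = compare_marks(prof_map, pop_a=stage_pos, pop_b=stage_neg)
            comparison.per_locus.to_csv(out / "mark_diff_per_locus.tsv", sep="\t")
            comparison.summary.rename("mean_abs_log2fc").to_csv(
                out / "mark_diff_summary.tsv", sep="\t"
            )
            first = next(iter(prof_map.values()))
            k = min(config.kmeans_k, max(len(first.locus_ids), 1))
            clustering = cluster_profiles(first, k=k, seed=config.seed)
            clustering.to_frame().to_csv(out / "profile_clusters.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted at stage {stages_run[-1] if stages_run else 'setup'}: {exc}"
        ) from exc

    files = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stages": stages_run,
        "seed": config.seed,
        "threshold": threshold,
        "parameters": asdict(config),
        "files": {f: _sha256(out / f) for f in files},
    }
    io.write_json(manifest, out / "run_manifest.json")
    return manifest
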