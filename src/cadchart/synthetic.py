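"""Synthetic coupled ATAC/RNA/histone-mark datasets with known ground truth.

The generator emulates the statistical structure of the primed-to-naive
transition data: a union peak set partitioned into six dynamics modules
across five ordered stages (primed ESC, the two reporter-sorted day-8
populations, a late double-positive intermediate, naive ESC); log-normal
low/high RPKM signal with replicate noise; gene expression coupled to the
chromatin state except for a designated discordant fraction at the day-8
pair, whose expression instead follows the histone-mark state; and
H3K4me3/H3K27ac binned signal tracks for the two day-8 populations with a
larger configured H3K27ac than H3K4me3 effect at discordant loci.

Peak accessibility is modeled as a locus property: each peak draws one
open-state and one closed-state amplitude, shared across the stages in that
state, with i.i.d. log-scale replicate noise on top. This makes "similar
accessibility between the two day-8 populations" hold for shared-open peaks
by construction, as in peak signal tracks of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io
from .quant import InfeasibleGeometryError, PeakSet

DEFAULT_STAGES = ("pESC", "d8_RFPneg", "d8_RFPpos", "RFPpos_GFPpos", "nESC")

# default module mix: the three dominant classes follow the published peak
# composition of the transition (permanently open 17.03%, opened-from-day-8
# 31.56%, transiently open 34.51%); the remainder is split over the
# open-to-closed, permanently closed and residual classes.
DEFAULT_MODULE_PROPORTIONS = (0.1703, 0.07, 0.3156, 0.3451, 0.05, 0.049)

MARKS = ("H3K4me3", "H3K27ac")
TRACK_BIN = 50  # bp, matches the default profile bin width
GENE_LENGTH = 2000  # bp merged-exon span of simulated genes
RNA_LIBRARY_SIZE = 2e7  # nominal mapped fragments for raw-count simulation
REPLICATE_DROPOUT = 0.02  # per-replicate peak non-detection probability


@dataclass
class SimulationConfig:
    """Parameters of the synthetic primed-to-naive dataset.

    Signal parameters are on the natural-log scale of RPKM/FPKM. The open
    and closed distributions are log-normal and well separated by default
    (mean log RPKM 5.0 vs 0.7, both sd 0.8: < 2% overlap), so empirical-FDR
    calibration of the open/closed threshold is well posed.
    """

    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_peaks: int = 2000
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    n_replicates_per_stage: int = 3
    module_proportions: tuple[float, ...] = DEFAULT_MODULE_PROPORTIONS
    open_signal_mean: float = 5.0
    open_signal_sd: float = 0.8
    closed_signal_mean: float = 0.7
    closed_signal_sd: float = 0.8
    replicate_noise_sd: float = 0.2
    discordant_up_fraction: float = 0.05
    discordant_down_fraction: float = 0.05
    h3k27ac_effect: float = 2.0
    h3k4me3_effect: float = 1.0
    day8_index: int = 1
    seed: int = 0

    def __post_init__(self):
        self.stage_labels = tuple(self.stage_labels)
        self.module_proportions = tuple(float(p) for p in self.module_proportions)
        if len(self.module_proportions) != 6:
            raise ValueError("module_proportions must have 6 entries")
        if abs(sum(self.module_proportions) - 1.0) > 1e-9:
            raise ValueError("module_proportions must sum to 1")
        if any(p < 0 for p in self.module_proportions):
            raise ValueError("module_proportions must be nonnegative")
        if self.open_signal_mean <= self.closed_signal_mean:
            raise ValueError("open_signal_mean must exceed closed_signal_mean")
        if self.h3k27ac_effect < self.h3k4me3_effect:
            raise ValueError("h3k27ac_effect must be >= h3k4me3_effect")
        if len(self.stage_labels) < 3:
            raise ValueError("need at least 3 stages")
        if not 1 <= self.day8_index < len(self.stage_labels) - 1:
            raise ValueError("day8_index must point at an intermediate stage pair")
        if self.discordant_up_fraction + self.discordant_down_fraction > 1:
            raise ValueError("discordant fractions sum above 1")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{stage}_rep{r + 1}"
            for stage in self.stage_labels
            for r in range(self.n_replicates_per_stage)
        ]

    @property
    def stage_design(self) -> dict[str, str]:
        return {
            f"{stage}_rep{r + 1}": stage
            for stage in self.stage_labels
            for r in range(self.n_replicates_per_stage)
        }

    def canonical_patterns(self) -> np.ndarray:
        """One representative binary trajectory per module, rows = modules 1..6."""
        n, d8 = self.n_stages, self.day8_index
        pats = np.zeros((6, n), dtype=np.int8)
        pats[0, :] = 1  # permanently open
        pats[1, 0] = 1  # open-to-closed, lost at day 8
        pats[2, d8:] = 1
        pats[2, 0] = 0  # opened from day 8 onward
        pats[3, d8 : min(d8 + 2, n - 1)] = 1  # transiently open around day 8
        # module 5: all zero
        pats[5, -1] = 1  # residual: opens only at the final stage
        return pats

    def open_cell_fraction(self) -> float:
        """Expected fraction of open peak-stage cells under the module mix."""
        pats = self.canonical_patterns()
        return float(
            sum(p * pats[m].mean() for m, p in enumerate(self.module_proportions))
        )

    def true_threshold_band(self) -> tuple[float, float]:
        """RPKM interval separating the bulk of closed and open populations.

        Band edges are the closed distribution's 99th and the open
        distribution's 1st percentile (z = 2.326).
        """
        z = 2.326
        lo = float(np.exp(self.closed_signal_mean + z * self.closed_signal_sd))
        hi = float(np.exp(self.open_signal_mean - z * self.open_signal_sd))
        return lo, hi

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            d = asdict(self)
            d["stage_labels"] = list(self.stage_labels)
            d["module_proportions"] = list(self.module_proportions)
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    peak_modules: pd.Series  # peak id -> true module label (1..6)
    patterns: pd.DataFrame  # peak id x stage binary chromatin state
    discordant_up_genes: tuple[str, ...]
    discordant_down_genes: tuple[str, ...]
    true_threshold_band: tuple[float, float]

    def __post_init__(self):
        if set(self.discordant_up_genes) & set(self.discordant_down_genes):
            raise ValueError("discordant gene sets must be disjoint")


@dataclass
class SyntheticBundle:
    """Everything one simulated experiment produces."""

    config: SimulationConfig
    peaks: PeakSet
    chrom_sizes: dict[str, int]
    atac: pd.DataFrame  # peak x sample RPKM
    background: pd.DataFrame  # background region x sample RPKM
    expression_fpkm: pd.DataFrame  # gene x sample FPKM
    expression_counts: pd.DataFrame  # gene x sample raw counts
    genes: pd.DataFrame  # gene annotation table
    tracks: dict[tuple[str, str], pd.DataFrame]  # (mark, stage) -> bedGraph frame
    replicate_peaks: dict[str, PeakSet]  # sample -> detected peaks
    fragments: dict[str, pd.DataFrame] | None  # sample -> fragment BED frame
    truth: GroundTruth


def _place_peaks(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping sorted peaks, lengths uniform in [300, 800) bp."""
    n = config.n_peaks
    lengths = rng.integers(300, 800, size=n)
    chrom_of = rng.integers(0, config.n_chromosomes, size=n)
    rows = []
    for c in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        lens = lengths[idx]
        free = config.chrom_length - int(lens.sum())
        if free < 0:
            raise InfeasibleGeometryError(
                f"cannot place {len(idx)} peaks totalling {lens.sum()} bp "
                f"on a {config.chrom_length} bp chromosome"
            )
        # random non-overlapping layout: split the free space into gaps
        cuts = np.sort(rng.integers(0, free + 1, size=len(idx)))
        gaps = np.diff(np.concatenate([[0], cuts]))
        starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lens[:-1])])
        for s, l in zip(starts, lens):
            rows.append((f"chr{c + 1}", int(s), int(s + l)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _stage_replicate_matrix(
    stage_level: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Expand peak-by-stage values to peak-by-sample with log-normal noise."""
    n, n_stages = stage_level.shape
    cols = {}
    for s, stage in enumerate(config.stage_labels):
        for r in range(config.n_replicates_per_stage):
            noise = rng.normal(0.0, config.replicate_noise_sd, size=n)
            cols[f"{stage}_rep{r + 1}"] = stage_level[:, s] * np.exp(noise)
    return pd.DataFrame(cols)


def generate_dataset(
    config: SimulationConfig, with_fragments: bool = False
) -> SyntheticBundle:
    """Generate one coupled multi-omic bundle; identical seeds, identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_peaks
    chrom_sizes = {
        f"chr{c + 1}": config.chrom_length for c in range(config.n_chromosomes)
    }
    peak_df = _place_peaks(config, rng)
    peaks = PeakSet(peak_df)
    peak_ids = peaks.ids.tolist()
    d8 = config.day8_index
    stage_pos = config.stage_labels[d8 + 1]  # RFP-positive day-8 population
    stage_neg = config.stage_labels[d8]  # RFP-negative day-8 population

    modules = rng.choice(np.arange(1, 7), size=n, p=config.module_proportions)
    pats = config.canonical_patterns()
    pattern_mat = pats[modules - 1] if n else np.zeros((0, config.n_stages), dtype=np.int8)

    # accessibility: per-peak open/closed amplitudes shared across stages
    amp_open = rng.lognormal(config.open_signal_mean, config.open_signal_sd, size=n)
    amp_closed = rng.lognormal(config.closed_signal_mean, config.closed_signal_sd, size=n)
    atac_stage = np.where(pattern_mat == 1, amp_open[:, None], amp_closed[:, None])
    atac = _stage_replicate_matrix(atac_stage, config, rng)
    atac.index = pd.Index(peak_ids, name="peak_id")

    # background: closed-state draws, one per peak and sample
    bg_vals = rng.lognormal(
        config.closed_signal_mean,
        config.closed_signal_sd,
        size=(n, len(config.sample_names)),
    )
    background = pd.DataFrame(
        bg_vals,
        index=pd.Index([f"bg_{i + 1}" for i in range(n)], name="region_id"),
        columns=config.sample_names,
    )

    # genes: one per peak, TSS at the peak center
    centers = ((peak_df_sorted := peaks.df)["start"] + peak_df_sorted["end"]) // 2
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    gene_ids = [pid.replace("peak", "gene") for pid in peak_ids]
    tss = centers.to_numpy()
    span_start = np.where(strands == "+", tss, np.maximum(tss - GENE_LENGTH, 0))
    span_end = np.where(
        strands == "+",
        np.minimum(tss + GENE_LENGTH, config.chrom_length),
        tss,
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": peak_df_sorted["chrom"].to_numpy(),
            "strand": strands,
            "tss": tss,
            "span_start": span_start,
            "span_end": span_end,
        }
    )

    # expression: tracks chromatin except at the day-8 pair for discordant genes
    expr_pattern = pattern_mat.copy()
    shared_open = np.flatnonzero((pattern_mat[:, d8] == 1) & (pattern_mat[:, d8 + 1] == 1))
    n_up = int(round(config.discordant_up_fraction * len(shared_open)))
    n_down = int(round(config.discordant_down_fraction * len(shared_open)))
    chosen = rng.choice(shared_open, size=n_up + n_down, replace=False) if n_up + n_down else np.array([], dtype=int)
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]
    expr_pattern[up_idx, d8] = 0  # silent in RFP-negative despite open chromatin
    expr_pattern[up_idx, d8 + 1] = 1
    expr_pattern[down_idx, d8] = 1
    expr_pattern[down_idx, d8 + 1] = 0

    amp_hi = rng.lognormal(config.open_signal_mean, config.open_signal_sd, size=n)
    amp_lo = rng.lognormal(config.closed_signal_mean, config.closed_signal_sd, size=n)
    fpkm_stage = np.where(expr_pattern == 1, amp_hi[:, None], amp_lo[:, None])
    fpkm = _stage_replicate_matrix(fpkm_stage, config, rng)
    fpkm.index = pd.Index(gene_ids, name="gene_id")
    counts = pd.DataFrame(
        rng.poisson(fpkm.to_numpy() * (GENE_LENGTH / 1e3) * (RNA_LIBRARY_SIZE / 1e6)),
        index=fpkm.index,
        columns=fpkm.columns,
    )

    # histone-mark tracks for the two day-8 populations: marks follow the
    # expression state, with configured per-mark effects at discordant loci
    effects = {"H3K4me3": config.h3k4me3_effect, "H3K27ac": config.h3k27ac_effect}
    mark_base = {m: rng.lognormal(3.0, 0.5, size=n) for m in MARKS}
    mark_low = {m: rng.lognormal(0.7, 0.5, size=n) for m in MARKS}
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for mark in MARKS:
        half = 2 ** (effects[mark] / 2.0)
        for stage, s_idx in ((stage_neg, d8), (stage_pos, d8 + 1)):
            level = np.where(
                expr_pattern[:, s_idx] == 1, mark_base[mark], mark_low[mark]
            ).astype(float)
            level[up_idx] = mark_base[mark][up_idx] * (
                half if s_idx == d8 + 1 else 1.0 / half
            )
            level[down_idx] = mark_base[mark][down_idx] * (
                half if s_idx == d8 else 1.0 / half
            )
            tracks[(mark, stage)] = _render_track(
                peaks, level, chrom_sizes, rng
            )

    # replicate-level called peaks: the union peaks with light random dropout
    replicate_peaks = {}
    for sample in config.sample_names:
        keep = rng.random(n) >= REPLICATE_DROPOUT
        replicate_peaks[sample] = (
            PeakSet(peaks.df[keep].drop(columns="id")) if keep.any() else PeakSet.empty()
        )

    fragments = _simulate_fragments(peaks, atac, chrom_sizes, rng) if with_fragments else None

    truth = GroundTruth(
        peak_modules=pd.Series(modules, index=peak_ids, name="module"),
        patterns=pd.DataFrame(
            pattern_mat, index=pd.Index(peak_ids, name="peak_id"), columns=config.stage_labels
        ),
        discordant_up_genes=tuple(sorted(np.array(gene_ids)[up_idx])),
        discordant_down_genes=tuple(sorted(np.array(gene_ids)[down_idx])),
        true_threshold_band=config.true_threshold_band(),
    )
    return SyntheticBundle(
        config=config,
        peaks=peaks,
        chrom_sizes=chrom_sizes,
        atac=atac,
        background=background,
        expression_fpkm=fpkm,
        expression_counts=counts,
        genes=genes,
        tracks=tracks,
        replicate_peaks=replicate_peaks,
        fragments=fragments,
        truth=truth,
    )


def _render_track(
    peaks: PeakSet,
    level: np.ndarray,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binned coverage: low log-normal baseline plus a Gaussian bump per peak."""
    sigma = 300.0
    reach = 1000  # bp of bump on each side of the center
    frames = []
    for chrom, size in chrom_sizes.items():
        nbins = size // TRACK_BIN
        vals = rng.lognormal(np.log(0.2), 0.5, size=nbins)
        grp = peaks.df[peaks.df["chrom"] == chrom]
        idx_in_set = grp.index.to_numpy()
        centers = ((grp["start"] + grp["end"]) // 2).to_numpy()
        for i, c in zip(idx_in_set, centers):
            b0 = max((c - reach) // TRACK_BIN, 0)
            b1 = min((c + reach) // TRACK_BIN + 1, nbins)
            x = (np.arange(b0, b1) + 0.5) * TRACK_BIN
            vals[b0:b1] += level[i] * np.exp(-((x - c) ** 2) / (2 * sigma**2))
        starts = np.arange(nbins) * TRACK_BIN
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + TRACK_BIN, "value": vals}
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "value"]
    )


FRAGMENT_NOISE_RATE = 2e-4  # background fragments per bp per sample
FRAGMENT_LENGTH = 100


def _simulate_fragments(
    peaks: PeakSet,
    atac: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-sample fragment BED frames consistent with the RPKM matrix.

    Per peak and sample, fragment counts are Poisson with mean
    rpkm * length/1e3 (a nominal per-million library scale); a sparse uniform
    background adds closed-level signal genome-wide.
    """
    df = peaks.df
    lengths = (df["end"] - df["start"]).to_numpy()
    out = {}
    genome = int(sum(chrom_sizes.values()))
    chrom_names = list(chrom_sizes)
    chrom_offsets = np.concatenate([[0], np.cumsum([chrom_sizes[c] for c in chrom_names])])
    peak_chroms = df["chrom"].to_numpy()
    peak_starts = df["start"].to_numpy()
    spans = np.maximum(lengths - FRAGMENT_LENGTH, 1)
    for sample in atac.columns:
        lam = atac[sample].to_numpy() * lengths / 1e3
        counts = rng.poisson(lam)
        rep_start = np.repeat(peak_starts, counts)
        rep_span = np.repeat(spans, counts)
        starts = rep_start + (rng.random(len(rep_start)) * rep_span).astype(np.int64)
        rows = [
            pd.DataFrame(
                {
                    "chrom": np.repeat(peak_chroms, counts),
                    "start": starts,
                    "end": starts + FRAGMENT_LENGTH,
                }
            )
        ]
        n_noise = rng.poisson(FRAGMENT_NOISE_RATE * genome)
        pos = rng.integers(0, genome - FRAGMENT_LENGTH, size=n_noise)
        ci = np.searchsorted(chrom_offsets, pos, side="right") - 1
        rows.append(
            pd.DataFrame(
                {
                    "chrom": [chrom_names[c] for c in ci],
                    "start": pos - chrom_offsets[ci],
                    "end": pos - chrom_offsets[ci] + FRAGMENT_LENGTH,
                }
            )
        )
        frame = pd.concat(rows, ignore_index=True)
        out[sample] = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def sample_rpkm_mixture(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled peak and background RPKM draws under the configured mixture.

    Peak values are an open/closed log-normal mixture with open weight equal
    to the expected open-cell fraction of the module mix; background values
    are pure closed-state draws. Used for threshold-calibration studies
    without building a full bundle.
    """
    w_open = config.open_cell_fraction()
    is_open = rng.random(n) < w_open
    peak = np.where(
        is_open,
        rng.lognormal(config.open_signal_mean, config.open_signal_sd, size=n),
        rng.lognormal(config.closed_signal_mean, config.closed_signal_sd, size=n),
    )
    background = rng.lognormal(
        config.closed_signal_mean, config.closed_signal_sd, size=n
    )
    return peak, background


def synthetic_peak_table(
    n_peaks: int = 10000,
    threshold: float = 25.16,
    module_proportions: tuple[float, ...] = DEFAULT_MODULE_PROPORTIONS,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a published per-peak RPKM supplementary table.

    Builds a peak table with exact module composition (largest-remainder
    rounding of ``module_proportions``) whose per-stage RPKM values are drawn
    from the configured open/closed distributions conditioned on the correct
    side of ``threshold`` — the defining property of a table whose module
    labels were derived by thresholding at that value. SYNTHETIC: this is a
    generated object, not measured data.
    """
    if config is None:
        config = SimulationConfig(module_proportions=module_proportions)
    rng = np.random.default_rng(seed)
    counts = _largest_remainder(np.asarray(module_proportions), n_peaks)
    modules = np.repeat(np.arange(1, 7), counts)
    pats = config.canonical_patterns()[modules - 1]
    n_stages = config.n_stages
    vals = np.empty((n_peaks, n_stages))
    open_mask = pats == 1
    vals[open_mask] = _truncated_lognormal(
        rng, config.open_signal_mean, config.open_signal_sd, open_mask.sum(), low=threshold
    )
    vals[~open_mask] = _truncated_lognormal(
        rng,
        config.closed_signal_mean,
        config.closed_signal_sd,
        (~open_mask).sum(),
        high=threshold,
    )
    lengths = rng.integers(300, 800, size=n_peaks)
    starts = np.arange(n_peaks) * 1000
    table = pd.DataFrame(
        {
            "peak_id": [f"peak_{i + 1}" for i in range(n_peaks)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths,
        }
    )
    for s, stage in enumerate(config.stage_labels):
        table[stage] = vals[:, s]
    table["true_module"] = modules
    return table


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    raw = proportions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _truncated_lognormal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float | None = None,
    high: float | None = None,
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mean, sd, size=max(size - filled, 16))
        if low is not None:
            draw = draw[draw >= low]
        if high is not None:
            draw = draw[draw < high]
        take = min(len(draw), size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def write_fixtures(bundle: SyntheticBundle, directory) -> dict:
    """Serialize a bundle to plain-text fixtures; returns the file manifest.

    The manifest maps each written file to its row and column counts and is
    also written as ``manifest.json`` in the directory.
    """
    d = io.ensure_dir(directory)
    manifest: dict[str, dict] = {}

    def record(name: str, rows: int, cols: int):
        manifest[name] = {"rows": int(rows), "cols": int(cols)}

    bundle.peaks.to_bed(d / "peaks.bed")
    record("peaks.bed", len(bundle.peaks), 4)
    io.write_chrom_sizes(bundle.chrom_sizes, d / "chrom.sizes")
    record("chrom.sizes", len(bundle.chrom_sizes), 2)
    for name, df in (
        ("atac_rpkm.tsv", bundle.atac),
        ("background_rpkm.tsv", bundle.background),
        ("expression_fpkm.tsv", bundle.expression_fpkm),
        ("expression_counts.tsv", bundle.expression_counts),
    ):
        io.write_matrix(df, d / name)
        record(name, len(df), df.shape[1] if len(df.columns) else 0)
    io.write_gene_table(bundle.genes, d / "genes.tsv")
    record("genes.tsv", len(bundle.genes), len(io.GENE_TABLE_COLUMNS))

    design = pd.DataFrame(
        {"sample": list(bundle.config.stage_design), "stage": list(bundle.config.stage_design.values())}
    )
    design.to_csv(d / "stage_design.tsv", sep="\t", index=False)
    record("stage_design.tsv", len(design), 2)
    bundle.config.to_yaml(d / "sim_config.yaml")
    record("sim_config.yaml", 1, 1)

    rp_dir = io.ensure_dir(d / "replicate_peaks")
    for sample, ps in bundle.replicate_peaks.items():
        ps.to_bed(rp_dir / f"{sample}.bed")
        record(f"replicate_peaks/{sample}.bed", len(ps), 4)
    tr_dir = io.ensure_dir(d / "tracks")
    for (mark, stage), df in bundle.tracks.items():
        io.write_bedgraph(df, tr_dir / f"{mark}_{stage}.bedgraph")
        record(f"tracks/{mark}_{stage}.bedgraph", len(df), 4)
    if bundle.fragments:
        fr_dir = io.ensure_dir(d / "fragments")
        for sample, df in bundle.fragments.items():
            df.to_csv(fr_dir / f"{sample}.bed", sep="\t", header=False, index=False)
            record(f"fragments/{sample}.bed", len(df), 3)

    truth_frame = bundle.truth.patterns.copy()
    truth_frame.insert(0, "module", bundle.truth.peak_modules)
    truth_frame.to_csv(d / "truth_modules.tsv", sep="\t")
    record("truth_modules.tsv", len(truth_frame), truth_frame.shape[1])
    io.write_json(
        {
            "discordant_up_genes": list(bundle.truth.discordant_up_genes),
            "discordant_down_genes": list(bundle.truth.discordant_down_genes),
            "true_threshold_band": list(bundle.truth.true_threshold_band),
        },
        d / "truth_genes.json",
    )
    record("truth_genes.json", len(bundle.truth.discordant_up_genes) + len(bundle.truth.discordant_down_genes), 1)

    io.write_json(manifest, d / "manifest.json")
    return manifest
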