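"""Genes open in both day-8 populations but differentially expressed.

The comparison pair is the reporter-sorted day-8 populations (RFP-negative
vs RFP-positive). A gene is discordant when at least one of its peaks is
open in both populations with similar accessibility (|ATAC log2 fold
change| below a cap) while its expression differs strongly and
significantly between the two populations. Differential expression uses a
Welch two-sample t-test on log2(FPKM + 1) with Benjamini-Hochberg
correction; fold changes are computed from group means of FPKM + 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .occupancy import StateMatrix
from .quant import PeakSet


def shared_open_peaks(states: StateMatrix, stage_a: str, stage_b: str) -> pd.Index:
    """Ids of peaks open in both named stages."""
    for stage in (stage_a, stage_b):
        if stage not in states.states.columns:
            raise KeyError(f"unknown stage label {stage!r}")
    mask = (states.states[stage_a] == 1) & (states.states[stage_b] == 1)
    return states.states.index[mask]


def differential_expression(
    expression: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Welch test on log2(FPKM + 1) with BH correction.

    Returns a frame indexed by gene id with columns ``log2_fold_change``
    (log2 of (mean_a + 1) / (mean_b + 1) on the FPKM scale, positive when
    higher in group A), ``p_value`` and BH-adjusted ``q_value``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group for the Welch test")
    a = expression[group_a].to_numpy(dtype=float)
    b = expression[group_b].to_numpy(dtype=float)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance identical groups
    lfc = np.log2(a.mean(axis=1) + 1.0) - np.log2(b.mean(axis=1) + 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"log2_fold_change": lfc, "p_value": p, "q_value": q},
        index=expression.index,
    )


@dataclass
class DiscordanceResult:
    """Genes discordant between accessibility and expression at day 8."""

    up_genes: tuple[str, ...]  # higher expression in the RFP-positive population
    down_genes: tuple[str, ...]  # higher expression in the RFP-negative population
    table: pd.DataFrame  # per shared-open gene: peak, atac/rna log2FC, q

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene sets must be disjoint")


def find_discordant(
    shared: pd.Index | Sequence[str],
    atac_stage_signal: pd.DataFrame,
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    stage_pos: str,
    stage_neg: str,
    atac_fc_max: float = 0.5,
    rna_fc_min: float = 1.0,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> DiscordanceResult:
    """Route shared-open genes into discordant up/down sets.

    ``de`` must be oriented positive-vs-negative (log2FC > 0 means higher in
    the RFP-positive population). When a gene has several shared-open peaks
    the one with the largest mean accessibility represents it.
    """
    if atac_fc_max <= 0 or rna_fc_min <= 0 or not 0 < q_max <= 1:
        raise ValueError("thresholds must be positive (q_max in (0, 1])")
    shared_ids = pd.Index(shared)
    ann = annotation[annotation["peak_id"].isin(shared_ids)]
    if len(shared_ids) and ann.empty:
        raise ValueError("annotation does not cover any shared-open peak")

    sig = atac_stage_signal.loc[ann["peak_id"]]
    ann = ann.assign(
        mean_signal=sig[[stage_pos, stage_neg]].mean(axis=1).to_numpy(),
        atac_log2fc=np.log2(
            (sig[stage_pos].to_numpy() + pseudocount)
            / (sig[stage_neg].to_numpy() + pseudocount)
        ),
    )
    best = (
        ann.sort_values("mean_signal", ascending=False)
        .drop_duplicates("nearest_gene")
        .set_index("nearest_gene")
    )
    table = best.join(de, how="inner")[
        ["peak_id", "atac_log2fc", "log2_fold_change", "q_value"]
    ].rename(columns={"log2_fold_change": "rna_log2fc"})

    callable_mask = (
        (table["atac_log2fc"].abs() <= atac_fc_max)
        & (table["rna_log2fc"].abs() >= rna_fc_min)
        & (table["q_value"] <= q_max)
    )
    called = table[callable_mask]
    up = tuple(sorted(called.index[called["rna_log2fc"] > 0]))
    down = tuple(sorted(called.index[called["rna_log2fc"] < 0]))
    return DiscordanceResult(up_genes=up, down_genes=down, table=table.sort_index())
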