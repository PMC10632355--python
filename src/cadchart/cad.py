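"""Charting of chromatin accessibility dynamics into six modules.

Each peak's binary open/closed trajectory across the ordered stages (primed
state first, naive state last) is classified into one of six modules:

1. permanently open at every stage;
2. open in the primed state, then permanently lost (open-to-closed with no
   reopening);
3. closed in the primed state, open from the first day-8 stage through the
   end (the naive-specific opening class);
4. closed at both ends but transiently open in between (the transient
   TE/PrE-signature class);
5. permanently closed;
6. every remaining trajectory (the residual class).

The day-8 anchor index is configurable because modules 3 and 4 are defined
relative to the stage at which the reporter-sorted day-8 populations appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .occupancy import StateMatrix
from .quant import PeakSet

MODULES = (1, 2, 3, 4, 5, 6)

CATEGORY_PROMOTER = "promoter"
CATEGORY_GENIC = "genic"
CATEGORY_DISTAL = "distal_intergenic"


def classify_pattern(pattern: Sequence[int], day8_index: int = 1) -> int:
    """Assign one module label to a binary open/closed trajectory.

    ``pattern`` is ordered from the primed state to the naive state and must
    have length >= 3; ``day8_index`` is the position of the first day-8
    stage. Total: every pattern receives exactly one label, with module 6
    absorbing everything the explicit rules do not cover.
    """
    p = tuple(int(x) for x in pattern)
    n = len(p)
    if n < 3:
        raise ValueError("pattern must cover at least 3 stages")
    if not 1 <= day8_index < n:
        raise ValueError("day8_index out of range for this pattern length")
    if any(x not in (0, 1) for x in p):
        raise ValueError("pattern must be binary")

    if all(p):
        return 1
    if not any(p):
        return 5
    if p[0] == 1 and p[-1] == 0 and _never_reopens(p):
        return 2
    if p[0] == 0 and all(p[day8_index:]):
        return 3
    if p[0] == 0 and p[-1] == 0 and any(p[1:-1]):
        return 4
    return 6


def _never_reopens(p: tuple[int, ...]) -> bool:
    """True if no closed stage is ever followed by an open one."""
    seen_closed = False
    for x in p:
        if x == 0:
            seen_closed = True
        elif seen_closed:
            return False
    return True


@dataclass
class ModuleAssignment:
    """Peak-to-module labels with per-module and per-stage summaries."""

    labels: pd.Series  # peak id -> module label
    patterns: pd.Series  # peak id -> pattern string, e.g. "01100"
    counts: pd.Series  # module -> peak count (always over modules 1..6)
    proportions: pd.Series  # module -> fraction of peaks
    per_stage_open: pd.Series  # stage label -> number of open peaks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pattern": self.patterns, "module": self.labels})

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "proportion": self.proportions})


def chart_modules(states: StateMatrix, day8_index: int = 1) -> ModuleAssignment:
    """Classify every peak's trajectory and summarize the module composition."""
    mat = states.states.to_numpy()
    labels = np.array(
        [classify_pattern(row, day8_index=day8_index) for row in mat], dtype=int
    )
    label_s = pd.Series(labels, index=states.peak_ids, name="module")
    pattern_s = pd.Series(
        ["".join(str(int(v)) for v in row) for row in mat],
        index=states.peak_ids,
        name="pattern",
    )
    counts = label_s.value_counts().reindex(MODULES, fill_value=0)
    counts.index.name = "module"
    total = int(counts.sum())
    proportions = counts / total if total else counts.astype(float)
    per_stage_open = pd.Series(
        mat.sum(axis=0) if len(mat) else np.zeros(len(states.stage_labels), dtype=int),
        index=states.stage_labels,
        name="open_peaks",
    ).astype(int)
    return ModuleAssignment(
        labels=label_s,
        patterns=pattern_s,
        counts=counts,
        proportions=proportions,
        per_stage_open=per_stage_open,
    )


def annotate_peaks(
    peaks: PeakSet, genes: pd.DataFrame, promoter_window: int = 2000
) -> pd.DataFrame:
    """Annotate each peak with its nearest gene, signed TSS distance and category.

    The nearest gene minimizes |peak center - TSS|; ties break to the gene
    earlier in coordinate order. The signed distance is negative when the
    peak center lies upstream of the TSS on the gene's strand. Category is
    ``promoter`` within +/- ``promoter_window`` bp of the TSS, else ``genic``
    when the center falls inside the gene's merged-exon span, else
    ``distal_intergenic``.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("gene annotation is empty")
    required = {"gene_id", "chrom", "strand", "tss", "span_start", "span_end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation lacks columns: {sorted(missing)}")

    by_chrom = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        grp = grp.sort_values(["tss", "span_start", "gene_id"], kind="mergesort")
        by_chrom[chrom] = {
            "tss": grp["tss"].to_numpy(),
            "gene_id": grp["gene_id"].to_numpy(),
            "strand": grp["strand"].to_numpy(),
            "span_start": grp["span_start"].to_numpy(),
            "span_end": grp["span_end"].to_numpy(),
        }

    rows = []
    for iv in peaks:
        if iv.chrom not in by_chrom:
            raise ValueError(f"no gene annotation on chromosome {iv.chrom!r}")
        g = by_chrom[iv.chrom]
        tss = g["tss"]
        center = iv.center
        idx = int(np.searchsorted(tss, center))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(tss):
                d = abs(center - int(tss[j]))
                # strict < keeps the earlier (left) gene on exact ties
                if best is None or d < best[0]:
                    best = (d, j)
        d_abs, j = best
        # among genes sharing the chosen TSS, take the first in coordinate order
        j = int(np.searchsorted(tss, tss[j], side="left"))
        strand = g["strand"][j]
        signed = center - int(tss[j]) if strand == "+" else int(tss[j]) - center
        if d_abs <= promoter_window:
            category = CATEGORY_PROMOTER
        elif int(g["span_start"][j]) <= center < int(g["span_end"][j]):
            category = CATEGORY_GENIC
        else:
            category = CATEGORY_DISTAL
        rows.append((iv.id, g["gene_id"][j], signed, category))
    return pd.DataFrame(
        rows, columns=["peak_id", "nearest_gene", "distance_to_tss", "category"]
    )
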