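"""Genomic interval arithmetic, background shuffling and RPKM quantification.

The central container is :class:`PeakSet`, a thin wrapper around a sorted
chrom/start/end/id frame. Replicate peak sets are merged by per-base support
counting; background regions are drawn length-matched from the genomic space
left free by an exclusion set; read counting assigns each fragment by its
midpoint; RPKM is reads per kilobase of interval per million library
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io


class InfeasiblePlacementError(RuntimeError):
    """No legal genomic placement exists for a region of the given length."""


class InfeasibleGeometryError(RuntimeError):
    """The requested intervals cannot be placed without overlap."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class PeakSet:
    """An ordered collection of non-negative intervals with unique ids.

    Always sorted by (chrom, start); ids are preserved if supplied and
    otherwise assigned as ``peak_1..peak_n`` in sorted order.
    """

    def __init__(self, df: pd.DataFrame, id_prefix: str = "peak"):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"PeakSet frame lacks required column {col!r}")
        if len(df) and ((df["start"] < 0).any() or (df["end"] <= df["start"]).any()):
            raise ValueError("PeakSet contains invalid intervals")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if "id" not in df.columns or df["id"].isna().any():
            df["id"] = [f"{id_prefix}_{i + 1}" for i in range(len(df))]
        if df["id"].duplicated().any():
            raise ValueError("PeakSet ids are not unique")
        self._df = df[["chrom", "start", "end", "id"]]

    @classmethod
    def from_bed(cls, path, id_prefix: str = "peak") -> "PeakSet":
        df = io.read_bed(path)
        if "name" in df.columns:
            df = df.rename(columns={"name": "id"})
        return cls(df, id_prefix=id_prefix)

    @classmethod
    def empty(cls) -> "PeakSet":
        return cls(pd.DataFrame(columns=["chrom", "start", "end", "id"]))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ids(self) -> pd.Series:
        return self._df["id"]

    @property
    def lengths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()

    def to_bed(self, path) -> None:
        out = self._df[["chrom", "start", "end", "id"]]
        out.to_csv(path, sep="\t", header=False, index=False)

    def subset(self, ids: Iterable[str]) -> "PeakSet":
        wanted = set(ids)
        return PeakSet(self._df[self._df["id"].isin(wanted)])

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.id)

    def validate_bounds(self, chrom_sizes: Mapping[str, int]) -> None:
        for chrom, group in self._df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} absent from size table")
            if (group["end"] > chrom_sizes[chrom]).any():
                raise ValueError(f"interval beyond end of {chrom}")


def merge_replicate_peaks(
    replicate_peak_sets: Sequence[PeakSet], min_support: int = 2
) -> PeakSet:
    """Merge replicate peak sets, keeping positions supported by enough replicates.

    Support is counted per base pair across replicates (a replicate
    contributes at most 1 at any base because its own intervals are merged
    first); maximal runs with support >= ``min_support`` become the output
    intervals, with fresh ids.
    """
    if not replicate_peak_sets:
        raise ValueError("no replicate peak sets supplied")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    events: dict[str, list[np.ndarray]] = {}
    for ps in replicate_peak_sets:
        flat = _self_merge(ps.df)
        for chrom, grp in flat.groupby("chrom", sort=False):
            events.setdefault(chrom, []).append(
                np.stack([grp["start"].to_numpy(), grp["end"].to_numpy()])
            )

    rows = []
    for chrom in sorted(events):
        starts = np.concatenate([e[0] for e in events[chrom]])
        ends = np.concatenate([e[1] for e in events[chrom]])
        pos = np.concatenate([starts, ends])
        delta = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        # collapse equal positions so coverage is evaluated between breakpoints
        uniq, inverse = np.unique(pos, return_inverse=True)
        net = np.zeros(len(uniq), dtype=int)
        np.add.at(net, inverse, delta)
        cov = np.cumsum(net)
        supported = cov >= min_support
        run_start = None
        for i, flag in enumerate(supported):
            if flag and run_start is None:
                run_start = uniq[i]
            elif not flag and run_start is not None:
                rows.append((chrom, int(run_start), int(uniq[i])))
                run_start = None
        if run_start is not None:  # pragma: no cover - coverage always closes
            rows.append((chrom, int(run_start), int(uniq[-1])))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _self_merge(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals within one replicate."""
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _merged_exclusion(exclusion: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = _self_merge(exclusion.df) if len(exclusion) else exclusion.df
    out = {}
    for chrom, grp in merged.groupby("chrom", sort=False):
        out[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def shuffle_background(
    peaks: PeakSet,
    chrom_sizes: Mapping[str, int],
    exclusion: PeakSet,
    seed: int,
) -> PeakSet:
    """Draw length-matched background regions avoiding an exclusion set.

    For each input peak length the set of legal start positions (start
    ranges whose interval fits inside a chromosome without touching the
    exclusion set) is computed exactly, and a start is drawn uniformly from
    that set, so every feasible placement succeeds deterministically under
    the seed. Output count and length multiset equal the input's.
    """
    rng = np.random.default_rng(seed)
    if len(peaks) == 0:
        return PeakSet.empty()
    excl = _merged_exclusion(exclusion)
    chroms = list(chrom_sizes)

    # free gaps between exclusion intervals, per chromosome
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        size = int(chrom_sizes[chrom])
        if chrom in excl:
            s, e = excl[chrom]
            bounds = [0] + list(np.clip(np.stack([s, e], axis=1).ravel(), 0, size)) + [size]
            pairs = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
        else:
            pairs = [(0, size)]
        gaps[chrom] = [(a, b) for a, b in pairs if b > a]

    lengths = peaks.lengths
    placements: dict[int, list[tuple[str, int, int]]] = {}
    for length in np.unique(lengths):
        ranges = []  # (chrom, first legal start, number of legal starts)
        for chrom in chroms:
            for a, b in gaps[chrom]:
                n_starts = b - a - int(length) + 1
                if n_starts > 0:
                    ranges.append((chrom, a, n_starts))
        if not ranges:
            raise InfeasiblePlacementError(
                f"no legal placement for a region of length {int(length)}"
            )
        placements[int(length)] = ranges

    rows = []
    for i, length in enumerate(lengths):
        ranges = placements[int(length)]
        counts = np.array([r[2] for r in ranges], dtype=np.int64)
        total = counts.sum()
        u = int(rng.integers(total))
        j = int(np.searchsorted(np.cumsum(counts), u, side="right"))
        chrom, first, _ = ranges[j]
        offset = u - (int(np.cumsum(counts)[j - 1]) if j else 0)
        start = first + offset
        rows.append((chrom, start, start + int(length)))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), id_prefix="bg")


def count_reads_in_intervals(fragments: pd.DataFrame, intervals: PeakSet) -> np.ndarray:
    """Count fragments per interval by fragment-midpoint assignment.

    ``fragments`` is a BED-like frame (chrom, start, end). A fragment is
    counted for every interval its midpoint falls in, so each fragment is
    assigned at most once per interval and never double-counted within a
    non-overlapping interval set.
    """
    counts = np.zeros(len(intervals), dtype=np.int64)
    if len(intervals) == 0 or len(fragments) == 0:
        return counts
    mids_by_chrom = {
        chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
        for chrom, grp in fragments.groupby("chrom", sort=False)
    }
    df = intervals.df
    for chrom, grp in df.groupby("chrom", sort=False):
        mids = mids_by_chrom.get(chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, grp["end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    return counts


def compute_rpkm(
    counts: np.ndarray | Sequence[int],
    lengths: np.ndarray | Sequence[int],
    library_size: float,
) -> np.ndarray:
    """Reads per kilobase of interval per million library fragments.

    rpkm = count / ((length / 1e3) * (library_size / 1e6)). Invariant under
    joint rescaling of all counts and the library size.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if (lengths <= 0).any():
        raise ValueError("interval lengths must be positive")
    return counts / ((lengths / 1e3) * (library_size / 1e6))
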