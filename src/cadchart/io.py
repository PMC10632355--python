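"""Readers and writers for the plain-text formats used throughout the package.

All genomic coordinates are 0-based, half-open (the BED dialect). Matrices
travel as tab-separated files with a header row of sample names and the
feature id in the first column; in memory they are plain :class:`pandas.DataFrame`
objects indexed by feature id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd


class BedParseError(ValueError):
    """A BED record could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file into a frame with chrom/start/end[/name].

    Lines starting with ``track``, ``browser`` or ``#`` are skipped. Raises
    :class:`BedParseError` with the offending line number on malformed input.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, "fewer than 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(path, lineno, "non-integer start/end") from None
            if start < 0 or end <= start:
                raise BedParseError(path, lineno, f"invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else None
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if df["name"].isna().all():
        df = df.drop(columns=["name"])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "id") if c in df.columns][:4]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chromosome-size text (name, length in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(path, lineno, "expected name and length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix with a header row and feature ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph-like binned coverage: chrom, start, end, value."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "span_start", "span_end"]


def read_gene_table(path) -> pd.DataFrame:
    """Simplified gene annotation: id, chrom, strand, TSS, merged-exon span."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} lacks columns: {missing}")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def load_peak_table(path) -> pd.DataFrame:
    """Load a per-peak table (peak id, coordinates, per-stage RPKM columns).

    The expected layout mirrors published per-peak supplementary tables:
    columns ``peak_id, chrom, start, end`` followed by one RPKM column per
    stage (any further annotation columns are carried along untouched).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["peak_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} lacks columns: {missing}")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
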