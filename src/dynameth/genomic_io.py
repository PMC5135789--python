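"""Genomic intervals, CpG methylation call tables, and BED I/O.

All coordinates are 0-based, half-open (BED convention). CpG calls are
assumed strand-merged per CpG dinucleotide; ``read_cpg_calls`` offers an
option to collapse +/- records at ``pos`` and ``pos + 1`` by summing counts
for callers that emit per-strand cytosine records.

Chromosomes sort naturally: chr1 < chr2 < ... < chr22 < chrX < chrY, with
any other names falling back to lexicographic order after the autosomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "CpGCall",
    "SampleCallSet",
    "AnnotationTrack",
    "chrom_sort_key",
    "read_cpg_calls",
    "write_cpg_calls",
    "read_bed",
    "write_bed",
    "overlap_bp",
    "overlaps_any",
    "global_methylation",
]

_CHROM_NUM = re.compile(r"^(?:chr)?(\d+)$")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: numeric autosomes first, then names."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.start, self.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class CpGCall:
    """Methylation evidence at one CpG in one sample."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self):
        if self.total_reads < 1:
            raise ValidationError(f"total_reads must be >= 1, got {self.total_reads}")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValidationError(
                f"meth_reads {self.meth_reads} outside [0, {self.total_reads}]"
            )

    @property
    def level(self) -> float:
        return self.meth_reads / self.total_reads


class SampleCallSet:
    """Sorted, duplicate-free CpG calls for one sample.

    Backed by a DataFrame with columns chrom, pos, meth_reads, total_reads;
    iteration yields :class:`CpGCall` records in (chrom, pos) order.
    """

    def __init__(self, sample_id: str, df: pd.DataFrame | None = None):
        self.sample_id = sample_id
        if df is None:
            df = pd.DataFrame(
                {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
                 "meth_reads": pd.Series(dtype=np.int64),
                 "total_reads": pd.Series(dtype=np.int64)}
            )
        df = df[["chrom", "pos", "meth_reads", "total_reads"]].copy()
        if len(df):
            if (df["total_reads"] < 1).any():
                raise ValidationError("total_reads must be >= 1 for every CpG")
            if ((df["meth_reads"] < 0) | (df["meth_reads"] > df["total_reads"])).any():
                raise ValidationError("meth_reads must lie in [0, total_reads]")
            df = df.sort_values(
                "pos", kind="mergesort"
            ).sort_values(
                "chrom", key=lambda s: s.map(lambda c: chrom_sort_key(c)),
                kind="mergesort",
            )
            if df.duplicated(["chrom", "pos"]).any():
                raise ValidationError("duplicate (chrom, pos) in call set")
            df = df.reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[CpGCall]:
        for row in self.df.itertuples(index=False):
            yield CpGCall(row.chrom, int(row.pos), int(row.meth_reads),
                          int(row.total_reads))

    def __eq__(self, other) -> bool:
        return (isinstance(other, SampleCallSet)
                and self.sample_id == other.sample_id
                and self.df.equals(other.df))

    @property
    def levels(self) -> np.ndarray:
        return self.df["meth_reads"].to_numpy() / self.df["total_reads"].to_numpy()

    @classmethod
    def from_calls(cls, sample_id: str, calls: Iterable[CpGCall]) -> "SampleCallSet":
        rows = [(c.chrom, c.pos, c.meth_reads, c.total_reads) for c in calls]
        df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_reads", "total_reads"])
        return cls(sample_id, df if rows else None)


class AnnotationTrack:
    """A named collection of (possibly overlapping) genomic intervals."""

    def __init__(self, name: str, intervals: Iterable[GenomicInterval] = ()):
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _tree_for(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees.get(chrom)

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        """All track intervals sharing >= 1 base with ``region``."""
        tree = self._tree_for(region.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(region.start, region.end)]
        return sorted(hits, key=GenomicInterval.sort_key)

    def overlaps(self, region: GenomicInterval) -> bool:
        tree = self._tree_for(region.chrom)
        return tree is not None and bool(tree.overlap(region.start, region.end))


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps_any(region: GenomicInterval, track: AnnotationTrack) -> bool:
    """True iff some track interval shares at least one base with ``region``."""
    return track.overlaps(region)


def global_methylation(callset: SampleCallSet) -> float:
    """Overall methylation: summed methylated reads over summed total reads.

    Equals the coverage-weighted mean of per-CpG methylation levels.
    """
    if len(callset) == 0:
        raise ValidationError("global methylation undefined for an empty call set")
    df = callset.df
    return float(df["meth_reads"].sum() / df["total_reads"].sum())


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

CPG_HEADER = "#chrom\tpos\tmeth_reads\ttotal_reads\tlevel"


def read_cpg_calls(
    path,
    min_coverage: int = 1,
    sample_id: str | None = None,
    collapse_strands: bool = False,
) -> SampleCallSet:
    """Read a tab-separated CpG call table.

    Expected columns: chrom, pos (0-based), meth_reads, total_reads; a fifth
    level column, if present, is ignored and recomputed from the counts.
    Lines starting with ``#`` are headers/comments. Records with
    ``total_reads < min_coverage`` are dropped after optional strand
    collapsing (``collapse_strands`` sums +/- records at pos and pos + 1).
    """
    path = Path(path)
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, line_no,
                                 f"expected >= 4 tab-separated columns, got {len(parts)}")
            chrom = parts[0]
            try:
                pos, meth, total = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-integer field: {exc}") from None
            if pos < 0:
                raise ParseError(path, line_no, f"negative position {pos}")
            if meth > total:
                raise ParseError(
                    path, line_no, f"meth_reads {meth} exceeds total_reads {total}"
                )
            if meth < 0:
                raise ParseError(path, line_no, f"negative meth_reads {meth}")
            rows.append((chrom, pos, meth, total))

    if collapse_strands and rows:
        rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
        merged: list[tuple[str, int, int, int]] = []
        i = 0
        while i < len(rows):
            chrom, pos, meth, total = rows[i]
            if (i + 1 < len(rows) and rows[i + 1][0] == chrom
                    and rows[i + 1][1] == pos + 1):
                meth += rows[i + 1][2]
                total += rows[i + 1][3]
                i += 2
            else:
                i += 1
            merged.append((chrom, pos, meth, total))
        rows = merged

    rows = [r for r in rows if r[3] >= min_coverage and r[3] >= 1]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_reads", "total_reads"])
    return SampleCallSet(sample_id or path.stem, df if rows else None)


def write_cpg_calls(callset: SampleCallSet, path) -> None:
    """Write a call set as a sorted, tab-separated table (deterministic)."""
    with open(path, "w") as fh:
        fh.write(CPG_HEADER + "\n")
        for row in callset.df.itertuples(index=False):
            level = row.meth_reads / row.total_reads
            fh.write(f"{row.chrom}\t{row.pos}\t{row.meth_reads}\t{row.total_reads}"
                     f"\t{level:.6g}\n")


def read_bed(path, name: str | None = None) -> AnnotationTrack:
    """Read a BED3+ file (0-based half-open) into an :class:`AnnotationTrack`."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, line_no,
                                 f"expected >= 3 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-integer coordinate: {exc}") from None
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            try:
                intervals.append(GenomicInterval(parts[0], start, end, label))
            except ValidationError as exc:
                raise ParseError(path, line_no, str(exc)) from None
    return AnnotationTrack(name or path.stem, intervals)


def write_bed(track: AnnotationTrack | Sequence[GenomicInterval], path,
              scores: Sequence[float] | None = None,
              strands: Sequence[str] | None = None) -> None:
    """Write intervals as BED (BED4, or BED6 when scores/strands given)."""
    intervals = list(track)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name or "."]
            if scores is not None or strands is not None:
                score = scores[i] if scores is not None else 0
                strand = strands[i] if strands is not None else "."
                cols += [str(score), strand]
            fh.write("\t".join(cols) + "\n")
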