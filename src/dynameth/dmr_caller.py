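"""Tile-based differential-methylation calling on targeted bisulfite data.

The pipeline tiles a capture panel on a fixed 200-bp genome grid, pools
CpG counts per tile and sample (the pooled ratio equals the
coverage-weighted mean of per-CpG levels), keeps tiles covered by more
than 10 reads in at least 70% of samples, tests every sample pair per tile
with a two-sided Fisher's exact test, corrects per pair with
Benjamini-Hochberg, and merges significant tiles (q <= 0.05 and
|delta| >= 0.3) into DMRs when they are less than 400 bp apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .genomic_io import GenomicInterval, SampleCallSet, chrom_sort_key
from .panel_design import Panel

__all__ = [
    "TileMatrix",
    "PairwiseResult",
    "DMR",
    "make_tiles",
    "aggregate_tile_counts",
    "coverage_filter",
    "fisher_exact",
    "bh_adjust",
    "pairwise_tests",
    "call_pairwise_dmrs",
    "dynamic_fraction",
    "match_dmr_sets",
]

DEFAULT_TILE_SIZE = 200


@dataclass
class TileMatrix:
    """Per-tile, per-sample pooled methylation counts.

    ``meth`` and ``total`` are (n_tiles, n_samples) integer arrays of
    summed methylated / total CpG read counts; a tile-sample cell with
    total 0 has no data (its level is NaN).
    """

    tiles: list[GenomicInterval]
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    tile_size: int = DEFAULT_TILE_SIZE

    def __post_init__(self):
        n, m = len(self.tiles), len(self.samples)
        if self.meth.shape != (n, m) or self.total.shape != (n, m):
            raise ValidationError("count arrays must be (n_tiles, n_samples)")
        if (self.meth > self.total).any() or (self.meth < 0).any():
            raise ValidationError("meth counts must lie in [0, total]")

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    @property
    def levels(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1),
                            np.nan)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None

    def subset(self, mask: np.ndarray) -> "TileMatrix":
        idx = np.flatnonzero(mask)
        return TileMatrix([self.tiles[i] for i in idx], list(self.samples),
                          self.meth[idx], self.total[idx], self.tile_size)

    def to_frame(self) -> pd.DataFrame:
        data = {"chrom": [t.chrom for t in self.tiles],
                "start": [t.start for t in self.tiles],
                "end": [t.end for t in self.tiles]}
        levels = self.levels
        for j, s in enumerate(self.samples):
            data[f"{s}.meth"] = self.meth[:, j]
            data[f"{s}.total"] = self.total[:, j]
            data[f"{s}.level"] = levels[:, j]
        return pd.DataFrame(data)


@dataclass
class PairwiseResult:
    """One tile's Fisher test for one sample pair."""

    tile: GenomicInterval
    sample_a: str
    sample_b: str
    delta: float          # level(a) - level(b)
    p_value: float
    q_value: float
    significant: bool


@dataclass
class DMR:
    """A merged run of significant tiles for one sample pair."""

    interval: GenomicInterval
    sample_a: str
    sample_b: str
    direction: str        # 'hypo' or 'hyper' in sample_a relative to sample_b
    tiles: list[GenomicInterval]
    min_q: float


def make_tiles(panel: Panel | Iterable[GenomicInterval],
               tile_size: int = DEFAULT_TILE_SIZE) -> list[GenomicInterval]:
    """Fixed-grid tiles ``[k*s, (k+1)*s)`` sharing >= 1 base with the panel.

    Tiles are anchored to multiples of ``tile_size`` genome-wide and are
    never clipped to region boundaries, so tiles are comparable across
    panels. Output is sorted and unique.
    """
    if tile_size <= 0:
        raise ValidationError(f"tile_size must be positive, got {tile_size}")
    seen: set[tuple[str, int]] = set()
    for region in panel:
        first = region.start // tile_size
        last = (region.end - 1) // tile_size
        for k in range(first, last + 1):
            seen.add((region.chrom, k))
    tiles = [GenomicInterval(chrom, k * tile_size, (k + 1) * tile_size)
             for chrom, k in seen]
    tiles.sort(key=GenomicInterval.sort_key)
    return tiles


def aggregate_tile_counts(tiles: Sequence[GenomicInterval],
                          callsets: Sequence[SampleCallSet],
                          tile_size: int = DEFAULT_TILE_SIZE) -> TileMatrix:
    """Pool CpG counts into tiles per sample.

    The tile level meth/total is the coverage-weighted methylation mean:
    summing counts weights each CpG's level by its coverage.
    """
    samples = [cs.sample_id for cs in callsets]
    n, m = len(tiles), len(samples)
    meth = np.zeros((n, m), dtype=np.int64)
    total = np.zeros((n, m), dtype=np.int64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = sorted({t.chrom for t in tiles}, key=chrom_sort_key)
    for chrom in chroms:
        idx = np.array([i for i, t in enumerate(tiles) if t.chrom == chrom])
        starts = np.array([tiles[i].start for i in idx])
        by_chrom[chrom] = (starts, idx)

    for j, cs in enumerate(callsets):
        df = cs.df
        for chrom, (starts, idx) in by_chrom.items():
            sub = df[df["chrom"] == chrom]
            if not len(sub):
                continue
            pos = sub["pos"].to_numpy()
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = (k >= 0) & (pos < starts[np.clip(k, 0, len(starts) - 1)] + tile_size)
            k = k[ok]
            rows = idx[k]
            np.add.at(meth[:, j], rows, sub["meth_reads"].to_numpy()[ok])
            np.add.at(total[:, j], rows, sub["total_reads"].to_numpy()[ok])
    return TileMatrix(list(tiles), samples, meth, total, tile_size)


def coverage_filter(matrix: TileMatrix, min_reads: int = 10,
                    min_sample_frac: float = 0.7) -> TileMatrix:
    """Keep tiles covered by more than ``min_reads`` in enough samples.

    A sample counts toward retention only with total reads strictly above
    ``min_reads``; a tile is retained when the count of such samples is at
    least ``min_sample_frac`` of all samples (inclusive).
    """
    n_ok = (matrix.total > min_reads).sum(axis=1)
    keep = n_ok >= min_sample_frac * len(matrix.samples)
    return matrix.subset(keep)


def fisher_exact(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table of counts.

    ``a`` and ``b`` are (methylated, unmethylated) counts for the two
    samples. The two-sided p follows the probability-mass rule: the sum of
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one. Computed in exact integer
    arithmetic, so ties are decided exactly.
    """
    am, au = a
    bm, bu = b
    if min(am, au, bm, bu) < 0:
        raise ValidationError("Fisher table counts must be non-negative")
    r1, r2 = am + au, bm + bu
    if r1 < 1 or r2 < 1:
        raise ValidationError("each sample needs >= 1 read")
    c1 = am + bm
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs_w = math.comb(r1, am) * math.comb(r2, bm)
    num = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs_w:
            num += w
    return num / math.comb(r1 + r2, c1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_tests(matrix: TileMatrix, sample_a: str, sample_b: str,
                   q_max: float = 0.05, delta_min: float = 0.3,
                   delta_inclusive: bool = True) -> list[PairwiseResult]:
    """Fisher + BH for one sample pair across all tiles with data in both.

    Tiles where either sample has zero reads are skipped (no test). BH
    correction is applied across the tested tiles of this pair only.
    """
    ia, ib = matrix.sample_index(sample_a), matrix.sample_index(sample_b)
    tested = np.flatnonzero((matrix.total[:, ia] > 0) & (matrix.total[:, ib] > 0))
    results: list[PairwiseResult] = []
    pvals = np.empty(len(tested))
    deltas = np.empty(len(tested))
    for out_i, i in enumerate(tested):
        am, at = int(matrix.meth[i, ia]), int(matrix.total[i, ia])
        bm, bt = int(matrix.meth[i, ib]), int(matrix.total[i, ib])
        pvals[out_i] = fisher_exact((am, at - am), (bm, bt - bm))
        deltas[out_i] = am / at - bm / bt
    qvals = bh_adjust(pvals) if len(tested) else pvals
    for out_i, i in enumerate(tested):
        abs_d = abs(deltas[out_i])
        passes_delta = abs_d >= delta_min if delta_inclusive else abs_d > delta_min
        results.append(PairwiseResult(
            tile=matrix.tiles[i], sample_a=sample_a, sample_b=sample_b,
            delta=float(deltas[out_i]), p_value=float(pvals[out_i]),
            q_value=float(qvals[out_i]),
            significant=bool(qvals[out_i] <= q_max and passes_delta)))
    return results


def call_pairwise_dmrs(matrix: TileMatrix, sample_a: str, sample_b: str,
                       q_max: float = 0.05, delta_min: float = 0.3,
                       merge_dist: int = 400,
                       delta_inclusive: bool = True) -> list[DMR]:
    """Call and merge DMRs between two samples.

    Significant tiles (q <= q_max and |delta| >= delta_min) with an
    inter-tile gap strictly less than ``merge_dist`` and the same direction
    are merged into one DMR spanning the member tiles.
    """
    results = pairwise_tests(matrix, sample_a, sample_b, q_max, delta_min,
                             delta_inclusive)
    sig = [r for r in results if r.significant]
    sig.sort(key=lambda r: r.tile.sort_key())
    dmrs: list[DMR] = []
    run: list[PairwiseResult] = []

    def flush():
        if not run:
            return
        tiles = [r.tile for r in run]
        direction = "hypo" if run[0].delta < 0 else "hyper"
        dmrs.append(DMR(
            interval=GenomicInterval(tiles[0].chrom, tiles[0].start,
                                     tiles[-1].end,
                                     f"{sample_a}_vs_{sample_b}"),
            sample_a=sample_a, sample_b=sample_b, direction=direction,
            tiles=tiles, min_q=min(r.q_value for r in run)))

    for r in sig:
        if run:
            prev = run[-1]
            same_dir = (r.delta < 0) == (prev.delta < 0)
            gap = r.tile.start - prev.tile.end
            if r.tile.chrom == prev.tile.chrom and gap < merge_dist and same_dir:
                run.append(r)
                continue
            flush()
            run = []
        run.append(r)
    flush()
    return dmrs


def dynamic_fraction(matrix: TileMatrix, q_max: float = 0.05,
                     delta_min: float = 0.3,
                     delta_inclusive: bool = True) -> float:
    """Fraction of tiles significant in at least one pairwise comparison.

    Runs every sample pair (with its own BH correction) and reports the
    share of the matrix's tiles that are dynamic; the remainder is static.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("dynamic_fraction needs >= 2 samples")
    if matrix.n_tiles == 0:
        return 0.0
    tile_key = {(t.chrom, t.start): i for i, t in enumerate(matrix.tiles)}
    dynamic = np.zeros(matrix.n_tiles, dtype=bool)
    for a, b in combinations(matrix.samples, 2):
        for r in pairwise_tests(matrix, a, b, q_max, delta_min, delta_inclusive):
            if r.significant:
                dynamic[tile_key[(r.tile.chrom, r.tile.start)]] = True
    return float(dynamic.mean())


def _nearest_distance(iv: GenomicInterval,
                      ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]
                      ) -> float:
    arrs = ref_by_chrom.get(iv.chrom)
    if arrs is None:
        return math.inf
    starts, ends = arrs
    gaps = np.maximum.reduce([starts - iv.end, iv.start - ends,
                              np.zeros_like(starts)])
    return float(gaps.min())


def match_dmr_sets(query: Sequence[DMR | GenomicInterval],
                   reference: Sequence[GenomicInterval],
                   within_bp: int = 300
                   ) -> tuple[list, list]:
    """Split query DMRs into (shared, query_only) by proximity to reference.

    A query DMR is *shared* when its distance to the nearest reference
    interval is at most ``within_bp`` (overlap counts as distance 0).
    """
    ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by: dict[str, list[GenomicInterval]] = {}
    for iv in reference:
        by.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by.items():
        ivs.sort(key=lambda v: v.start)
        ref_by_chrom[chrom] = (np.array([v.start for v in ivs]),
                               np.array([v.end for v in ivs]))
    shared, query_only = [], []
    for item in query:
        iv = item.interval if isinstance(item, DMR) else item
        if _nearest_distance(iv, ref_by_chrom) <= within_bp:
            shared.append(item)
        else:
            query_only.append(item)
    return shared, query_only


def write_dmr_bed(dmrs: Sequence[DMR], path, q_cap: float = 1e-30) -> None:
    """Write DMRs as BED6: name = pair, score = -log10 q (capped), strand
    '+' for hyper / '-' for hypo in the first sample."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = int(-math.log10(max(d.min_q, q_cap)) * 10)
            strand = "+" if d.direction == "hyper" else "-"
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                     f"\t{d.sample_a}_vs_{d.sample_b}\t{score}\t{strand}\n")
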