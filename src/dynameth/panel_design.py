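"""Capture-panel design from candidate differentially methylated regions.

The procedure mirrors the design of a dynamic-methylome capture assay:

1. filter candidate DMRs on repeat content, number of dynamic CpGs,
   region length and chromosome (autosomes only by default);
2. score survivors by three min-max-rescaled components — dynamic-CpG
   density, maximum pairwise methylation difference, and overlap with a
   putative enhancer or promoter — summed into a score in [0, 3];
3. assign each region an *origin* (the sample in which it is most
   hypomethylated) and select greedily under a byte budget while keeping
   the cumulative bases per origin balanced;
4. rescue unselected regions that overlap eQTL intervals;
5. merge all selections into a sorted, non-overlapping panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genomic_io import (AnnotationTrack, GenomicInterval, chrom_sort_key,
                         overlaps_any, read_bed)

__all__ = [
    "CandidateRegion",
    "ScoredRegion",
    "Panel",
    "DesignConfig",
    "dynamic_cpg_count",
    "filter_candidates",
    "score_regions",
    "assign_origin",
    "balanced_select",
    "eqtl_augment",
    "assemble_panel",
    "panel_summary",
    "design_panel",
    "read_candidate_regions",
    "write_panel_bed",
]


@dataclass
class CandidateRegion:
    """A candidate DMR with per-sample methylation evidence.

    ``sample_levels`` maps sample id to the region-mean methylation level;
    ``cpg_levels`` maps sample id to per-CpG levels (one entry per CpG, in
    a consistent order across samples). ``repeat_frac`` is the fraction of
    bases covered by repeat annotation.
    """

    interval: GenomicInterval
    source: str
    sample_levels: Mapping[str, float]
    cpg_levels: Mapping[str, Sequence[float]]
    repeat_frac: float

    def __post_init__(self):
        if not self.sample_levels:
            raise ValidationError("candidate region needs >= 1 sample level")
        if not 0.0 <= self.repeat_frac <= 1.0:
            raise ValidationError(f"repeat_frac {self.repeat_frac} outside [0, 1]")
        n_cpgs = {len(v) for v in self.cpg_levels.values()}
        if len(n_cpgs) > 1:
            raise ValidationError("cpg_levels ragged across samples")
        if self.cpg_levels and next(iter(n_cpgs)) == 0:
            raise ValidationError("candidate region needs >= 1 CpG")
        for levels in list(self.cpg_levels.values()) + [list(self.sample_levels.values())]:
            arr = np.asarray(levels, dtype=float)
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise ValidationError("methylation levels must lie in [0, 1]")

    @property
    def n_cpgs(self) -> int:
        if not self.cpg_levels:
            return 0
        return len(next(iter(self.cpg_levels.values())))


@dataclass
class ScoredRegion:
    region: CandidateRegion
    n_dynamic_cpgs: int
    density: float           # dynamic CpGs per bp
    max_diff: float          # max pairwise region-mean difference
    overlap_flag: int        # 1 iff enhancer-or-promoter overlap
    score: float             # sum of the three unit-rescaled components
    origin: str              # sample with minimum region methylation

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval


@dataclass
class Panel:
    """Sorted, non-overlapping capture target intervals with provenance."""

    regions: list[GenomicInterval]
    total_bp: int
    n_regions: int

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "Panel":
        regions = sorted(intervals, key=GenomicInterval.sort_key)
        return cls(regions, sum(len(r) for r in regions), len(regions))

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return self.n_regions

    def as_track(self, name: str = "panel") -> AnnotationTrack:
        return AnnotationTrack(name, self.regions)


@dataclass
class DesignConfig:
    """Filter and selection parameters for panel design.

    Defaults follow the published design: repeat content <= 60%, at least
    two dynamic CpGs (pairwise difference >= 0.3), length >= 100 bp, sex
    chromosomes excluded.
    """

    diff_threshold: float = 0.3
    repeat_max: float = 0.6
    repeat_inclusive: bool = True    # <= vs strict <
    min_dynamic_cpgs: int = 2
    min_length_bp: int = 100
    budget_bp: int | None = None
    exclude_chroms: frozenset[str] = frozenset({"chrX", "chrY", "X", "Y"})

    def __post_init__(self):
        if not 0 < self.diff_threshold <= 1:
            raise ValidationError("diff_threshold must be in (0, 1]")
        if not 0 <= self.repeat_max <= 1:
            raise ValidationError("repeat_max must be in [0, 1]")
        if self.min_dynamic_cpgs < 0 or self.min_length_bp < 0:
            raise ValidationError("minimum thresholds must be non-negative")


def dynamic_cpg_count(region: CandidateRegion, diff_threshold: float = 0.3) -> int:
    """Number of CpGs whose level spread across samples meets the threshold.

    A CpG is *dynamic* when its (max - min) methylation level over the
    samples is at least ``diff_threshold``.
    """
    if len(region.cpg_levels) < 2:
        raise ValidationError(
            "dynamic CpG count needs >= 2 samples (no pairwise difference "
            f"defined for region {region.interval.name or region.interval}"
            ")"
        )
    mat = np.asarray([region.cpg_levels[s] for s in sorted(region.cpg_levels)],
                     dtype=float)
    spread = np.nanmax(mat, axis=0) - np.nanmin(mat, axis=0)
    return int(np.sum(spread >= diff_threshold))


def filter_candidates(candidates: Sequence[CandidateRegion],
                      config: DesignConfig) -> list[CandidateRegion]:
    """Apply the capture-suitability filters; input order is preserved."""
    kept = []
    for cand in candidates:
        if cand.interval.chrom in config.exclude_chroms:
            continue
        if config.repeat_inclusive:
            if cand.repeat_frac > config.repeat_max:
                continue
        elif cand.repeat_frac >= config.repeat_max:
            continue
        if len(cand.interval) < config.min_length_bp:
            continue
        if dynamic_cpg_count(cand, config.diff_threshold) < config.min_dynamic_cpgs:
            continue
        kept.append(cand)
    return kept


def assign_origin(region: CandidateRegion) -> str:
    """Sample with the minimum region-mean methylation (ties: smallest id)."""
    return min(region.sample_levels, key=lambda s: (region.sample_levels[s], s))


def _minmax(values: np.ndarray) -> np.ndarray:
    # A non-discriminating component (constant across the set) is mapped to
    # all-zero so it adds no rank information.
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def score_regions(filtered: Sequence[CandidateRegion],
                  enhancer_track: AnnotationTrack,
                  promoter_track: AnnotationTrack,
                  diff_threshold: float = 0.3) -> list[ScoredRegion]:
    """Score regions by the three-component rescaled sum; sort descending.

    Components, each min-max rescaled to [0, 1] across the input set:
    dynamic-CpG density (count per bp), maximum pairwise region-mean
    methylation difference, and a 0/1 enhancer-or-promoter overlap flag.
    """
    if not filtered:
        raise ValidationError("score_regions needs >= 1 region")
    n_dyn = np.array([dynamic_cpg_count(r, diff_threshold) for r in filtered])
    length = np.array([len(r.interval) for r in filtered], dtype=float)
    density = n_dyn / length
    max_diff = np.array([
        max(r.sample_levels.values()) - min(r.sample_levels.values())
        for r in filtered
    ])
    flag = np.array([
        int(overlaps_any(r.interval, enhancer_track)
            or overlaps_any(r.interval, promoter_track))
        for r in filtered
    ])
    score = _minmax(density) + _minmax(max_diff) + _minmax(flag.astype(float))
    scored = [
        ScoredRegion(region=r, n_dynamic_cpgs=int(n_dyn[i]),
                     density=float(density[i]), max_diff=float(max_diff[i]),
                     overlap_flag=int(flag[i]), score=float(score[i]),
                     origin=assign_origin(r))
        for i, r in enumerate(filtered)
    ]
    scored.sort(key=lambda s: (-s.score, s.interval.sort_key()))
    return scored


def balanced_select(scored: Sequence[ScoredRegion], budget_bp: int) -> Panel:
    """Greedy selection under a base-pair budget with balanced origins.

    At each step the origin with the smallest cumulative selected bases
    (lexicographic tie-break) that still has candidates contributes its
    highest-scoring remaining region. This deliberately skips globally
    higher-scoring regions whose origin is already well represented.
    Selection stops once the budget is reached; the budget-crossing region
    is kept.
    """
    if budget_bp <= 0:
        raise ValidationError(f"budget_bp must be positive, got {budget_bp}")
    queues: dict[str, list[ScoredRegion]] = {}
    for sr in scored:  # input is sorted descending by score
        queues.setdefault(sr.origin, []).append(sr)
    for q in queues.values():
        q.reverse()  # pop() from the end == best remaining

    cum_bp = {origin: 0 for origin in queues}
    selected: list[ScoredRegion] = []
    total = 0
    while total < budget_bp and any(queues.values()):
        origin = min((o for o in queues if queues[o]),
                     key=lambda o: (cum_bp[o], o))
        sr = queues[origin].pop()
        selected.append(sr)
        cum_bp[origin] += len(sr.interval)
        total += len(sr.interval)
    panel = Panel.from_intervals(sr.interval for sr in selected)
    panel.selection_order = selected  # provenance for reports
    return panel


def eqtl_augment(remaining: Sequence[ScoredRegion],
                 eqtl_track: AnnotationTrack) -> list[ScoredRegion]:
    """Unselected regions overlapping (>= 1 bp) an eQTL interval, rank kept."""
    return [sr for sr in remaining if overlaps_any(sr.interval, eqtl_track)]


def assemble_panel(selections: Sequence[Sequence]) -> Panel:
    """Union of region lists; overlapping intervals merged, provenance kept.

    Accepts lists of :class:`ScoredRegion` or bare :class:`GenomicInterval`.
    Intervals sharing >= 1 base are merged into one; half-open bookends
    (end == start) are *not* merged. Provenance labels are concatenated.
    """
    flat: list[GenomicInterval] = []
    for lst in selections:
        for item in lst:
            iv = item.interval if hasattr(item, "interval") else item
            flat.append(iv)
    if not flat:
        return Panel([], 0, 0)
    flat.sort(key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = flat[0].chrom, flat[0].start, flat[0].end
    cur_names: list[str] = [flat[0].name] if flat[0].name else []
    for iv in flat[1:]:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
            if iv.name and iv.name not in cur_names:
                cur_names.append(iv.name)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end,
                                          ",".join(cur_names) or None))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_names = [iv.name] if iv.name else []
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end,
                                  ",".join(cur_names) or None))
    return Panel.from_intervals(merged)


def panel_summary(panel: Panel, tracks: Sequence[AnnotationTrack],
                  cpg_positions: Mapping[str, Sequence[int]] | None = None
                  ) -> pd.DataFrame:
    """Overlap summary of a panel against annotation tracks.

    Returns one row per track with the number and fraction of track
    features overlapped by the panel, and the fraction of panel regions
    overlapping the track. A leading row reports panel totals (n_regions,
    total_bp, and the number of supplied CpG positions inside the panel).
    """
    panel_track = panel.as_track()
    n_cpgs_in = 0
    if cpg_positions:
        for chrom, positions in cpg_positions.items():
            pos = np.asarray(positions)
            for iv in panel.regions:
                if iv.chrom == chrom:
                    n_cpgs_in += int(np.sum((pos >= iv.start) & (pos < iv.end)))
    rows = [{"track": "(panel)", "n_features": panel.n_regions,
             "n_overlapped": panel.n_regions, "pct_track_covered": 1.0,
             "pct_panel_overlapping": 1.0, "total_bp": panel.total_bp,
             "n_cpgs_in_panel": n_cpgs_in}]
    for track in tracks:
        n_feat = len(track)
        n_hit = sum(1 for iv in track if panel_track.overlaps(iv))
        n_panel_hit = sum(1 for iv in panel.regions if track.overlaps(iv))
        rows.append({
            "track": track.name,
            "n_features": n_feat,
            "n_overlapped": n_hit,
            "pct_track_covered": n_hit / n_feat if n_feat else 0.0,
            "pct_panel_overlapping":
                n_panel_hit / panel.n_regions if panel.n_regions else 0.0,
            "total_bp": sum(len(iv) for iv in track),
            "n_cpgs_in_panel": n_cpgs_in,
        })
    return pd.DataFrame(rows)


def design_panel(candidate_sets: Mapping[str, Sequence[CandidateRegion]],
                 enhancer_track: AnnotationTrack,
                 promoter_track: AnnotationTrack,
                 eqtl_track: AnnotationTrack | None,
                 config: DesignConfig,
                 budgets_bp: Mapping[str, int]) -> Panel:
    """Full design pipeline over one or more candidate source sets.

    Each source set is filtered, scored and budget-selected independently
    (with eQTL rescue from its ranked remainder); the selections are then
    merged into one panel.
    """
    selections: list[list[ScoredRegion]] = []
    for source, candidates in candidate_sets.items():
        filtered = filter_candidates(candidates, config)
        if not filtered:
            continue
        scored = score_regions(filtered, enhancer_track, promoter_track,
                               config.diff_threshold)
        budget = budgets_bp.get(source, config.budget_bp)
        if budget is None:
            raise ValidationError(f"no budget for candidate source {source!r}")
        panel = balanced_select(scored, budget)
        picked = panel.selection_order
        selections.append(picked)
        if eqtl_track is not None:
            chosen = {id(sr) for sr in picked}
            remaining = [sr for sr in scored if id(sr) not in chosen]
            selections.append(eqtl_augment(remaining, eqtl_track))
    return assemble_panel(selections)


# ---------------------------------------------------------------------------
# File-level interfaces
# ---------------------------------------------------------------------------

def read_candidate_regions(regions_bed, sample_levels_tsv,
                           cpg_levels_tsv=None, source: str | None = None,
                           ) -> list[CandidateRegion]:
    """Load candidates from a BED file plus companion level tables.

    ``sample_levels_tsv``: region_id x sample matrix of region-mean levels.
    ``cpg_levels_tsv`` (optional): long table with columns region_id,
    sample, cpg_index, level. Regions lacking per-CpG levels fall back to
    replicating the region mean for each of ``n_cpgs`` (column 5 of the
    BED, when present). The BED name column must match region_id.
    """
    track = read_bed(regions_bed)
    levels = pd.read_csv(sample_levels_tsv, sep="\t", index_col=0)
    repeat_col = None
    if "repeat_frac" in levels.columns:
        repeat_col = levels.pop("repeat_frac")
    cpg_long = None
    if cpg_levels_tsv is not None:
        cpg_long = pd.read_csv(cpg_levels_tsv, sep="\t")
        cpg_long = {rid: g for rid, g in cpg_long.groupby("region_id")}
    out = []
    for iv in track:
        rid = iv.name
        if rid is None or rid not in levels.index:
            raise ValidationError(f"region {iv} missing from sample-level table")
        sample_levels = levels.loc[rid].dropna().to_dict()
        if cpg_long is not None and rid in cpg_long:
            g = cpg_long[rid].sort_values("cpg_index")
            cpg_levels = {s: sg["level"].tolist() for s, sg in g.groupby("sample")}
        else:
            cpg_levels = {s: [v] for s, v in sample_levels.items()}
        repeat_frac = float(repeat_col.loc[rid]) if repeat_col is not None else 0.0
        out.append(CandidateRegion(iv, source or Path(str(regions_bed)).stem,
                                   sample_levels, cpg_levels, repeat_frac))
    return out


def write_panel_bed(panel: Panel, path, scores: Sequence[float] | None = None
                    ) -> None:
    """Write a panel as BED6 (score = design score x 1000, truncated)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(panel.regions):
            score = int(scores[i] * 1000) if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                     f"\t{score}\t.\n")


def read_panel_bed(path) -> Panel:
    """Read a panel BED back into a :class:`Panel` (no merging applied)."""
    track = read_bed(path)
    return Panel.from_intervals(track.intervals)
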