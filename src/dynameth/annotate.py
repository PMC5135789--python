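"""Feature-annotation utilities: promoter construction and overlap statistics.

A feature overlaps the panel when the two share at least one base
(half-open coordinates, so bookends do not overlap). Promoters are
strand-independent windows of +/- ``flank_bp`` around a TSS, clipped at
the chromosome origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genomic_io import AnnotationTrack, GenomicInterval
from .panel_design import Panel

__all__ = [
    "TssRecord",
    "make_promoters",
    "feature_overlap_pct",
    "platform_cpg_overlap",
    "read_tss",
    "annotation_report",
]


@dataclass(frozen=True)
class TssRecord:
    chrom: str
    position: int          # 0-based TSS coordinate
    gene: str
    strand: str = "+"

    def __post_init__(self):
        if self.position < 0:
            raise ValidationError(f"TSS position must be >= 0, got {self.position}")


def make_promoters(tss_list: Sequence[TssRecord], flank_bp: int = 1000
                   ) -> AnnotationTrack:
    """Promoter track: [max(0, tss - flank), tss + flank) per record."""
    intervals = [
        GenomicInterval(t.chrom, max(0, t.position - flank_bp),
                        t.position + flank_bp, t.gene)
        for t in tss_list
    ]
    return AnnotationTrack("promoters", intervals)


def feature_overlap_pct(panel: Panel, track: AnnotationTrack
                        ) -> tuple[float, float]:
    """(fraction of track features hit by the panel, fraction of panel
    regions hit by the track); both 0.0 for empty inputs."""
    panel_track = panel.as_track()
    n_feat = len(track)
    n_hit = sum(1 for iv in track if panel_track.overlaps(iv)) if n_feat else 0
    n_panel = panel.n_regions
    n_panel_hit = sum(1 for iv in panel.regions if track.overlaps(iv)) if n_panel else 0
    return (n_hit / n_feat if n_feat else 0.0,
            n_panel_hit / n_panel if n_panel else 0.0)


def platform_cpg_overlap(platform_cpgs: Mapping[str, Sequence[int]],
                         panel: Panel) -> float:
    """Fraction of platform CpG positions inside any panel region.

    A CpG is inside a region when its C position falls in [start, end).
    """
    total = sum(len(v) for v in platform_cpgs.values())
    if total == 0:
        return 0.0
    inside = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in panel.regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, positions in platform_cpgs.items():
        ivs = by_chrom.get(chrom)
        if not ivs:
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        pos = np.asarray(positions)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        inside += int(ok.sum())
    return inside / total


def read_tss(path) -> list[TssRecord]:
    """Read TSS records from a 4-column TSV (chrom, pos, gene, strand) or
    BED6 (start column taken as the TSS position)."""
    path = Path(path)
    records: list[TssRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, line_no, "expected >= 4 columns")
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-integer TSS: {exc}") from None
            if len(parts) >= 6:  # BED6: chrom start end name score strand
                records.append(TssRecord(parts[0], pos, parts[3], parts[5]))
            else:
                records.append(TssRecord(parts[0], pos, parts[2], parts[3]))
    return records


def annotation_report(panel: Panel, tracks: Sequence[AnnotationTrack],
                      platform_cpgs: Mapping[str, Sequence[int]] | None = None
                      ) -> pd.DataFrame:
    """Per-track overlap percentages, mirroring the panel summary figures."""
    rows = []
    for track in tracks:
        pct_track, pct_panel = feature_overlap_pct(panel, track)
        rows.append({"track": track.name, "n_features": len(track),
                     "pct_track_covered": pct_track,
                     "pct_panel_overlapping": pct_panel})
    df = pd.DataFrame(rows)
    if platform_cpgs is not None:
        df.attrs["platform_cpg_overlap"] = platform_cpg_overlap(platform_cpgs,
                                                                panel)
    return df
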