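"""Seeded synthetic methylomes with planted DMRs.

The generator emulates the statistical structure the pipeline assumes:
CpG positions with geometric inter-CpG spacing, a shared per-CpG baseline
methylation drawn from a Beta distribution, non-overlapping hypomethylated
DMRs planted in a random proper subset of cell types, Poisson read
coverage, binomial methylation counts, and a small bisulfite
conversion-failure rate that makes unmethylated cytosines read as
methylated. Planted DMRs are CpG-enriched (every fully contained 200-bp
grid tile holds at least ``dmr_min_cpgs_per_tile`` CpGs), mirroring the
CpG density of regulatory regions.

All outputs are bit-reproducible for a fixed seed; per-cell-type read
simulation uses seeds spawned deterministically from the run seed so the
call order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .genomic_io import AnnotationTrack, GenomicInterval, SampleCallSet
from .panel_design import CandidateRegion
from .annotate import TssRecord

__all__ = [
    "SimConfig",
    "PlantedDMR",
    "SimTruth",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_calls",
    "simulate_tracks",
    "simulate_dataset",
    "candidate_regions_from_truth",
]

TILE = 200  # grid used for the CpG-density guarantee inside planted DMRs


@dataclass
class SimConfig:
    """Study conditions for the synthetic methylome.

    Defaults correspond to the conditions the pipeline is benchmarked
    under: 2 cell types, 100 planted hypomethylated DMRs with a 0.5
    methylation drop, Poisson(30) coverage, and a 0.4% conversion-failure
    rate (a 99.6% bisulfite conversion rate).
    """

    n_chroms: int = 2
    chrom_len_bp: int = 1_000_000
    cpg_spacing: float = 80.0        # mean geometric inter-CpG spacing (bp)
    n_celltypes: int = 2
    n_dmrs: int = 100
    dmr_len_bp: tuple[int, int] = (400, 1000)
    delta: float = 0.5               # planted methylation drop
    baseline_beta: tuple[float, float] = (8.0, 2.0)
    coverage_lambda: float = 30.0
    conv_fail: float = 0.004
    repeat_fraction: float = 0.1
    dmr_min_cpgs_per_tile: int = 3
    dmr_min_gap_bp: int = 600
    hyper: bool = False              # plant hypermethylation instead
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.delta <= 1:
            raise ValidationError("delta must be in (0, 1]")
        if not 0 <= self.conv_fail <= 0.05:
            raise ValidationError("conv_fail must be in [0, 0.05]")
        if min(self.n_chroms, self.chrom_len_bp, self.n_celltypes) < 1:
            raise ValidationError("genome and cell-type counts must be positive")
        if self.cpg_spacing < 1 or self.coverage_lambda < 0:
            raise ValidationError("spacing must be >= 1 and coverage >= 0")
        if self.n_dmrs < 0 or self.dmr_len_bp[0] > self.dmr_len_bp[1]:
            raise ValidationError("invalid DMR count or length range")

    @property
    def celltypes(self) -> list[str]:
        return [f"ct{i:02d}" for i in range(self.n_celltypes)]

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class PlantedDMR:
    interval: GenomicInterval
    affected: tuple[str, ...]
    delta: float


@dataclass
class SimTruth:
    """Ground truth of one simulated methylome."""

    config: SimConfig
    cpg_positions: dict[str, np.ndarray]
    baseline: dict[str, np.ndarray]
    levels: dict[str, dict[str, np.ndarray]]   # celltype -> chrom -> level
    dmrs: list[PlantedDMR]

    @property
    def celltypes(self) -> list[str]:
        return self.config.celltypes

    def tile_truth_delta(self, tiles: Sequence[GenomicInterval],
                         celltype_a: str, celltype_b: str) -> np.ndarray:
        """Noise-free tile-level difference |mean_a - mean_b| per tile.

        The expected pooled tile level under uniform Poisson coverage is
        the unweighted mean of the true CpG levels in the tile; tiles
        without CpGs get NaN.
        """
        out = np.full(len(tiles), np.nan)
        for i, t in enumerate(tiles):
            pos = self.cpg_positions.get(t.chrom)
            if pos is None:
                continue
            lo, hi = np.searchsorted(pos, [t.start, t.end])
            if hi == lo:
                continue
            la = self.levels[celltype_a][t.chrom][lo:hi]
            lb = self.levels[celltype_b][t.chrom][lo:hi]
            out[i] = abs(float(la.mean()) - float(lb.mean()))
        return out


def simulate_genome(config: SimConfig
                    ) -> tuple[dict[str, np.ndarray], AnnotationTrack]:
    """CpG positions (geometric spacing) and a repeat-masked track."""
    rng = config._rng(0)
    positions: dict[str, np.ndarray] = {}
    repeats: list[GenomicInterval] = []
    p = 1.0 / config.cpg_spacing
    for chrom in config.chroms:
        n_guess = int(config.chrom_len_bp * p * 1.5) + 10
        gaps = rng.geometric(p, size=n_guess)
        pos = np.cumsum(gaps)
        while pos[-1] < config.chrom_len_bp:
            more = rng.geometric(p, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
        positions[chrom] = pos[pos < config.chrom_len_bp].astype(np.int64)

        if config.repeat_fraction > 0:
            block = 1000
            n_blocks = int(config.repeat_fraction * config.chrom_len_bp / block)
            starts = np.sort(rng.integers(
                0, max(1, config.chrom_len_bp - block), size=n_blocks))
            repeats.extend(
                GenomicInterval(chrom, int(s), int(s) + block) for s in starts)
    return positions, AnnotationTrack("repeats", repeats)


def _place_dmrs(config: SimConfig, rng: np.random.Generator
                ) -> list[GenomicInterval]:
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chroms}
    out: list[GenomicInterval] = []
    max_tries = 200 * max(config.n_dmrs, 1)
    tries = 0
    while len(out) < config.n_dmrs:
        if tries > max_tries:
            raise ValidationError(
                "genome too small for the requested number of DMRs")
        tries += 1
        chrom = config.chroms[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(config.dmr_len_bp[0],
                                  config.dmr_len_bp[1] + 1))
        if length >= config.chrom_len_bp:
            raise ValidationError("DMR length exceeds chromosome length")
        start = int(rng.integers(0, config.chrom_len_bp - length))
        end = start + length
        gap = config.dmr_min_gap_bp
        if any(start < e + gap and s < end + gap for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        out.append(GenomicInterval(chrom, start, end, f"dmr{len(out):04d}"))
    out.sort(key=GenomicInterval.sort_key)
    return [GenomicInterval(iv.chrom, iv.start, iv.end, f"dmr{i:04d}")
            for i, iv in enumerate(out)]


def _enrich_cpgs(positions: np.ndarray, dmr: GenomicInterval,
                 min_per_tile: int) -> np.ndarray:
    """Guarantee >= min_per_tile CpGs in every grid tile inside the DMR."""
    added = []
    first = (dmr.start + TILE - 1) // TILE          # first tile fully inside
    last = dmr.end // TILE                          # one past last full tile
    for k in range(first, last):
        t0, t1 = k * TILE, (k + 1) * TILE
        lo, hi = np.searchsorted(positions, [t0, t1])
        need = min_per_tile - (hi - lo)
        if need > 0:
            have = set(positions[lo:hi].tolist())
            grid = np.linspace(t0 + 10, t1 - 10, min_per_tile).astype(np.int64)
            for g in grid:
                while int(g) in have:
                    g += 1
                have.add(int(g))
                added.append(int(g))
                need -= 1
                if need == 0:
                    break
    if not added:
        return positions
    return np.unique(np.concatenate([positions, np.array(added, dtype=np.int64)]))


def simulate_methylomes(config: SimConfig,
                        cpg_positions: Mapping[str, np.ndarray]) -> SimTruth:
    """Plant DMRs and derive per-cell-type true methylation levels.

    Baseline per-CpG methylation ~ Beta(a, b) is shared across cell
    types; inside each planted DMR a random proper subset of cell types
    (all of them only when there is a single cell type) has its level
    shifted by ``delta`` (floored at 0 for hypo, capped at 1 for hyper).
    CpG positions are augmented inside DMRs to meet the per-tile density
    guarantee; the returned truth holds the final position set.
    """
    rng = config._rng(1)
    dmr_ivs = _place_dmrs(config, rng)

    positions = {c: np.asarray(p, dtype=np.int64).copy()
                 for c, p in cpg_positions.items()}
    for iv in dmr_ivs:
        positions[iv.chrom] = _enrich_cpgs(positions[iv.chrom], iv,
                                           config.dmr_min_cpgs_per_tile)

    a, b = config.baseline_beta
    baseline = {c: rng.beta(a, b, size=len(p)) for c, p in positions.items()}
    levels = {ct: {c: baseline[c].copy() for c in positions}
              for ct in config.celltypes}

    dmrs: list[PlantedDMR] = []
    for iv in dmr_ivs:
        if config.n_celltypes == 1:
            affected = tuple(config.celltypes)
        else:
            size = int(rng.integers(1, config.n_celltypes))  # proper subset
            affected = tuple(sorted(
                rng.choice(config.celltypes, size=size, replace=False)))
        lo, hi = np.searchsorted(positions[iv.chrom], [iv.start, iv.end])
        for ct in affected:
            seg = levels[ct][iv.chrom][lo:hi]
            if config.hyper:
                levels[ct][iv.chrom][lo:hi] = np.minimum(1.0, seg + config.delta)
            else:
                levels[ct][iv.chrom][lo:hi] = np.maximum(0.0, seg - config.delta)
        dmrs.append(PlantedDMR(iv, affected, config.delta))
    return SimTruth(config, positions, baseline, levels, dmrs)


def simulate_calls(truth: SimTruth, celltype: str,
                   config: SimConfig | None = None) -> SampleCallSet:
    """Draw read counts for one cell type.

    Per CpG: total ~ Poisson(coverage_lambda) and methylated reads ~
    Binomial(total, m + (1 - m) * conv_fail); CpGs with zero coverage are
    omitted. Deterministic given the run seed and the cell type.
    """
    config = config or truth.config
    ct_index = config.celltypes.index(celltype)
    rng = config._rng(1000 + ct_index)
    import pandas as pd

    frames = []
    for chrom in config.chroms:
        pos = truth.cpg_positions[chrom]
        m = truth.levels[celltype][chrom]
        total = rng.poisson(config.coverage_lambda, size=len(pos))
        p = np.clip(m + (1.0 - m) * config.conv_fail, 0.0, 1.0)
        meth = rng.binomial(total, p)
        keep = total > 0
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[keep],
            "meth_reads": meth[keep], "total_reads": total[keep]}))
    df = pd.concat(frames, ignore_index=True) if frames else None
    if df is not None and not len(df):
        df = None
    return SampleCallSet(celltype, df)


def simulate_tracks(truth: SimTruth, config: SimConfig | None = None,
                    enhancer_overlap_frac: float = 0.6,
                    eqtl_overlap_frac: float = 0.3,
                    n_background: int = 50, n_tss: int = 50
                    ) -> dict[str, object]:
    """Enhancer / promoter-TSS / eQTL annotation emulations.

    ``enhancer_overlap_frac`` (resp. ``eqtl_overlap_frac``) of the planted
    DMRs receive an overlapping enhancer (eQTL) interval; background
    intervals and TSSs are placed uniformly. Deterministic given the seed.
    """
    config = config or truth.config
    rng = config._rng(2)
    enhancers: list[GenomicInterval] = []
    eqtls: list[GenomicInterval] = []
    for dmr in truth.dmrs:
        iv = dmr.interval
        if rng.random() < enhancer_overlap_frac:
            off = int(rng.integers(-200, max(1, len(iv) - 100)))
            start = max(0, iv.start + off)
            enhancers.append(GenomicInterval(iv.chrom, start, start + 500))
        if rng.random() < eqtl_overlap_frac:
            centre = int(rng.integers(iv.start, iv.end))
            eqtls.append(GenomicInterval(iv.chrom, max(0, centre - 50),
                                         centre + 50))
    tss: list[TssRecord] = []
    for chrom in config.chroms:
        for s in rng.integers(0, config.chrom_len_bp - 1000, size=n_background):
            enhancers.append(GenomicInterval(chrom, int(s), int(s) + 500))
        for s in rng.integers(0, config.chrom_len_bp - 1000, size=n_background):
            eqtls.append(GenomicInterval(chrom, int(s), int(s) + 100))
        for i, s in enumerate(rng.integers(1000, config.chrom_len_bp - 1000,
                                           size=n_tss)):
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(TssRecord(chrom, int(s), f"{chrom}_gene{i:03d}", strand))
    return {
        "enhancers": AnnotationTrack("enhancers", enhancers),
        "tss": tss,
        "eqtls": AnnotationTrack("eqtls", eqtls),
    }


def simulate_dataset(config: SimConfig
                     ) -> tuple[SimTruth, dict[str, SampleCallSet],
                                AnnotationTrack, dict[str, object]]:
    """End-to-end convenience: genome, truth, per-cell-type calls, tracks."""
    positions, repeat_track = simulate_genome(config)
    truth = simulate_methylomes(config, positions)
    callsets = {ct: simulate_calls(truth, ct, config)
                for ct in config.celltypes}
    tracks = simulate_tracks(truth, config)
    return truth, callsets, repeat_track, tracks


def candidate_regions_from_truth(truth: SimTruth,
                                 repeat_track: AnnotationTrack,
                                 source: str = "sim") -> list[CandidateRegion]:
    """Turn planted DMRs into panel-design candidates with true levels."""
    from .genomic_io import overlap_bp

    out = []
    for dmr in truth.dmrs:
        iv = dmr.interval
        lo, hi = np.searchsorted(truth.cpg_positions[iv.chrom],
                                 [iv.start, iv.end])
        cpg_levels = {ct: truth.levels[ct][iv.chrom][lo:hi].tolist()
                      for ct in truth.celltypes}
        sample_levels = {ct: float(np.mean(v)) if len(v) else 0.0
                         for ct, v in cpg_levels.items()}
        rep_bp = sum(overlap_bp(iv, r) for r in repeat_track.overlapping(iv))
        out.append(CandidateRegion(iv, source, sample_levels, cpg_levels,
                                   min(1.0, rep_bp / len(iv))))
    return out
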