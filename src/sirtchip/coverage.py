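"""Alignment filtering, per-base coverage pileup, normalization, and the
compiled rDNA repeat profile.

The coverage value at a base is the number of read intervals containing it
(reads are piled up directly, with no fragment extension).  Multimapping
reads are discarded genome-wide except over an explicit repeat whitelist —
by default the single annotated rDNA unit, onto which the tandem array's
reads are compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import (
    FeatureAnnotation,
    FeatureClassError,
    GenomeLayout,
    Interval,
)
from .reads import ReadSet, check_reads_in_bounds


class DegenerateLibraryError(ValueError):
    """A track with zero mapped reads cannot be normalized."""


@dataclass(frozen=True)
class AlignmentFilterParams:
    """Mapping-quality filter with a repeat whitelist.

    ``min_mapq`` defaults to 20 (kept when MAPQ >= 20); multimappers are kept
    only where they overlap a whitelist interval, normally the rDNA unit.
    """

    min_mapq: int = 20
    repeat_whitelist: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        object.__setattr__(self, "repeat_whitelist", tuple(self.repeat_whitelist))


@dataclass
class CoverageTrack:
    """Dense per-base arrays per chromosome plus library-size metadata."""

    values: dict[str, np.ndarray]
    total_mapped_reads: int
    scale_factor: float = 1.0

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.values.items()},
            self.total_mapped_reads,
            self.scale_factor,
        )

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def genome_mean(self) -> float:
        n = sum(len(v) for v in self.values.values())
        return self.total_signal / n if n else 0.0

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if set(self.values) != set(other.values):
            raise ValueError("tracks cover different chromosomes")
        return CoverageTrack(
            {c: self.values[c] + other.values[c] for c in self.values},
            self.total_mapped_reads + other.total_mapped_reads,
            1.0,
        )


@dataclass
class RepeatProfile:
    """Per-base counts in repeat-unit coordinates, compiled over all copies."""

    unit_length: int
    values: np.ndarray
    n_copies: int

    @property
    def total(self) -> float:
        return float(self.values.sum())


def filter_alignments(reads: ReadSet, params: AlignmentFilterParams) -> ReadSet:
    """Keep reads with MAPQ >= min_mapq that are unique mappers, plus
    multimappers overlapping the repeat whitelist."""
    if reads.total_count == 0:
        return reads
    keep = reads.mapqs >= params.min_mapq
    multi = reads.is_multimapper
    if multi.any():
        allowed = np.zeros(reads.total_count, dtype=bool)
        for iv in params.repeat_whitelist:
            allowed |= (
                (reads.chroms == iv.chrom)
                & (reads.starts < iv.end)
                & (reads.ends > iv.start)
            )
        # whitelisted multimappers bypass the MAPQ filter (their MAPQ is
        # meaningless by construction); everything else must be unique
        keep = (keep & ~multi) | (multi & allowed)
    return reads.subset(keep)


def pileup(reads: ReadSet, layout: GenomeLayout) -> CoverageTrack:
    """Coverage(x) = number of read intervals containing x."""
    check_reads_in_bounds(reads, layout)
    values: dict[str, np.ndarray] = {}
    for chrom, length in layout.lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        mask = reads.chroms == chrom
        if mask.any():
            np.add.at(diff, reads.starts[mask], 1)
            np.add.at(diff, reads.ends[mask], -1)
        values[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(values, reads.total_count)


def start_pileup(reads: ReadSet, layout: GenomeLayout) -> CoverageTrack:
    """Count of read 5'-most (leftmost) coordinates per base.

    Bins built from these counts are independent Poisson under a uniform
    null, which is what the binned peak caller tests.
    """
    check_reads_in_bounds(reads, layout)
    values: dict[str, np.ndarray] = {}
    for chrom, length in layout.lengths.items():
        arr = np.zeros(length, dtype=np.int64)
        mask = reads.chroms == chrom
        if mask.any():
            np.add.at(arr, reads.starts[mask], 1)
        values[chrom] = arr
    return CoverageTrack(values, reads.total_count)


def normalize_to_reference(track: CoverageTrack, reference_total: int) -> CoverageTrack:
    """Rescale a track so library sizes are comparable across factors.

    Every value is multiplied by ``reference_total / total_mapped_reads``;
    the input track is left untouched.
    """
    if track.total_mapped_reads <= 0:
        raise DegenerateLibraryError("track has zero mapped reads")
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    # target scale is defined on the raw counts, so renormalizing an already
    # scaled track lands on the same values as normalizing the original
    target = reference_total / track.total_mapped_reads
    s = target / track.scale_factor
    return CoverageTrack(
        {c: v.astype(np.float64) * s for c, v in track.values.items()},
        track.total_mapped_reads,
        scale_factor=target,
    )


def compile_repeat_coverage(
    reads: ReadSet, repeat_unit: FeatureAnnotation, n_copies: int
) -> RepeatProfile:
    """Sum per-base counts of every read overlapping the repeat unit, in unit
    coordinates; counts are raw sums over the array, not per-copy averages."""
    if repeat_unit.feature_class != "rDNA_repeat":
        raise FeatureClassError(
            f"compile_repeat_coverage needs an rDNA_repeat feature, "
            f"got {repeat_unit.feature_class!r}"
        )
    unit = repeat_unit.interval
    profile = np.zeros(unit.length, dtype=np.int64)
    mask = (
        (reads.chroms == unit.chrom)
        & (reads.starts < unit.end)
        & (reads.ends > unit.start)
    )
    if mask.any():
        lo = np.clip(reads.starts[mask] - unit.start, 0, unit.length)
        hi = np.clip(reads.ends[mask] - unit.start, 0, unit.length)
        diff = np.zeros(unit.length + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        profile = np.cumsum(diff[:-1])
    return RepeatProfile(unit.length, profile, n_copies)


def write_bedgraph(track: CoverageTrack, path: str | Path, name: str = "coverage") -> None:
    """Run-length-merged bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, vals in track.values.items():
            if not len(vals):
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            bounds = np.concatenate(([0], change, [len(vals)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = vals[s]
                if v == 0:
                    continue
                out = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{out}\n")


def write_wiggle(track: CoverageTrack, path: str | Path, name: str = "coverage") -> None:
    """fixedStep span=1 wiggle (1-based, per the wiggle standard)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom, vals in track.values.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1 span=1\n")
            if np.issubdtype(vals.dtype, np.integer):
                fh.write("\n".join(str(int(v)) for v in vals))
            else:
                fh.write("\n".join(format(float(v), "g") for v in vals))
            fh.write("\n")
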