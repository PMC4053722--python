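"""Mapped-read containers and read-file I/O.

Reads are fixed-length intervals with a mapping quality and a multimapper
flag; they are stored columnar (NumPy arrays) so that filtering and pileup
over 10^5-10^6 reads stay vectorized.  BED6 is the text interchange format
(score column = MAPQ, name column = ``uniq``/``multi``); SAM input is also
accepted when alignments come from a mapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .genome import GenomeLayout, Interval, ParseError, STRANDS


class Read(NamedTuple):
    interval: Interval
    mapq: int
    is_multimapper: bool


@dataclass
class ReadSet:
    """Columnar set of mapped reads (constant read length per set)."""

    chroms: np.ndarray  # str array
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    strands: np.ndarray  # str array of +/-/.
    mapqs: np.ndarray  # int64, 0..60
    is_multimapper: np.ndarray  # bool
    read_length: int

    def __post_init__(self) -> None:
        n = len(self.starts)
        for arr in (self.chroms, self.ends, self.strands, self.mapqs, self.is_multimapper):
            if len(arr) != n:
                raise ValueError("ReadSet column lengths disagree")
        if n and not np.all(self.ends - self.starts == self.read_length):
            raise ValueError("ReadSet contains reads of varying length")

    @property
    def total_count(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.total_count

    def __iter__(self) -> Iterator[Read]:
        for i in range(self.total_count):
            yield Read(
                Interval(
                    str(self.chroms[i]),
                    int(self.starts[i]),
                    int(self.ends[i]),
                    str(self.strands[i]),
                ),
                int(self.mapqs[i]),
                bool(self.is_multimapper[i]),
            )

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
            self.strands[mask],
            self.mapqs[mask],
            self.is_multimapper[mask],
            self.read_length,
        )

    @classmethod
    def from_columns(
        cls,
        chroms,
        starts,
        strands,
        mapqs,
        is_multimapper,
        read_length: int,
    ) -> "ReadSet":
        starts = np.asarray(starts, dtype=np.int64)
        return cls(
            np.asarray(chroms, dtype=object),
            starts,
            starts + int(read_length),
            np.asarray(strands, dtype=object),
            np.asarray(mapqs, dtype=np.int64),
            np.asarray(is_multimapper, dtype=bool),
            int(read_length),
        )

    @classmethod
    def empty(cls, read_length: int) -> "ReadSet":
        return cls.from_columns([], [], [], [], [], read_length)

    @classmethod
    def concat(cls, sets: list["ReadSet"]) -> "ReadSet":
        sets = [s for s in sets if s.total_count or len(sets) == 1]
        if not sets:
            raise ValueError("cannot concatenate zero ReadSets")
        rl = sets[0].read_length
        if any(s.read_length != rl for s in sets):
            raise ValueError("read lengths differ across concatenated sets")
        return cls(
            np.concatenate([s.chroms for s in sets]),
            np.concatenate([s.starts for s in sets]),
            np.concatenate([s.ends for s in sets]),
            np.concatenate([s.strands for s in sets]),
            np.concatenate([s.mapqs for s in sets]),
            np.concatenate([s.is_multimapper for s in sets]),
            rl,
        )


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    """BED6: name encodes the multimapper flag, score carries the MAPQ."""
    with open(path, "w") as fh:
        for i in range(reads.total_count):
            name = "multi" if reads.is_multimapper[i] else "uniq"
            fh.write(
                f"{reads.chroms[i]}\t{reads.starts[i]}\t{reads.ends[i]}\t"
                f"{name}\t{reads.mapqs[i]}\t{reads.strands[i]}\n"
            )


def read_reads_bed(path: str | Path) -> ReadSet:
    chroms, starts, ends, strands, mapqs, multi = [], [], [], [], [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        chroms.append(parts[0])
        starts.append(s)
        ends.append(e)
        multi.append(len(parts) > 3 and parts[3] == "multi")
        mapqs.append(int(parts[4]) if len(parts) > 4 else 60)
        strands.append(parts[5] if len(parts) > 5 and parts[5] in STRANDS else ".")
    if not starts:
        raise ParseError(f"{path}: empty read file")
    lengths = np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64)
    if not np.all(lengths == lengths[0]):
        raise ParseError(f"{path}: reads are not constant-length")
    return ReadSet.from_columns(chroms, starts, strands, mapqs, multi, int(lengths[0]))


def read_reads_sam(path: str | Path) -> ReadSet:
    """Import mapped reads from SAM/BAM; secondary flag (0x100) or NH>1 marks
    a multimapper."""
    import pysam

    chroms, starts, strands, mapqs, multi = [], [], [], [], []
    lengths = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            strands.append("-" if rec.is_reverse else "+")
            mapqs.append(rec.mapping_quality)
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            multi.append(rec.is_secondary or nh > 1)
            lengths.add(rec.reference_end - rec.reference_start)
    if not starts:
        raise ParseError(f"{path}: no mapped reads")
    if len(lengths) != 1:
        raise ParseError(f"{path}: reads are not constant-length")
    return ReadSet.from_columns(chroms, starts, strands, mapqs, multi, lengths.pop())


def check_reads_in_bounds(reads: ReadSet, layout: GenomeLayout) -> None:
    """Raise a bounds error naming the first offending read."""
    from .genome import BoundsError

    lengths = layout.lengths
    for chrom in np.unique(reads.chroms.astype(str)) if reads.total_count else []:
        if chrom not in lengths:
            idx = int(np.argmax(reads.chroms == chrom))
            raise BoundsError(f"read #{idx} maps to unknown chromosome {chrom!r}")
        mask = reads.chroms == chrom
        if reads.starts[mask].min() < 0 or reads.ends[mask].max() > lengths[chrom]:
            sub = np.flatnonzero(
                mask & ((reads.starts < 0) | (reads.ends > lengths[chrom]))
            )
            i = int(sub[0])
            raise BoundsError(
                f"read #{i} [{reads.starts[i]}, {reads.ends[i]}) exceeds "
                f"{chrom} length {lengths[chrom]}"
            )
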