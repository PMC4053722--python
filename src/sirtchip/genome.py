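"""Genome coordinate frame, feature annotations, and interval-format I/O.

All coordinates inside the package are 0-based half-open on a fixed
:class:`GenomeLayout`; conversion to and from 1-based formats (GFF3, wiggle)
happens only at the I/O boundary, so no off-by-one arithmetic leaks into the
analysis code.

Feature classes follow the study design: ``ORF`` (gene bodies), ``pol3_gene``
(RNA polymerase III transcribed genes such as tRNAs), ``telomeric_repeat``
(TG1-3 repeat clusters, terminal or internal), ``rDNA_repeat`` (the single
annotated ribosomal DNA unit onto which the tandem array is compiled), and
``other``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("ORF", "pol3_gene", "telomeric_repeat", "rDNA_repeat", "other")

STRANDS = ("+", "-", ".")


class GenomeError(ValueError):
    """Base class for coordinate/annotation errors."""


class BoundsError(GenomeError):
    """An interval does not fit inside its chromosome."""


class ParseError(GenomeError):
    """A line of an interval file violates its format."""


class StrandError(GenomeError):
    """A strand-requiring operation received an unstranded feature."""


class FeatureClassError(GenomeError):
    """An operation received a feature of the wrong class."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise GenomeError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise GenomeError("chromosome names must be unique")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if int(length) < 1:
                raise GenomeError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column TSV of (name, length)."""
        names, lengths = [], []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected two tab-separated columns")
            names.append(parts[0])
            try:
                lengths.append(int(parts[1]))
            except ValueError:
                raise ParseError(f"{path}:{i}: non-integer length {parts[1]!r}") from None
        return cls(tuple(names), tuple(lengths))

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomeError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise GenomeError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """A named, classed interval (gene, repeat cluster, ...)."""

    feature_id: str
    interval: Interval
    feature_class: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise FeatureClassError(
                f"unknown feature class {self.feature_class!r} for {self.feature_id}"
            )


class AnnotationSet:
    """Feature collection indexed by class and by genomic position.

    The positional index is an interval tree per chromosome; ``query`` returns
    exactly the features overlapping a query interval (half-open semantics).
    """

    def __init__(self, layout: GenomeLayout, features: Iterable[FeatureAnnotation]):
        self.layout = layout
        feats = tuple(features)
        seen: set[str] = set()
        lengths = layout.lengths
        for f in feats:
            if f.feature_id in seen:
                raise GenomeError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            iv = f.interval
            if iv.chrom not in lengths:
                raise BoundsError(f"feature {f.feature_id!r}: unknown chromosome {iv.chrom!r}")
            if iv.end > lengths[iv.chrom]:
                raise BoundsError(
                    f"feature {f.feature_id!r} ends at {iv.end} beyond "
                    f"{iv.chrom} length {lengths[iv.chrom]}"
                )
        self.features = feats
        self._by_id = {f.feature_id: f for f in feats}
        self._by_class: dict[str, list[FeatureAnnotation]] = {c: [] for c in FEATURE_CLASSES}
        for f in feats:
            self._by_class[f.feature_class].append(f)
        self._trees: dict[str, IntervalTree] = {}
        for f in feats:
            tree = self._trees.setdefault(f.interval.chrom, IntervalTree())
            tree.addi(f.interval.start, f.interval.end, f)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[FeatureAnnotation]:
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> FeatureAnnotation:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def features_of_class(self, feature_class: str) -> tuple[FeatureAnnotation, ...]:
        return tuple(self._by_class.get(feature_class, ()))

    @property
    def orfs(self) -> tuple[FeatureAnnotation, ...]:
        return self.features_of_class("ORF")

    def query(self, interval: Interval) -> list[FeatureAnnotation]:
        """Features overlapping ``interval`` (position index; see tests for the
        linear-scan oracle this is checked against)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(interval.start, interval.end)]
        hits.sort(key=lambda f: (f.interval.start, f.interval.end, f.feature_id))
        return hits

    def write_bed(self, path: str | Path) -> None:
        """Write BED6 plus a 7th column carrying the feature class."""
        feats = sorted(
            self.features, key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end)
        )
        with open(path, "w") as fh:
            for f in feats:
                iv = f.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.feature_id}\t0\t"
                    f"{iv.strand}\t{f.feature_class}\n"
                )


ClassMap = Mapping[str, str]


def _map_class(key: str, class_map: ClassMap | None, context: str) -> str:
    if class_map and key in class_map:
        cls = class_map[key]
        if cls not in FEATURE_CLASSES:
            raise FeatureClassError(f"{context}: class_map maps {key!r} to unknown class {cls!r}")
        return cls
    if key in FEATURE_CLASSES:
        return key
    logger.warning("%s: unmapped feature type %r assigned class 'other'", context, key)
    return "other"


def load_annotations(
    path: str | Path,
    layout: GenomeLayout,
    format: str = "BED",
    class_map: ClassMap | None = None,
) -> AnnotationSet:
    """Load features from a BED4/BED6(+class) or GFF3 file.

    BED is 0-based half-open and used as-is; GFF3 is 1-based inclusive and the
    start is shifted by -1 on load. ``class_map`` translates the file's type
    key (GFF3 ``type`` column; BED 7th column, falling back to the name column)
    into a feature class; unmapped keys become ``other`` with a warning.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unsupported annotation format {format!r}")
    feats: list[FeatureAnnotation] = []
    auto = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("track"):
            continue
        parts = line.split("\t")
        ctx = f"{path}:{lineno}"
        if fmt == "BED":
            if len(parts) < 3:
                raise ParseError(f"{ctx}: BED needs >=3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{ctx}: non-integer BED coordinates") from None
            name = parts[3] if len(parts) > 3 and parts[3] else f"feature_{auto}"
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            type_key = parts[6] if len(parts) > 6 and parts[6] else name
        else:  # GFF3
            if len(parts) < 8:
                raise ParseError(f"{ctx}: GFF3 needs >=8 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError:
                raise ParseError(f"{ctx}: non-integer GFF3 coordinates") from None
            strand = parts[6] if parts[6] in STRANDS else "."
            type_key = parts[2]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            ) if len(parts) > 8 else {}
            name = attrs.get("ID") or attrs.get("Name") or f"feature_{auto}"
        auto += 1
        if start < 0 or start >= end:
            raise ParseError(f"{ctx}: invalid interval [{start}, {end})")
        try:
            iv = Interval(chrom, start, end, strand)
        except GenomeError as exc:
            raise ParseError(f"{ctx}: {exc}") from None
        if chrom not in layout.lengths:
            raise BoundsError(f"{ctx}: feature {name!r} on unknown chromosome {chrom!r}")
        if end > layout.length_of(chrom):
            raise BoundsError(
                f"{ctx}: feature {name!r} ends at {end} beyond {chrom} "
                f"length {layout.length_of(chrom)}"
            )
        feats.append(FeatureAnnotation(name, iv, _map_class(type_key, class_map, ctx)))
    return AnnotationSet(layout, feats)
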