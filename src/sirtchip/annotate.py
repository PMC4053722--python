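"""Peak-to-gene annotation: location classes, embedded ORFs, and ORF-binding
calls by fractional coverage.

A peak is assigned the location class with which it shares the most bp among
ORF, Pol III gene, telomeric repeat, promoter (a fixed strand-aware window
upstream of each ORF start), and intergenic (the remainder).  A gene is
called bound when the union of peaks covers strictly more than
``min_orf_fraction`` of its ORF (default 60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    AnnotationSet,
    FeatureAnnotation,
    FeatureClassError,
    Interval,
    StrandError,
)
from .peaks import PeakSet

DEFAULT_PRIORITY = ("ORF", "pol3_gene", "telomeric_repeat", "promoter", "intergenic")


@dataclass(frozen=True)
class ClassificationParams:
    promoter_window: int = 500
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        if self.promoter_window < 0:
            raise ValueError("promoter_window must be >= 0")


@dataclass
class PeakClassification:
    assigned: dict[int, str]  # peak index -> class
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    class_bp: dict[str, int]  # bp of peak assigned per class (whole-peak bp)
    embedded_orfs: list[str]


@dataclass(frozen=True)
class BindingCallParams:
    min_orf_fraction: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 < self.min_orf_fraction <= 1.0:
            raise ValueError("min_orf_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GeneBindingCall:
    gene_id: str
    covered_fraction: float
    bound: bool


def promoter_interval(orf: FeatureAnnotation, window: int, chrom_length: int) -> Interval | None:
    """Strand-aware window upstream of the ORF start, clipped to the
    chromosome; None when the window has zero length."""
    if orf.interval.strand not in ("+", "-"):
        raise StrandError(f"ORF {orf.feature_id!r} is unstranded")
    if window == 0:
        return None
    iv = orf.interval
    if iv.strand == "+":
        s, e = max(0, iv.start - window), iv.start
    else:
        s, e = iv.end, min(chrom_length, iv.end + window)
    if s >= e:
        return None
    return Interval(iv.chrom, s, e)


def _merged(intervals: Sequence[Interval]) -> dict[str, np.ndarray]:
    """Per-chromosome (n, 2) arrays of merged, sorted intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _overlap_bp(iv: Interval, merged: dict[str, np.ndarray]) -> int:
    arr = merged.get(iv.chrom)
    if arr is None or not len(arr):
        return 0
    lo = np.maximum(arr[:, 0], iv.start)
    hi = np.minimum(arr[:, 1], iv.end)
    return int(np.clip(hi - lo, 0, None).sum())


def classify_peak_locations(
    peaks: PeakSet,
    annots: AnnotationSet,
    params: ClassificationParams = ClassificationParams(),
) -> PeakClassification:
    """Assign each peak the max-bp-overlap class; exact ties break by
    ``params.priority``; collect ORFs wholly contained in a single peak."""
    if not annots.orfs:
        raise FeatureClassError("annotation set contains no ORFs")
    lengths = annots.layout.lengths
    regions = {
        "ORF": _merged([f.interval for f in annots.orfs]),
        "pol3_gene": _merged([f.interval for f in annots.features_of_class("pol3_gene")]),
        "telomeric_repeat": _merged(
            [f.interval for f in annots.features_of_class("telomeric_repeat")]
        ),
        "promoter": _merged(
            [
                iv
                for f in annots.orfs
                if (iv := promoter_interval(f, params.promoter_window, lengths[f.interval.chrom]))
            ]
        ),
    }
    any_region = _merged(
        [
            Interval(chrom, int(s), int(e))
            for reg in regions.values()
            for chrom, arr in reg.items()
            for s, e in arr
        ]
    )
    rank = {c: i for i, c in enumerate(params.priority)}
    assigned: dict[int, str] = {}
    class_bp: dict[str, int] = {c: 0 for c in params.priority}
    for i, peak in enumerate(peaks):
        overlaps = {c: _overlap_bp(peak.interval, regions[c]) for c in regions}
        covered = _overlap_bp(peak.interval, any_region)
        overlaps["intergenic"] = peak.interval.length - covered
        best = max(overlaps.values())
        winners = [c for c, v in overlaps.items() if v == best]
        cls = min(winners, key=lambda c: rank.get(c, len(rank)))
        assigned[i] = cls
        class_bp[cls] = class_bp.get(cls, 0) + peak.interval.length
    n = len(assigned)
    counts = {c: sum(1 for v in assigned.values() if v == c) for c in params.priority}
    fractions = {c: (counts[c] / n if n else 0.0) for c in counts}
    embedded = sorted(
        f.feature_id
        for f in annots.orfs
        if any(p.interval.contains(f.interval) for p in peaks)
    )
    return PeakClassification(assigned, counts, fractions, class_bp, embedded)


def orf_coverage_fraction(gene: FeatureAnnotation, peaks: PeakSet) -> float:
    """Fraction of the ORF covered by the union of peak intervals."""
    if gene.feature_class != "ORF":
        raise FeatureClassError(
            f"orf_coverage_fraction needs an ORF, got {gene.feature_class!r}"
        )
    covered = _overlap_bp(gene.interval, _merged(peaks.intervals))
    return covered / gene.interval.length


def call_bound_genes(
    peaks: PeakSet,
    annots: AnnotationSet,
    params: BindingCallParams = BindingCallParams(),
) -> list[GeneBindingCall]:
    """One call per ORF; bound iff covered fraction strictly exceeds the
    threshold (default: strictly more than 60% of the ORF)."""
    merged = _merged(peaks.intervals)
    calls = []
    for gene in annots.orfs:
        frac = _overlap_bp(gene.interval, merged) / gene.interval.length
        calls.append(GeneBindingCall(gene.feature_id, frac, frac > params.min_orf_fraction))
    return calls


def bound_gene_ids(calls: Sequence[GeneBindingCall]) -> set[str]:
    return {c.gene_id for c in calls if c.bound}


def write_classification_tsv(
    classification: PeakClassification, peaks: PeakSet, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfactor\tclass\n")
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{peaks.factor_name}\t{classification.assigned[i]}\n"
            )


def write_binding_tsv(calls: Sequence[GeneBindingCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcovered_fraction\tbound\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.covered_fraction:.6f}\t{int(c.bound)}\n")
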