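import numpy as np
import pytest

from sirtchip.genome import AnnotationSet, FeatureAnnotation, GenomeLayout, Interval
from sirtchip.reads import ReadSet


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout(("chrI", "chrII"), (4000, 5000))


@pytest.fixture
def make_reads():
    """Factory: build a ReadSet from (chrom, start, mapq, is_multimapper)
    tuples with a fixed read length."""

    def _make(entries, read_length=10, strand="+"):
        if not entries:
            return ReadSet.empty(read_length)
        chroms, starts, mapqs, multi = zip(*entries)
        return ReadSet.from_columns(
            list(chroms), list(starts), [strand] * len(entries),
            list(mapqs), list(multi), read_length,
        )

    return _make


def random_annotations(layout: GenomeLayout, n: int, rng: np.random.Generator,
                       feature_class: str = "ORF") -> AnnotationSet:
    """Random (possibly overlapping) stranded features for index/IO tests."""
    feats = []
    for i in range(n):
        ci = int(rng.integers(len(layout.chrom_names)))
        chrom = layout.chrom_names[ci]
        length = int(rng.integers(10, 400))
        start = int(rng.integers(0, layout.chrom_lengths[ci] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(
            FeatureAnnotation(
                f"f{i}", Interval(chrom, start, start + length, strand), feature_class
            )
        )
    return AnnotationSet(layout, feats)
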