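"""Overlap statistics: Monte-Carlo fold-over-random enrichment of peak sets
for feature classes, hypergeometric gene-set overlap, multi-way Venn
partitions, and regulation-class association tests.

The randomization null re-places the *peaks*: each peak is dropped uniformly
at random on its own chromosome with its length preserved (overlaps among
placed peaks permitted), while the feature annotations stay fixed.  Fold is
observed / mean(null) and the empirical p-value uses the add-one estimator
(1 + #{null >= observed}) / (n_perm + 1), so it can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genome import GenomeError, GenomeLayout, Interval


class PlacementError(GenomeError):
    """A peak is longer than its chromosome; no uniform placement exists."""


class ContainmentError(ValueError):
    """Gene sets must be subsets of the universe."""


class PartitionError(ValueError):
    """Regulation classes must partition the universe."""


@dataclass
class EnrichmentResult:
    mode: str  # "feature_count" or "bp"
    observed: float
    expected: float
    fold: float
    empirical_p: float
    n_perm: int
    seed: int
    null_sd: float
    saturated: bool = False  # expected == 0; fold reported as +inf

    def to_record(self) -> dict:
        return {
            "mode": self.mode,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "empirical_p": self.empirical_p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_sd": self.null_sd,
            "null": "uniform re-placement of peaks per chromosome, lengths preserved, overlaps allowed",
        }


@dataclass
class OverlapResult:
    n_universe: int
    n_A: int
    n_B: int
    n_intersection: int
    p_value: float


@dataclass
class ClassAssociation:
    observed: int
    expected: float
    direction: str  # "enriched" or "depleted"
    p_two_sided: float


AssociationResult = dict[str, ClassAssociation]


def _merge_arrays(intervals: Iterable[Interval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
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


def interval_overlap(
    setA: Sequence[Interval], setB: Sequence[Interval]
) -> tuple[int, int, int]:
    """(bp_overlap of the two union sets, #A intervals hit, #B intervals hit).

    Within-set overlaps are merged before the bp computation; the hit counts
    refer to the original (pre-merge) intervals.
    """
    mA, mB = _merge_arrays(setA), _merge_arrays(setB)
    bp = 0
    for chrom in set(mA) & set(mB):
        a, b = mA[chrom], mB[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi > lo:
                bp += int(hi - lo)
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1

    def hits(origs: Sequence[Interval], merged: dict[str, np.ndarray]) -> int:
        n = 0
        for iv in origs:
            arr = merged.get(iv.chrom)
            if arr is None:
                continue
            k = np.searchsorted(arr[:, 1], iv.start, side="right")
            if k < len(arr) and arr[k, 0] < iv.end:
                n += 1
        return n

    return bp, hits(setA, mB), hits(setB, mA)


def _null_statistic(
    peak_chroms: list[str],
    peak_lens: np.ndarray,
    layout: GenomeLayout,
    features: dict[str, np.ndarray],
    mode: str,
    n_perm: int,
    rng: np.random.Generator,
    n_features_total: int,
) -> np.ndarray:
    lengths = layout.lengths
    chrom_of = np.asarray(peak_chroms, dtype=object)
    max_start = np.array([lengths[c] for c in peak_chroms], dtype=np.int64) - peak_lens
    if np.any(max_start < 0):
        bad = int(np.argmax(max_start < 0))
        raise PlacementError(
            f"peak of length {peak_lens[bad]} exceeds chromosome "
            f"{peak_chroms[bad]!r} length {lengths[peak_chroms[bad]]}"
        )
    starts = rng.integers(0, max_start + 1, size=(n_perm, len(peak_lens)))
    out = np.empty(n_perm, dtype=np.float64)
    # feature id offsets per chromosome for distinct-feature counting
    offsets: dict[str, int] = {}
    off = 0
    for chrom, arr in features.items():
        offsets[chrom] = off
        off += len(arr)
    for t in range(n_perm):
        if mode == "feature_count":
            hit = np.zeros(n_features_total, dtype=bool)
            for j in range(len(peak_lens)):
                arr = features.get(peak_chroms[j])
                if arr is None:
                    continue
                s = starts[t, j]
                e = s + peak_lens[j]
                lo = int(np.searchsorted(arr[:, 1], s, side="right"))
                hi = int(np.searchsorted(arr[:, 0], e, side="left"))
                if hi > lo:
                    hit[offsets[peak_chroms[j]] + lo : offsets[peak_chroms[j]] + hi] = True
            out[t] = hit.sum()
        else:  # bp overlap of the union of placed peaks with the features
            placed = [
                Interval(peak_chroms[j], int(starts[t, j]), int(starts[t, j] + peak_lens[j]))
                for j in range(len(peak_lens))
            ]
            merged = _merge_arrays(placed)
            bp = 0
            for chrom, arr in merged.items():
                feats = features.get(chrom)
                if feats is None:
                    continue
                i = k = 0
                while i < len(arr) and k < len(feats):
                    lo = max(arr[i, 0], feats[k, 0])
                    hi = min(arr[i, 1], feats[k, 1])
                    if hi > lo:
                        bp += int(hi - lo)
                    if arr[i, 1] <= feats[k, 1]:
                        i += 1
                    else:
                        k += 1
            out[t] = bp
    return out


def fold_enrichment_random(
    peaks,
    features: Sequence[Interval],
    layout: GenomeLayout,
    mode: str = "feature_count",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed overlap statistic vs a uniform peak re-placement null.

    ``mode='feature_count'`` counts distinct features hit by at least one
    peak (natural for discrete features such as Pol III genes or telomeric
    repeat clusters); ``mode='bp'`` measures union bp overlap (natural for
    peak-vs-peak comparisons).
    """
    if mode not in ("feature_count", "bp"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    peak_ivs = list(peaks.intervals) if hasattr(peaks, "intervals") else list(peaks)
    feat_merged = _merge_arrays(features)
    n_features_total = sum(len(a) for a in feat_merged.values())

    bp, _, n_feat_hit = interval_overlap(peak_ivs, list(features))
    if mode == "feature_count":
        # count against merged features for consistency with the null
        hit = 0
        for chrom, arr in feat_merged.items():
            for s, e in arr:
                if any(iv.chrom == chrom and iv.start < e and s < iv.end for iv in peak_ivs):
                    hit += 1
        observed = float(hit)
    else:
        observed = float(bp)

    rng = np.random.default_rng(seed)
    null = _null_statistic(
        [iv.chrom for iv in peak_ivs],
        np.asarray([iv.length for iv in peak_ivs], dtype=np.int64),
        layout,
        feat_merged,
        mode,
        n_perm,
        rng,
        n_features_total,
    )
    expected = float(null.mean())
    saturated = expected == 0.0
    fold = float("inf") if saturated else observed / expected
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return EnrichmentResult(
        mode, observed, expected, fold, p, n_perm, seed, float(null.std(ddof=0)), saturated
    )


def geneset_overlap_test(
    A: set, B: set, universe: set
) -> OverlapResult:
    """Upper-tail hypergeometric probability of drawing >= |A∩B| members of B
    when sampling |A| genes from the universe."""
    A, B, universe = set(A), set(B), set(universe)
    if not A <= universe or not B <= universe:
        raise ContainmentError("A and B must be subsets of the universe")
    k = len(A & B)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(B), len(A)))
    return OverlapResult(len(universe), len(A), len(B), k, min(p, 1.0))


@dataclass
class VennResult:
    region_counts: dict[str, int]  # key e.g. "A&B" for exclusive regions
    pairwise: dict[tuple[str, str], OverlapResult]


def multiway_overlap(sets: Mapping[str, set], universe: set) -> VennResult:
    """Exclusive membership-region counts for all 2^k - 1 regions plus all
    pairwise hypergeometric overlap tests."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    for name in names:
        if not set(sets[name]) <= set(universe):
            raise ContainmentError(f"set {name!r} is not a subset of the universe")
    regions: dict[str, int] = {}
    for r in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if r >> i & 1]
        others = [n for n in names if n not in members]
        region = set(universe)
        for m in members:
            region &= set(sets[m])
        for o in others:
            region -= set(sets[o])
        regions["&".join(members)] = len(region)
    pairwise = {
        (a, b): geneset_overlap_test(set(sets[a]), set(sets[b]), set(universe))
        for a, b in combinations(names, 2)
    }
    return VennResult(regions, pairwise)


def _hypergeom_two_sided(k: int, M: int, K: int, N: int) -> float:
    """Two-sided p by summing all outcomes at most as probable as k
    (drawing N from M with K successes)."""
    support = np.arange(max(0, N + K - M), min(K, N) + 1)
    pmf = sps.hypergeom.pmf(support, M, K, N)
    p_obs = float(sps.hypergeom.pmf(k, M, K, N))
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def regulation_association_test(
    bound: set, classes: Mapping[str, str], universe: set
) -> AssociationResult:
    """Per regulation class (down / up / unchanged): observed bound count,
    hypergeometric expectation, direction, and a two-sided p-value."""
    bound, universe = set(bound), set(universe)
    if set(classes) != universe:
        raise PartitionError("classes must cover exactly the universe")
    if not bound <= universe:
        raise ContainmentError("bound genes must lie in the universe")
    by_class: dict[str, set] = {}
    for gene, cls in classes.items():
        by_class.setdefault(cls, set()).add(gene)
    out: AssociationResult = {}
    M, N = len(universe), len(bound)
    for cls, members in sorted(by_class.items()):
        K = len(members)
        obs = len(bound & members)
        expected = N * K / M
        out[cls] = ClassAssociation(
            observed=obs,
            expected=expected,
            direction="enriched" if obs >= expected else "depleted",
            p_two_sided=_hypergeom_two_sided(obs, M, K, N),
        )
    return out
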