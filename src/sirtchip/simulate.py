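"""Synthetic genomes, annotations, expression tables, and ChIP/input read
sets with planted enrichment structure.

The generator emulates the signal classes a sirtuin-style chromatin factor
shows in budding yeast ChIP-seq: (a) gene-body coating that ramps toward the
3' end of ORFs and scales with expression quintile, (b) telomeric-repeat
enrichment decaying away from the cluster with an ~1 kb e-folding distance,
(c) sharp promoter point peaks, (d) broad peaks centered on Pol III genes,
plus a uniform Poisson background shared with the input library and
multimapping reads confined to a single annotated rDNA unit standing in for
the tandem array (~175 copies).  Every generator is a pure function of its
configuration and seed, so downstream stages can be tested against a known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome import AnnotationSet, FeatureAnnotation, GenomeLayout, Interval
from .metagene import InsufficientGenesError, MetageneParams, assign_quintiles
from .peaks import Peak, PeakSet
from .reads import ReadSet


class CapacityError(ValueError):
    """Requested features cannot be packed into the genome."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Genome-scale study conditions for the toy simulation.

    Defaults give a 4 x 200 kb genome with 250 ORFs (roughly yeast gene
    density), 20 Pol III genes, 8 telomeric repeat clusters, one 9.1 kb rDNA
    unit carrying 175-copy metadata, 50 bp reads, and an expected library of
    2 x 10^5 reads per sample.
    """

    n_chroms: int = 4
    chrom_length: int = 200_000
    n_orfs: int = 250
    orf_length_range: tuple[int, int] = (600, 2000)
    n_pol3: int = 20
    pol3_length: int = 120
    n_telomere_clusters: int = 8
    telomere_cluster_length: int = 300
    rdna_copies: int = 175
    rdna_unit_length: int = 9100
    background_rate: float = 0.1
    read_length: int = 50
    library_size: int = 200_000
    scale_to_library: bool = True
    multimapper_fraction: float = 0.05
    expr_log_location: float = 0.0
    expr_log_scale: float = 1.0
    frac_down: float = 0.3
    frac_up: float = 0.3
    regulation_bias: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "n_orfs", "n_pol3", "n_telomere_clusters", "rdna_copies"
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if not 0 <= self.multimapper_fraction < 1:
            raise ValueError("multimapper_fraction must be in [0, 1)")


@dataclass(frozen=True)
class FactorModel:
    """Planted enrichment parameters for one ChIP-ed factor.

    The effective 3' fold of a quintile-q gene is
    ``orf_3prime_fold * orf_quintile_scaling[q-1]``; the scaling vector must
    be non-decreasing (quintile 5 = highest expression, strongest coating).
    All fold parameters are >= 1; a fold of 1 everywhere is a null factor
    statistically indistinguishable from input.
    """

    factor_name: str = "factor"
    orf_3prime_fold: float = 5.0
    orf_quintile_scaling: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    telomere_fold: float = 30.0
    telomere_decay_bp: float = 1000.0
    promoter_fold: float = 6.0
    promoter_width: int = 150
    pol3_fold: float = 10.0
    pol3_width: int = 500

    def __post_init__(self) -> None:
        for name in ("orf_3prime_fold", "telomere_fold", "promoter_fold", "pol3_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.telomere_decay_bp <= 0:
            raise ValueError("telomere_decay_bp must be > 0")
        scaling = tuple(float(x) for x in self.orf_quintile_scaling)
        if any(b < a for a, b in zip(scaling, scaling[1:])):
            raise ValueError("orf_quintile_scaling must be non-decreasing")
        object.__setattr__(self, "orf_quintile_scaling", scaling)

    @classmethod
    def null(cls, factor_name: str = "null") -> "FactorModel":
        return cls(
            factor_name=factor_name,
            orf_3prime_fold=1.0,
            orf_quintile_scaling=(1.0,) * 5,
            telomere_fold=1.0,
            promoter_fold=1.0,
            pol3_fold=1.0,
        )


def _place_nonoverlapping(
    lengths_to_place: list[int],
    layout: GenomeLayout,
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    max_tries_per_feature: int = 2000,
) -> list[Interval]:
    """Uniform random placement with rejection against already-placed
    features; bounded retries, then a capacity error."""
    chrom_names = list(layout.chrom_names)
    chrom_lengths = np.asarray(layout.chrom_lengths, dtype=np.int64)
    placed: list[Interval] = []
    for L in lengths_to_place:
        weights = np.clip(chrom_lengths - L + 1, 0, None).astype(np.float64)
        if weights.sum() == 0:
            raise CapacityError(f"feature of length {L} exceeds every chromosome")
        weights /= weights.sum()
        for _ in range(max_tries_per_feature):
            ci = int(rng.choice(len(chrom_names), p=weights))
            chrom = chrom_names[ci]
            start = int(rng.integers(0, chrom_lengths[ci] - L + 1))
            end = start + L
            if all(not (start < e and s < end) for s, e in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(Interval(chrom, start, end))
                break
        else:
            raise CapacityError(
                f"could not place a {L} bp feature after {max_tries_per_feature} tries; "
                "genome too crowded"
            )
    return placed


def build_toy_genome(config: SyntheticConfig) -> tuple[GenomeLayout, AnnotationSet]:
    """Random non-overlapping feature placement, reproducible from the seed."""
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        (config.chrom_length,) * config.n_chroms,
    )
    want_rdna = config.rdna_copies > 0 and config.rdna_unit_length > 0
    demand = (
        config.n_orfs * config.orf_length_range[1]
        + config.n_pol3 * config.pol3_length
        + config.n_telomere_clusters * config.telomere_cluster_length
        + (config.rdna_unit_length if want_rdna else 0)
    )
    if demand >= 0.8 * layout.total_bp:
        raise CapacityError(
            f"feature demand {demand} bp >= 80% of the {layout.total_bp} bp genome"
        )
    rng = np.random.default_rng(config.seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    feats: list[FeatureAnnotation] = []

    if want_rdna:
        rdna = _place_nonoverlapping([config.rdna_unit_length], layout, rng, occupied)[0]
        feats.append(
            FeatureAnnotation(
                "rDNA_unit", rdna, "rDNA_repeat", name=f"copies={config.rdna_copies}"
            )
        )
    orf_lengths = [
        int(rng.integers(config.orf_length_range[0], config.orf_length_range[1] + 1))
        for _ in range(config.n_orfs)
    ]
    for i, iv in enumerate(_place_nonoverlapping(orf_lengths, layout, rng, occupied)):
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(
            FeatureAnnotation(
                f"ORF{i + 1:04d}",
                Interval(iv.chrom, iv.start, iv.end, strand),
                "ORF",
            )
        )
    pol3_lengths = [config.pol3_length] * config.n_pol3
    for i, iv in enumerate(_place_nonoverlapping(pol3_lengths, layout, rng, occupied)):
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(
            FeatureAnnotation(
                f"tRNA{i + 1:03d}",
                Interval(iv.chrom, iv.start, iv.end, strand),
                "pol3_gene",
            )
        )
    tel_lengths = [config.telomere_cluster_length] * config.n_telomere_clusters
    for i, iv in enumerate(_place_nonoverlapping(tel_lengths, layout, rng, occupied)):
        feats.append(FeatureAnnotation(f"TEL{i + 1:02d}", iv, "telomeric_repeat"))
    return layout, AnnotationSet(layout, feats)


def simulate_expression(
    annots: AnnotationSet, config: SyntheticConfig, seed: int | None = None
) -> dict[str, float]:
    """Log-normal expression per ORF (location 0, scale 1 by default)."""
    orfs = annots.orfs
    if len(orfs) < 5:
        raise InsufficientGenesError(f"need >= 5 ORFs, got {len(orfs)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    draws = rng.lognormal(config.expr_log_location, config.expr_log_scale, len(orfs))
    return {f.feature_id: float(v) for f, v in zip(orfs, draws)}


def simulate_regulation_classes(
    annots: AnnotationSet,
    expr: Mapping[str, float],
    config: SyntheticConfig,
    seed: int | None = None,
) -> dict[str, str]:
    """Partition ORFs into down / up / unchanged at a simulated diauxic
    shift.

    Highly expressed (fermentation-program) genes are biased toward the
    "down" class and away from "up", with strength ``regulation_bias``; bias
    0 gives a uniform partition.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = sorted(expr, key=lambda g: (expr[g], g))
    n = len(genes)
    rank_frac = (np.arange(n) + 0.5) / n
    n_down = round(config.frac_down * n)
    n_up = round(config.frac_up * n)
    classes = {g: "unchanged" for g in genes}
    w_down = np.exp(config.regulation_bias * (rank_frac - 0.5))
    down_idx = rng.choice(n, size=n_down, replace=False, p=w_down / w_down.sum())
    for i in down_idx:
        classes[genes[i]] = "down"
    remaining = [i for i in range(n) if classes[genes[i]] == "unchanged"]
    w_up = np.exp(-config.regulation_bias * (rank_frac[remaining] - 0.5))
    up_idx = rng.choice(remaining, size=min(n_up, len(remaining)), replace=False,
                        p=w_up / w_up.sum())
    for i in up_idx:
        classes[genes[i]] = "up"
    return classes


def factor_multiplier(
    model: FactorModel,
    layout: GenomeLayout,
    annots: AnnotationSet,
    expr: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Per-base enrichment multiplier m(x) for a factor.

    Four terms — 3'-ramped ORF coating scaled by expression quintile,
    exponentially decaying telomeric spreading, promoter plateaus, and broad
    Pol III plateaus — combined pointwise by maximum, never below 1.
    """
    k = len(model.orf_quintile_scaling)
    quintiles = assign_quintiles(expr, MetageneParams(n_quantiles=k))
    m = {c: np.ones(layout.length_of(c)) for c in layout.chrom_names}

    for orf in annots.orfs:
        iv = orf.interval
        F = model.orf_3prime_fold * model.orf_quintile_scaling[quintiles[orf.feature_id] - 1]
        L = iv.length
        frac = np.arange(L) / (L - 1) if L > 1 else np.ones(1)
        ramp = 1.0 + (F - 1.0) * frac
        if iv.strand == "-":
            ramp = ramp[::-1]
        np.maximum(m[iv.chrom][iv.start : iv.end], ramp, out=m[iv.chrom][iv.start : iv.end])

    if model.telomere_fold > 1:
        reach = int(model.telomere_decay_bp * np.log((model.telomere_fold - 1) / 0.01)) + 1
        for tel in annots.features_of_class("telomeric_repeat"):
            iv = tel.interval
            arr = m[iv.chrom]
            np.maximum(arr[iv.start : iv.end], model.telomere_fold,
                       out=arr[iv.start : iv.end])
            for side in ("left", "right"):
                if side == "left":
                    lo, hi = max(0, iv.start - reach), iv.start
                    d = iv.start - np.arange(lo, hi)
                else:
                    lo, hi = iv.end, min(len(arr), iv.end + reach)
                    d = np.arange(lo, hi) - iv.end + 1
                if lo < hi:
                    decay = 1.0 + (model.telomere_fold - 1.0) * np.exp(
                        -d / model.telomere_decay_bp
                    )
                    np.maximum(arr[lo:hi], decay, out=arr[lo:hi])

    def plateau(center: int, width: int, fold: float, chrom: str) -> None:
        if fold <= 1 or width < 1:
            return
        arr = m[chrom]
        lo = max(0, center - width // 2)
        hi = min(len(arr), lo + width)
        np.maximum(arr[lo:hi], fold, out=arr[lo:hi])

    for orf in annots.orfs:
        iv = orf.interval
        tss = iv.start if iv.strand == "+" else iv.end - 1
        plateau(tss, model.promoter_width, model.promoter_fold, iv.chrom)
    for g in annots.features_of_class("pol3_gene"):
        iv = g.interval
        plateau((iv.start + iv.end) // 2, model.pol3_width, model.pol3_fold, iv.chrom)
    return m


def _reads_from_rates(
    rates: dict[str, np.ndarray],
    config: SyntheticConfig,
    rng: np.random.Generator,
    annots: AnnotationSet,
) -> ReadSet:
    """Poisson read starts per base from the rate arrays, plus multimappers
    confined to the rDNA unit."""
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    rl = config.read_length
    for chrom, lam in rates.items():
        n_start = len(lam) - rl + 1
        if n_start <= 0:
            continue
        counts = rng.poisson(lam[:n_start])
        pos = np.repeat(np.arange(n_start, dtype=np.int64), counts)
        starts.append(pos)
        chroms.append(np.full(len(pos), chrom, dtype=object))
    start_arr = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    chrom_arr = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    n_unique = len(start_arr)

    rdna = annots.features_of_class("rDNA_repeat")
    n_multi = 0
    if rdna and config.multimapper_fraction > 0:
        unit = rdna[0].interval
        n_multi = rng.poisson(config.multimapper_fraction * max(n_unique, 1))
        multi_starts = rng.integers(unit.start, unit.end - rl + 1, size=n_multi)
        start_arr = np.concatenate([start_arr, multi_starts.astype(np.int64)])
        chrom_arr = np.concatenate([chrom_arr, np.full(n_multi, unit.chrom, dtype=object)])

    n = len(start_arr)
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    mapqs = np.full(n, 60, dtype=np.int64)
    multi = np.zeros(n, dtype=bool)
    if n_multi:
        mapqs[n_unique:] = 0
        multi[n_unique:] = True
    order = np.lexsort((start_arr, chrom_arr.astype(str)))
    return ReadSet.from_columns(
        chrom_arr[order], start_arr[order], strands[order], mapqs[order],
        multi[order], rl,
    )


def simulate_factor_reads(
    model: FactorModel,
    layout: GenomeLayout,
    annots: AnnotationSet,
    expr: Mapping[str, float],
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[ReadSet, ReadSet]:
    """(chip, input) read sets.

    Input read starts are uniform Poisson; chip starts are Poisson with the
    background intensity modulated by the factor's multiplier track.  With
    ``scale_to_library`` the intensities are rescaled so each library's
    expected uniquely-mapped read count equals ``library_size``; otherwise
    ``background_rate`` is used as given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = factor_multiplier(model, layout, annots, expr)
    chip_rates = {c: config.background_rate * m[c] for c in m}
    input_rates = {
        c: np.full(layout.length_of(c), config.background_rate) for c in layout.chrom_names
    }
    if config.scale_to_library:
        chip_total = sum(r.sum() for r in chip_rates.values())
        input_total = sum(r.sum() for r in input_rates.values())
        chip_rates = {c: r * (config.library_size / chip_total) for c, r in chip_rates.items()}
        input_rates = {c: r * (config.library_size / input_total) for c, r in input_rates.items()}
    chip = _reads_from_rates(chip_rates, config, rng, annots)
    inp = _reads_from_rates(input_rates, config, rng, annots)
    return chip, inp


def resample_reads(reads: ReadSet, target: int, seed: int = 0) -> ReadSet:
    """Multinomial resampling to an exact library size; relative rates are
    preserved within multinomial error."""
    if reads.total_count == 0:
        raise ValueError("cannot resample an empty ReadSet")
    rng = np.random.default_rng(seed)
    idx = rng.choice(reads.total_count, size=target, replace=target > reads.total_count)
    idx.sort()
    return reads.subset(idx)


@dataclass(frozen=True)
class PeakSetDesign:
    """Overlap design for k synthetic peak sets with exact sharing."""

    n_sets: int = 3
    n_peaks: int = 100
    peak_length: int = 400
    shared_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.n_sets < 1 or self.n_peaks < 1:
            raise ValueError("n_sets and n_peaks must be >= 1")


def simulate_peak_sets(
    design: PeakSetDesign, layout: GenomeLayout, seed: int = 0
) -> list[PeakSet]:
    """Shared peaks placed once and copied into every set; private peaks
    placed independently, disjoint within each set, so realized pairwise
    shared counts equal the design exactly."""
    rng = np.random.default_rng(seed)
    n_shared = round(design.shared_fraction * design.n_peaks)
    occupied: dict[str, list[tuple[int, int]]] = {}
    shared = _place_nonoverlapping(
        [design.peak_length] * n_shared, layout, rng, occupied
    )
    sets = []
    for i in range(design.n_sets):
        occ = {c: list(v) for c, v in occupied.items()}
        private = _place_nonoverlapping(
            [design.peak_length] * (design.n_peaks - n_shared), layout, rng, occ
        )
        peaks = [
            Peak(iv, posterior=float(rng.uniform(0.51, 1.0)), score=1.0)
            for iv in shared + private
        ]
        sets.append(PeakSet(f"set{i + 1}", peaks))
    return sets


def write_expression_tsv(expr: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for g in sorted(expr):
            fh.write(f"{g}\t{expr[g]!r}\n")


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    out = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if line.strip():
            g, v = line.split("\t")
            out[g] = float(v)
    return out


def write_regulation_tsv(classes: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tregulation\n")
        for g in sorted(classes):
            fh.write(f"{g}\t{classes[g]}\n")


def read_regulation_tsv(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if line.strip():
            g, v = line.split("\t")
            out[g] = v
    return out


def write_config(config: SyntheticConfig, path: str | Path) -> None:
    """Plain key: value config file."""
    with open(path, "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k}: {v}\n")
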