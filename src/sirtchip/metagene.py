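"""Expression-stratified metagene composite profiles.

Every ORF body is rescaled to a fixed number of bins (default 1,000), with
single-bp flank bins on each side (default 500 up and 500 down, in
transcription orientation); genes are stratified into expression quantiles
(default quintiles, label 5 = highest expression) and each row of the
composite is the per-bin mean over the genes in that quantile.  Bin values
are mean per-base coverage, so profile height does not depend on gene
length; flank bins that fall off a chromosome end are recorded as missing
(NaN) and ignored by the composite mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .coverage import CoverageTrack
from .genome import AnnotationSet, FeatureAnnotation, StrandError


class InsufficientGenesError(ValueError):
    """Fewer genes than quantile groups."""


@dataclass(frozen=True)
class MetageneParams:
    n_orf_bins: int = 1000
    n_flank_bins: int = 500
    flank_bp_per_bin: int = 1
    n_quantiles: int = 5
    sum_tags: bool = False  # per-bin sum instead of mean (length-dependent)

    def __post_init__(self) -> None:
        for name in ("n_orf_bins", "n_flank_bins", "flank_bp_per_bin", "n_quantiles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_orf_bins


@dataclass
class MetageneProfile:
    matrix: np.ndarray  # (K, n_bins) float, NaN for all-missing bins
    n_genes: tuple[int, ...]
    params: MetageneParams


ExpressionTable = Mapping[str, float]
QuintileAssignment = dict[str, int]


def assign_quintiles(expr: ExpressionTable, params: MetageneParams = MetageneParams()) -> QuintileAssignment:
    """Rank genes ascending by expression (ties broken by gene id, stable)
    and give rank r of n the label floor(r*K/n) + 1; sizes differ by <= 1 and
    label K holds the highest-expressed genes."""
    k = params.n_quantiles
    n = len(expr)
    if n < k:
        raise InsufficientGenesError(f"{n} genes < {k} quantile groups")
    ranked = sorted(expr, key=lambda g: (expr[g], g))
    return {g: (r * k) // n + 1 for r, g in enumerate(ranked)}


def _oriented_window(track: CoverageTrack, gene: FeatureAnnotation, flank_bp: int):
    """(upstream, body, downstream) arrays in transcription orientation,
    NaN-padded where a flank runs off the chromosome."""
    iv = gene.interval
    if iv.strand not in ("+", "-"):
        raise StrandError(f"gene {gene.feature_id!r} is unstranded")
    vals = track.values[iv.chrom]

    def window(lo: int, hi: int) -> np.ndarray:
        out = np.full(hi - lo, np.nan)
        s, e = max(lo, 0), min(hi, len(vals))
        if s < e:
            out[s - lo : e - lo] = vals[s:e]
        return out

    body = vals[iv.start : iv.end].astype(np.float64)
    left = window(iv.start - flank_bp, iv.start)
    right = window(iv.end, iv.end + flank_bp)
    if iv.strand == "+":
        return left, body, right
    return right[::-1], body[::-1], left[::-1]


def gene_profile(
    track: CoverageTrack,
    gene: FeatureAnnotation,
    params: MetageneParams = MetageneParams(),
) -> np.ndarray:
    """Fixed-length bin vector for one gene: n_flank upstream bins, n_orf_bins
    length-normalized body bins, n_flank downstream bins.

    Body bin i holds the mean coverage over bases whose scaled index
    floor(pos*n/L) equals i; genes shorter than n_orf_bins are positionally
    sampled (bin i = coverage at base floor(i*L/n)).  Flank bins sample one
    base each, ``flank_bp_per_bin`` apart.  Minus-strand genes are mirrored
    so index 0 is always the 5' flank edge.
    """
    n = params.n_orf_bins
    flank_bp = params.n_flank_bins * params.flank_bp_per_bin
    up, body, down = _oriented_window(track, gene, flank_bp)
    L = len(body)

    if L >= n:
        idx = (np.arange(L) * n) // L
        sums = np.bincount(idx, weights=body, minlength=n)
        if params.sum_tags:
            body_bins = sums
        else:
            counts = np.bincount(idx, minlength=n)
            body_bins = sums / counts
    else:
        body_bins = body[(np.arange(n) * L) // n]

    # flank bins sample single bases, flank_bp_per_bin apart, nearest-first
    step = params.flank_bp_per_bin
    up_bins = up[::step] if step > 1 else up
    down_bins = down[::step] if step > 1 else down
    return np.concatenate([up_bins[: params.n_flank_bins],
                           body_bins,
                           down_bins[: params.n_flank_bins]])


def composite_profile(
    track: CoverageTrack,
    annots: AnnotationSet,
    quintiles: QuintileAssignment,
    params: MetageneParams = MetageneParams(),
) -> MetageneProfile:
    """Per-quantile arithmetic mean of gene profiles, ignoring missing bins.

    An empty quantile yields an all-NaN row rather than an error.
    """
    orfs = annots.orfs
    missing = [f.feature_id for f in orfs if f.feature_id not in quintiles]
    if missing:
        raise InsufficientGenesError(
            f"quintile assignment misses {len(missing)} ORFs (e.g. {missing[0]!r})"
        )
    k = params.n_quantiles
    sums = np.zeros((k, params.n_bins))
    counts = np.zeros((k, params.n_bins))
    n_genes = [0] * k
    for gene in orfs:
        row = quintiles[gene.feature_id] - 1
        vec = gene_profile(track, gene, params)
        ok = ~np.isnan(vec)
        sums[row, ok] += vec[ok]
        counts[row, ok] += 1
        n_genes[row] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(counts > 0, sums / counts, np.nan)
    return MetageneProfile(matrix, tuple(n_genes), params)


def write_profile(profile: MetageneProfile, path: str | Path) -> None:
    """TSV matrix (rows = quantiles) plus a JSON sidecar with parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("quantile\t" + "\t".join(f"bin{i}" for i in range(profile.matrix.shape[1])) + "\n")
        for r in range(profile.matrix.shape[0]):
            vals = "\t".join(format(v, ".6g") for v in profile.matrix[r])
            fh.write(f"{r + 1}\t{vals}\n")
    sidecar = {"params": asdict(profile.params), "n_genes": list(profile.n_genes)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n"
    )
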