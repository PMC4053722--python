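"""Peak containers, posterior filtering, and a simple input-relative binned
peak caller.

Externally produced peak calls (e.g. from a Bayesian HMM caller) enter
through :class:`PeakSet` with their per-peak posterior probabilities and are
filtered with a strict ``posterior > threshold`` rule.  The built-in caller
is deliberately simple plumbing: fixed-width bins of read-start counts,
Poisson upper-tail p-values against the scaled input, Benjamini-Hochberg
control, and gap-merging of significant bins.  It makes no claim of
reproducing any particular HMM caller's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

from .coverage import CoverageTrack
from .genome import GenomeError, Interval, ParseError


@dataclass(frozen=True)
class Peak:
    interval: Interval
    posterior: float = 1.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")
        if self.score < 0:
            raise ValueError("peak score must be non-negative")


class PeakSet:
    """Position-sorted, non-overlapping peaks for one factor.

    Overlapping input peaks are merged at construction (interval union,
    posterior = max, score = sum).
    """

    def __init__(self, factor_name: str, peaks: Iterable[Peak]):
        self.factor_name = factor_name
        srt = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        merged: list[Peak] = []
        for p in srt:
            if merged and merged[-1].interval.overlaps(p.interval):
                q = merged[-1]
                merged[-1] = Peak(
                    Interval(
                        q.interval.chrom,
                        q.interval.start,
                        max(q.interval.end, p.interval.end),
                        q.interval.strand,
                    ),
                    max(q.posterior, p.posterior),
                    q.score + p.score,
                )
            else:
                merged.append(p)
        self.peaks: tuple[Peak, ...] = tuple(merged)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    @property
    def total_bp(self) -> int:
        return sum(p.interval.length for p in self.peaks)


@dataclass(frozen=True)
class BinnedCallerParams:
    bin_width: int = 50
    fdr: float = 0.05
    merge_gap: int = 100
    min_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")


def filter_peaks_by_posterior(peaks: PeakSet, threshold: float) -> PeakSet:
    """Retain peaks whose posterior strictly exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return PeakSet(peaks.factor_name, [p for p in peaks if p.posterior > threshold])


def _bin_counts(arr: np.ndarray, width: int) -> np.ndarray:
    edges = np.arange(0, len(arr), width)
    return np.add.reduceat(arr, edges)


def call_peaks_binned(
    chip: CoverageTrack,
    input: CoverageTrack,
    params: BinnedCallerParams = BinnedCallerParams(),
    factor_name: str = "chip",
) -> PeakSet:
    """Input-relative Poisson test on fixed-width bins of read-start counts.

    Per bin the chip start count ``c`` is tested against lambda = s*n, where
    ``n`` is the input bin count and ``s`` the chip/input library ratio;
    lambda is floored at the genome-wide mean chip bin count so empty input
    bins do not produce spurious calls.  Benjamini-Hochberg runs across all
    bins; significant bins with fold >= min_fold are merged when separated by
    at most ``merge_gap`` bp.  Each peak carries score = sum(c - lambda) and
    a posterior surrogate 1 - min(adjusted q) over its bins.
    """
    if set(chip.values) != set(input.values) or any(
        len(chip.values[c]) != len(input.values[c]) for c in chip.values
    ):
        raise GenomeError("chip and input tracks do not share a layout")
    input_total = input.total_signal
    if input_total <= 0:
        raise ValueError("input track has zero reads")
    s = chip.total_signal / input_total

    chroms: list[str] = []
    bin_lo: list[np.ndarray] = []
    c_all: list[np.ndarray] = []
    lam_all: list[np.ndarray] = []
    for chrom in chip.values:
        c = _bin_counts(chip.values[chrom], params.bin_width).astype(np.float64)
        n = _bin_counts(input.values[chrom], params.bin_width).astype(np.float64)
        chroms.extend([chrom] * len(c))
        bin_lo.append(np.arange(len(c)) * params.bin_width)
        c_all.append(c)
        lam_all.append(s * n)
    c = np.concatenate(c_all)
    lam = np.concatenate(lam_all)
    lam = np.maximum(lam, c.mean())  # stabilizer for empty input bins
    lo = np.concatenate(bin_lo)
    chrom_arr = np.asarray(chroms, dtype=object)

    # upper-tail Poisson P(X >= c | lam)
    p = stats.poisson.sf(c - 1, lam)
    q = stats.false_discovery_control(p, method="bh")
    sig = (q <= params.fdr) & (c / lam >= params.min_fold)

    peaks: list[Peak] = []
    idx = np.flatnonzero(sig)
    lengths = {ch: len(v) for ch, v in chip.values.items()}
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run:
            return
        ch = str(chrom_arr[run[0]])
        start = int(lo[run[0]])
        end = min(int(lo[run[-1]]) + params.bin_width, lengths[ch])
        score = float(np.sum(c[run] - lam[run]))
        posterior = float(1.0 - np.min(q[run]))
        peaks.append(Peak(Interval(ch, start, end), posterior, max(score, 0.0)))

    for i in idx:
        if run and (
            chrom_arr[i] != chrom_arr[run[-1]]
            or lo[i] - (lo[run[-1]] + params.bin_width) > params.merge_gap
        ):
            flush(run)
            run = []
        run.append(int(i))
    flush(run)
    return PeakSet(factor_name, peaks)


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED6 with score = round(posterior*1000); exact posteriors and scores
    go to a ``<path>.tsv`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh, open(path.with_suffix(path.suffix + ".tsv"), "w") as side:
        side.write("chrom\tstart\tend\tfactor\tposterior\tscore\n")
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.factor_name}\t"
                f"{round(p.posterior * 1000)}\t{iv.strand}\n"
            )
            side.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.factor_name}\t"
                f"{p.posterior!r}\t{p.score!r}\n"
            )


def read_peaks_bed(
    path: str | Path, factor_name: str | None = None, score_is_posterior: bool = True
) -> PeakSet:
    """Load a BED peak file; the sidecar TSV, when present, restores exact
    posteriors.  Without a sidecar, column 5 is read as posterior*1000 when
    ``score_is_posterior`` else kept as a generic score with posterior 1."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".tsv")
    peaks: list[Peak] = []
    name = factor_name
    if sidecar.exists():
        for lineno, line in enumerate(sidecar.read_text().splitlines()[1:], start=2):
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{sidecar}:{lineno}: expected 6 columns")
            name = name or parts[3]
            peaks.append(
                Peak(Interval(parts[0], int(parts[1]), int(parts[2])),
                     float(parts[4]), float(parts[5]))
            )
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            iv = Interval(parts[0], int(parts[1]), int(parts[2]))
            name = name or (parts[3] if len(parts) > 3 else "peaks")
            raw = float(parts[4]) if len(parts) > 4 else 1000.0
            if score_is_posterior:
                peaks.append(Peak(iv, min(raw / 1000.0, 1.0), raw))
            else:
                peaks.append(Peak(iv, 1.0, raw))
    return PeakSet(name or "peaks", peaks)
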