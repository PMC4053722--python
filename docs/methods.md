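# Methods

## Coordinate model

All intervals are 0-based half-open on an explicit chromosome layout;
conversion to 1-based formats (GFF3 in, wiggle out) happens only at I/O
boundaries. Feature classes are study-specific (`ORF`, `pol3_gene`,
`telomeric_repeat`, `rDNA_repeat`, `other`) and are attached at load time
through a user-supplied mapping from the file's type key; unmapped keys
become `other` with a logged warning, because no annotation format carries
these classes natively. The positional index is an interval tree per
chromosome and is tested against a brute-force linear scan.

## Alignment filter and coverage

The filter keeps uniquely mapping reads with MAPQ ≥ 20 (inclusive; the
conventional reading of a mapping-quality cutoff of 20) and keeps
multimapping reads only where they overlap a repeat whitelist, by default
the single annotated rDNA unit. Whitelisted multimappers bypass the MAPQ
test, since a multimapper's MAPQ is near zero by construction.

Coverage is a direct pileup: the value at a base is the number of read
intervals containing it, with no fragment-length extension, duplicate
removal, or smoothing. Two invariants pin the implementation down exactly:
Σ coverage = Σ read lengths for every read set, and per-base equality with
a naive counter on small random genomes. Track normalization multiplies by
`reference_total / total_mapped_reads`; the scale is always defined
relative to the raw counts, so renormalizing an already scaled track equals
normalizing the original (exact linearity). rDNA reads are compiled into a
profile in repeat-unit coordinates as **raw sums** over the whole tandem
array (copy-number metadata is carried but not divided out), with an
optional per-copy mode; the raw sum is what makes the repeat array's read
mass directly comparable to single-copy loci.

Dense per-base arrays are used throughout; they are the right trade-off for
genomes up to ~100 Mb, which is this package's intended scale.

## Peak handling

Externally produced peak calls carry a per-peak posterior probability and
are filtered with a strict `posterior > threshold` rule (default 0.5), so a
peak at exactly the threshold is dropped. Within a set, overlapping peaks
are merged at construction (posterior = max, score = sum), making every
`PeakSet` sorted and non-overlapping — the precondition for all overlap
arithmetic downstream.

The built-in caller is plumbing, not a contribution: it exists so the
pipeline runs end-to-end on synthetic reads, and it deliberately makes no
claim of matching any HMM-based caller's output. It bins read 5′-start
counts (not per-base coverage) into fixed 50 bp bins, so bin counts are
independent Poisson under a uniform null and Benjamini–Hochberg across bins
is valid. Per bin, the chip count *c* is tested against λ = s·n (n = input
bin count, s = library-size ratio), with λ floored at the genome-wide mean
chip bin count so empty input bins cannot generate calls from nothing; the
floor makes the test conservative in high-input bins, which is the right
failure direction for a screening caller. Significant bins (BH q ≤ fdr,
fold ≥ 2) merge across gaps ≤ 100 bp; the peak's posterior surrogate is
1 − min(q), letting called peaks flow through the same posterior filter as
external calls. Calibration (false-positive genomes ≤ 2× nominal FDR over
200 null genomes) and recall (≥ 95% of planted 10-fold spikes) are part of
the test suite.

## Peak annotation and binding calls

A peak's location class is the one with maximal bp overlap among ORF,
Pol III gene, telomeric repeat, promoter, and intergenic (the remainder);
exact ties break by a fixed priority order (ORF first), making the
classification total and deterministic. The promoter category is not
operationally standard, so it is defined here as a fixed 500 bp
strand-aware window upstream of the ORF start — a conventional yeast
intergenic scale — and is configurable. Both per-peak counts (headline) and
per-class bp are reported.

ORF binding uses the union of peak intervals: a gene is bound when coverage
strictly exceeds 60% of the ORF. Peaks overlapping two ORFs contribute to
both genes; no exclusive assignment is attempted, because adjacent coated
genes are independently scored phenomena.

## Metagene composites

Gene bodies are rescaled to 1,000 bins; bin *i* averages the bases whose
scaled index floor(pos·1000/L) equals *i*, in transcription orientation
(minus-strand genes fully mirrored). Averaging (rather than summing) makes
profile height independent of gene length, which is what makes quintile
rows with different length distributions comparable; a sum mode is
available behind a flag. Genes shorter than 1,000 bp are positionally
sampled (bin *i* = coverage at base floor(i·L/1000)) rather than left with
empty bins. Flanks are 500 single-bp bins per side in genomic (not
length-normalized) units; flank bins falling off a chromosome end are
recorded as missing and ignored by the composite mean, and flanks
overlapping neighboring genes are not masked by default. Expression
quintiles are assigned by ascending rank with ties broken lexically by gene
id: rank *r* of *n* gets label floor(r·K/n)+1, so group sizes differ by at
most one and the top label always holds the maximum. An empty quantile
yields an all-missing row rather than an error.

## Overlap enrichment

The randomization null re-places the **peaks**, each uniformly on its own
chromosome with length preserved and overlaps among placed peaks permitted,
while feature annotations stay fixed — features are fixed biology, peaks
are the sampled object. Every result records the null definition, seed,
permutation count, and null SD. Two observed statistics are available:
`feature_count` (distinct features hit by ≥ 1 peak; natural for discrete
features like Pol III genes or telomeric clusters) and `bp` (union bp
overlap; natural for peak-vs-peak comparisons), and the empirical p uses
the add-one estimator so it is never zero. The Monte-Carlo machinery is
tested against exhaustive placement enumeration on a 100 bp toy genome.

Gene-set overlaps use the upper-tail hypergeometric probability (verified
against exact combinatorial enumeration for all universes ≤ 12);
multi-way comparisons report all 2ᵏ−1 exclusive Venn regions plus pairwise
tests. The regulation-class association test is two-sided by summation of
all hypergeometric outcomes at most as probable as the observed one (with a
1e-9 relative tolerance for floating-point pmf ties), a convention stated
explicitly because "two-sided" is ambiguous for discrete tests.

## Synthetic data: what it emulates

The generator plants the four signal classes the analysis is designed to
detect, on top of a uniform Poisson background shared with the input
library:

- **ORF coating:** per-base multiplier ramps linearly from 1 at the 5′ end
  to `orf_3prime_fold × quintile_scaling[q]` at the 3′-terminal base,
  strand-oriented. The default scaling (0.2, 0.4, 0.6, 0.8, 1.0) with fold
  5 gives effective 3′ folds of 1–5 across quintiles.
- **Telomeric repeats:** full `telomere_fold` (default 30) inside a
  cluster, decaying outside as 1 + (fold−1)·e^(−d/1000 bp). The decay is
  applied symmetrically on both sides: clusters are placed anywhere in the
  genome (terminal and internal clusters behave alike), so "inward" has no
  preferred direction.
- **Promoters:** a plateau (default 6×, 150 bp) centered on each ORF start.
- **Pol III genes:** a broad plateau (default 10×, 500 bp) on the midpoint.

Terms combine pointwise by **maximum**, not product, so coincident regions
(a promoter abutting a telomere cluster) do not compound unrealistically.
Reads are fixed-length intervals sampled as Poisson counts per start
position; with `scale_to_library` (default) intensities are rescaled so
each library's expected size is `library_size`. Multimapping reads
(MAPQ 0) are confined to the rDNA unit at a configurable fraction of the
library, mirroring the repeat policy of the filter. Expression is
log-normal (location 0, scale 1) for a heavy right tail that separates the
top quintile. Regulation classes partition the ORFs 30/30/40 into
down/up/unchanged with an expression-rank bias (strength 2.0): highly
expressed genes preferentially "down", mirroring the fermentation program
shutting off at the diauxic shift. Every generator is a pure function of
(config, seed).

**Default study scale:** 4 chromosomes × 200 kb, 250 ORFs of 600–2,000 bp
(roughly yeast gene density), 20 Pol III genes, 8 telomeric clusters of
300 bp, one 9.1 kb rDNA unit with 175-copy metadata, 50 bp reads, 2 × 10⁵
reads per library. These sizes keep the full test suite and the acceptance
script in the tens of seconds while leaving every per-quintile group with
50 genes.

What the simulation does **not** model: sequence content (no FASTA, no GC
bias, no mappability structure), sequencing error, fragment-length
variation, duplicate reads, or copy-number variation. Passing the planted-
truth tests therefore demonstrates the correctness of the downstream
arithmetic and the statistical calibration of the tests under idealized
Poisson sampling — not robustness to the biases of real libraries.

## Numerical and design choices

- Quintile ranking ties break lexically by gene id, making assignment
  deterministic under permutation of input order.
- Classification ties break by a declared priority order, never by
  insertion order.
- Empirical p-values use (1 + #)/(1 + n); fold over an empty null
  expectation is reported as +∞ with an explicit `saturated` flag rather
  than raising.
- The caller floors λ at the mean chip bin count (degenerate-input guard);
  zero-read libraries raise a dedicated error in normalization.
- Feature placement is uniform rejection sampling with bounded retries and
  a capacity error beyond 80% occupancy; placement, like everything else,
  is reproducible from the seed.
- Pipeline manifests contain parameters, seeds, and SHA-256 checksums of
  every output but no timestamps or absolute paths, so reruns are
  byte-identical — determinism is asserted, not assumed.

## Known limitations

- The built-in caller's detection threshold (fold ≥ 2, BH across all bins)
  means gradual 3′ ramps are only called over the portion of the gene body
  where the planted fold exceeds ~2–3; under default conditions the strict
  ">60% of ORF" binding rule therefore yields few bound genes (~10 of
  250), and the regulation-association ratio computed on them is
  underpowered — the calibration of the association statistic itself is
  what the test suite validates. External peak calls with broader support
  do not have this limitation.
- Composite flanks can include neighboring genes' signal (no masking by
  default), visible as raised flank bins at high gene density.
- `feature_count` vs `bp` can give materially different folds for broad
  peaks over small features; both modes are exposed and recorded precisely
  because the right choice depends on the question.
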