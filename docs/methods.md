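# Methods

This note documents the models and procedures implemented in foxcobind, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Coordinates and formats

All coordinates are 0-based, half-open (BED semantics); fetched sequence
always has length `end − start`. Peak files are ENCODE narrowPeak (summit =
start + column-10 offset; an offset of −1 falls back to the interval
midpoint) or plain BED (summit = interval midpoint — made explicit because
peak callers differ in whether they report summits at all). Tag files are
BED6 rows whose start column is the read 5′ anchor. Gene models and
expression tables are headered TSV. FASTA I/O goes through Biopython;
genomes are held in memory as uppercase strings over {A,C,G,T,N}, which is
appropriate for the megabase-scale genomes this package analyses and
simulates.

## Consensus and co-binding partition

Two intervals overlap iff they share at least one base
(`max(starts) < min(ends)` on the same chromosome). Consensus filtering
keeps every primary-caller peak overlapping ≥ 1 confirming-caller peak and
preserves primary coordinates, matching the convention of keeping one
caller's coordinates for downstream work.

Co-binding categories are connected components of the overlap graph over
*all* peaks of *all* factors (within- and between-factor edges alike),
computed by a per-chromosome sorted sweep with union–find. This is the
merge-then-intersect behaviour of standard interval toolchains, and it is
transitive: chained overlaps can join two peaks that do not themselves
touch. Within a component, same-factor peaks that overlap are counted as one
"merged event", so each category reports region counts, raw peak counts and
merged-event counts — Venn diagrams in the literature use either of the last
two, so both are emitted.

The representative summit of a factor in a multi-peak region is that of its
highest-scoring peak, ties broken by leftmost summit. This choice is not
forced by anything upstream; it is configurable in the sense that the
per-region peak lists are retained on `CategoryRegion`. Summit co-localization
is the fraction of shared regions whose two representative summits differ by
≤ 160 bp; the boundary is inclusive (a 160-bp distance counts as "within
160 bp").

## Motif scanning and enrichment

Patterns are IUPAC strings compiled to regular expressions with overlapping
matches enabled; a genome `N` never matches any pattern position. Minus-
strand hits are windows whose reverse complement matches the pattern and are
reported in genome coordinates with the matched sequence in motif
orientation. A window matching on both strands (possible only for
self-reverse-complementary patterns) is reported once, keeping the + strand.
All overlapping occurrences are counted; there is no greedy masking.

Two motif lengths are first-class: the 7-mer core `GTAAACA` and the broader
11-mer `ATGTAAACAAS` (S = G or C); any IUPAC pattern can be substituted. The
per-region motif fraction uses a window of `summit ± window_half` (default
±200 bp, clipped at chromosome ends). Enrichment of k motif-bearing regions
out of n against a background rate p₀ uses the exact binomial tail
(scipy's `binomtest`; the test suite checks it against direct pmf summation
to 1e-12).

The permuted-core survey scores the core plus its 21 single-position
substitutions (22 variants) in peak windows versus background windows; the
background is length-matched positions sampled uniformly from the genome,
10× the peak count, seeded. Variants are ranked by binomial p-value, and a
consensus is derived from the top four variants: at each position the core
base is primary (upper case) and any alternative base carried by a
top-ranked variant is secondary (lower case), e.g. `G/a T A/c A A C/t A`.
A variant with zero background occurrences gets an infinite-ratio sentinel
and a NaN p-value rather than a fabricated number.

## Flanking-base preference (Monte-Carlo)

For a set of peak summits, the observed sample is every genome-wide core
motif occurrence (both strands, with ≥ 5 bp of sequence on each side in
motif orientation) whose start lies within a 200-bp window centred on a
summit. "200 bp regions flanking summits" is read as this centred window
(±100 bp), consistent with the 200-bp summit-spanning window used for motif
searching; the width is a parameter for anyone preferring ±200 bp. Base
counts are tallied at offsets −5…−1, +1…+5 in motif orientation — minus-
strand occurrences contribute reverse-complemented flanks so "upstream"
always means 5′ of the motif as written; this is required for the resulting
frequency matrix (logo export) to be meaningful. Instances with `N` at an
offset are excluded from that offset's counts and tallied separately.

The null resamples the same number of occurrences from the genome-wide
index, uniformly **without replacement** within each of 1000 repetitions
(repetitions independent), matching the idea of "the same number of motifs
taken from the whole genome". Per (offset, base) cell the null mean and
population SD over repetitions give z = (obs − mean)/sd. Significance is
one-sided enrichment at z > 13 SD; depletion beyond −13 SD is flagged
separately rather than folded into the same call. Numerical edge cases: a
zero null SD with a deviating observation is marked significant with a
sentinel infinite z (any deviation from a constant null is infinitely
extreme); zero SD with a matching observation gives z = 0. Population SD
(divide by n_reps) is used because the repetitions fully enumerate the
simulation; at 1000 repetitions the alternative differs by < 0.1%.

Two statistical properties of this design are worth noting. First, the null
index includes the summit-proximal instances themselves, so at small
simulated scales the null mean is pulled toward the observed composition
and z-scores are conservative relative to genome-scale data, where bound
instances are a negligible index fraction. Second, because sampling is
without replacement from a finite index, the null SD carries the
finite-population correction automatically.

## Tag-density profiles

Tags are extended to the assumed fragment length (default 200 bp): a + tag
at p covers [p, p+200), a − tag covers [p−199, p+1), clipped at chromosome
bounds. Coverage in a bin is counted as **bases of fragment overlap**, not
fragment midpoints — robust when bins (default 10 bp) are far narrower than
fragments, and exactly mass-conserving (the matrix total equals the total
fragment-window overlap, which the tests check against a direct count).
Minus-oriented anchors (minus-strand genes) have their columns reversed so
upstream is always plotted left. Anchors off the chromosome are dropped with
a warning count; windows partly past an edge are kept zero-padded. Rows can
be ordered by total signal (descending, stable) for heatmap export; window
half-widths of 5 kb (heatmaps), 1 kb and 500 bp (profiles) are the
conventional choices and are plain parameters.

## Gene assignment and regulation association

A summit is assigned to a gene iff it lies in the strand-aware window
TSS−5 kb … TSS+2 kb (mirrored for − genes), boundaries inclusive. When
several genes qualify the nearest |summit − TSS| wins; exact ties go to the
lexicographically smallest gene id (a deterministic, documented tie-break —
nothing upstream dictates one). Location classes use precedence
promoter > exon > intron > intergenic on the summit position, with the
promoter window defaulting to −1000…+100 around the TSS (a common annotator
default; configurable since no single definition is canonical). Differences
between two location-class proportions are tested with a two-sided Fisher
exact test — the natural exact test for a 2×2 table; the suite verifies it
against full hypergeometric enumeration.

Expression records carry signed linear fold changes (sign = direction,
magnitude ≥ 1); a converter accepts log2 input. A gene is "up" iff
fold change > 1.5 **and** FDR < 0.05, "down" iff fold change < −1.5 and
FDR < 0.05; the inequalities are strict, so boundary values are
"unchanged". The category × regulation table assigns each merged region's
representative summits to genes; a gene hit by regions of multiple
categories is counted once per category and the multiplicity is reported,
since de-duplication policy is a presentation choice. TSS-group metaprofiles
compare up- and down-regulated genes with a seeded random control sampled
from unchanged genes, sized to the mean of the two group sizes.

## Synthetic data: what it emulates and what it does not

The generator plants a fully recorded ground truth (`TruthTable`) so every
downstream stage is scored without re-reading the genome:

- **Genome** — i.i.d. bases (default uniform), default 2 × 1.2 Mb. Uniform
  composition gives a background core-motif density of 2·L/4⁷ (~122
  instances per Mb, both strands).
- **Architecture** — regions are laid out on a 10-kb slot grid, shuffled,
  one region per slot, so planted regions never overlap each other and class
  recovery by partitioning is exact by construction. Each factor of a
  region's class gets one peak (width 200–400 bp) whose summit is jittered
  by ≤ 40 bp around the region anchor; the jitter bound must stay below half
  the minimum width so same-region peaks always overlap. Default class
  counts (30/15/15 specific, 25/15/10 pairwise, 25 triple) keep the full
  study fast while populating every class.
- **Second caller and noise** — a confirming caller re-reports every true
  peak with ±30 bp coordinate jitter; each caller additionally gains 10%
  caller-specific false peaks placed on a 1-kb grid kept clear of all true
  peaks, so false peaks can never be rescued by chance overlap and consensus
  filtering removes exactly the primary caller's false peaks.
- **Motifs and flanks** — one core motif per selected region (class-level
  planting probability, default 1), + strand only (strand symmetry of the
  scanner is tested separately), centred on the region anchor, with the ten
  flanking bases drawn from a configurable per-offset distribution. The
  default plants a 90% A at −2 and 90% T at −1 — the strong 5′ A/T
  preference this analysis is designed to detect.
- **Tags** — signal fragments centred at summit + N(0, 50 bp), strands
  pointing at the summit (+ anchors 5′, − anchors 3′, mirroring real read
  anchors), 20 000 signal + 5 000 uniform background tags per factor by
  default. Signal is allocated to peaks proportionally to the number of
  co-binding factors in the region's class, so average tag density rises
  from factor-specific to triple-shared regions — the qualitative occupancy
  pattern of the real co-binding data.
- **Genes and expression** — one gene per region with its TSS placed within
  ±1.5 kb of the anchor (always inside the assignment window), plus unbound
  filler genes placed ≥ 5.1 kb from every anchor so no planted summit can
  fall in their window; regulated genes draw |fold change| ∈ (1.6, 5) with
  FDR < 0.045, unchanged genes |fold change| < 1.4 with FDR uniform on
  (0.05, 1]. Per-class (P(up), P(down)) defaults concentrate upregulation in
  FOXO3-containing categories and downregulation in FOXK2/FOXJ3-specific
  ones.

Not emulated: read length and sequencing error, duplication and mappability
artifacts, diploid genomes, non-uniform background composition, peaks
without motifs driven by indirect binding, and genes with multiple
transcripts. Passing tests therefore demonstrate correctness of the
analysis machinery and recoverability of planted effects under clean
conditions — not performance on the noise structure of real ChIP-seq.

All generators and analysis stages draw from `numpy.random.default_rng`
seeded from a single master seed split per stage (SHA-256 of
`"{seed}:{stage}"`), so a rerun with the same inputs and seed is
bit-identical, including the Monte-Carlo null and the control-gene sample.

## Problem sizes

The default synthetic study uses a 2.4-Mb genome, 135 regions, three 25k-tag
tracks and ~200 genes; the flanking-preference recovery analyses use a 2-Mb
genome with 500 planted summit-proximal motifs and 1000 resampling
repetitions. These sizes populate every co-binding class, give the
Monte-Carlo statistic enough instances for the planted 90% skews to clear
the 13-SD cut with margin (z ≈ 17–18), and keep a full end-to-end run in
seconds.

## Known limitations

- The overlap partition is transitive; long chains of peaks can fuse regions
  a pairwise-intersection view would keep apart. This matches the cited
  merge behaviour but should be kept in mind for very dense peak sets.
- The flanking statistic's 13-SD rule is an absolute-count criterion whose
  power grows with the number of summit-proximal motif instances; small
  peak sets legitimately flag nothing (see the z dilution note above).
- The permuted-motif survey's background is a design choice (uniform
  length-matched windows, 10× peaks); GC- or repeat-matched backgrounds are
  not implemented.
- `fraction_regions_with_motif` uses a window of 2·window_half + 1 bases
  (symmetric and summit-inclusive), so window edges differ by one base from
  a naive ±window_half slice.
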