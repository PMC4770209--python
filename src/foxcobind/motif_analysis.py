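"""IUPAC motif scanning and motif-frequency statistics.

Scanning is exact-match over IUPAC degeneracy classes (no position-weight
scoring): a window matches when every base falls in the corresponding IUPAC
class. N in the genome never matches. Minus-strand hits are reported in
genome coordinates with the matched sequence given in motif orientation;
windows matching on both strands (palindromic patterns) are reported once,
keeping the + strand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from scipy import stats

from .io_formats import Genome, Peak

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(pattern: str) -> set[str]:
    """All concrete sequences matched by an IUPAC pattern."""
    if not pattern:
        raise ValueError("empty pattern")
    choices = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r}")
        choices.append(IUPAC[ch])
    return {"".join(combo) for combo in product(*choices)}


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r}")
        cls = IUPAC[ch]
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    # lookahead so overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    matched: str  # in motif orientation


def _scan_sequence(seq: str, pattern: str, chrom: str,
                   strands: str) -> list[MotifHit]:
    hits = []
    rx = _pattern_regex(pattern)
    plus_starts = set()
    for m in rx.finditer(seq):
        hits.append(MotifHit(chrom, m.start(), m.start() + len(pattern),
                             "+", m.group(1)))
        plus_starts.add(m.start())
    if strands == "both":
        rc = revcomp(pattern)
        if rc == pattern:
            return hits  # palindromic: minus hits duplicate plus hits
        rx_rc = _pattern_regex(rc)
        for m in rx_rc.finditer(seq):
            if m.start() in plus_starts:
                continue  # window already reported on + strand
            hits.append(MotifHit(chrom, m.start(), m.start() + len(pattern),
                                 "-", revcomp(m.group(1))))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_motif(genome_or_sequence: Genome | str, pattern: str,
               strands: str = "both", chrom: str = "seq") -> list[MotifHit]:
    """All occurrences of an IUPAC pattern; strands in {"plus", "both"}."""
    if strands not in ("plus", "both"):
        raise ValueError(f"strands must be 'plus' or 'both', got {strands!r}")
    pattern = pattern.upper()
    if isinstance(genome_or_sequence, Genome):
        out: list[MotifHit] = []
        for name in genome_or_sequence.chroms:
            out.extend(_scan_sequence(genome_or_sequence[name], pattern,
                                      name, strands))
        return out
    return _scan_sequence(genome_or_sequence.upper(), pattern, chrom, strands)


# ---------------------------------------------------------------------------
# per-region motif statistics
# ---------------------------------------------------------------------------

def _as_summit_list(regions: Iterable) -> list[tuple[str, int]]:
    out = []
    for r in regions:
        if isinstance(r, Peak):
            out.append((r.chrom, r.summit))
        elif isinstance(r, tuple) and len(r) == 2:
            out.append((str(r[0]), int(r[1])))
        else:
            raise TypeError(f"cannot extract (chrom, summit) from {r!r}")
    return out


def _summit_window_counts(regions: Iterable, genome: Genome, pattern: str,
                          window_half: int) -> list[int]:
    counts = []
    for chrom, summit in _as_summit_list(regions):
        chrom_len = genome.lengths[chrom]
        lo = max(0, summit - window_half)
        hi = min(chrom_len, summit + window_half + 1)
        seq = genome.fetch(chrom, lo, hi)
        counts.append(len(_scan_sequence(seq, pattern.upper(), chrom, "both")))
    return counts


def fraction_regions_with_motif(regions: Sequence, genome: Genome,
                                pattern: str,
                                window_half: int = 200) -> tuple[int, int, float]:
    """(k, n, k/n): regions whose summit +/- window_half window (clipped to
    the chromosome) carries >= 1 motif hit on either strand."""
    regions = list(regions)
    if not regions:
        raise ValueError("no regions given")
    counts = _summit_window_counts(regions, genome, pattern, window_half)
    k = sum(c > 0 for c in counts)
    return k, len(counts), k / len(counts)


def motif_count_per_region(regions: Sequence, genome: Genome, pattern: str,
                           window_half: int = 200) -> dict[int, int]:
    """Histogram {hit count -> number of regions} over summit windows."""
    regions = list(regions)
    if not regions:
        raise ValueError("no regions given")
    counts = _summit_window_counts(regions, genome, pattern, window_half)
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    return hist


def binomial_enrichment(k: int, n: int, p0: float,
                        tail: str = "greater") -> float:
    """Exact binomial tail probability of k successes in n trials at rate p0.

    two_sided sums the probabilities of all outcomes no more likely than k.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}
    if tail not in alt:
        raise ValueError(f"tail must be one of {sorted(alt)}")
    return float(stats.binomtest(k, n, p0, alternative=alt[tail]).pvalue)


# ---------------------------------------------------------------------------
# permuted-core-motif survey
# ---------------------------------------------------------------------------

def single_substitution_variants(core: str) -> list[str]:
    """The core plus all single-position substitutions (first)."""
    core = core.upper()
    variants = [core]
    for i, base in enumerate(core):
        for alt in "ACGT":
            if alt != base:
                variants.append(core[:i] + alt + core[i + 1:])
    return variants


@dataclass
class SurveyRow:
    variant: str
    k_peaks: int
    n_peaks: int
    fraction_peaks: float
    fraction_background: float
    ratio: float          # inf when the background fraction is 0
    p_value: float        # nan flags a degenerate (zero-background) test


def permuted_motif_survey(peak_regions: Sequence, background_regions: Sequence,
                          genome: Genome, core: str = "GTAAACA",
                          variants: Sequence[str] | None = None,
                          window_half: int = 200,
                          top_k: int = 4) -> tuple[list[SurveyRow], str]:
    """Occurrence of core-motif variants in bound vs background regions.

    Each variant's peak fraction is tested against the background fraction
    with an exact binomial test; rows are returned ranked by p-value. The
    consensus string marks, per position, the core base (upper case) and any
    alternative base carried by the top-ranked variants (lower case),
    formatted like G/a.
    """
    if variants is None:
        variants = single_substitution_variants(core)
    rows = []
    for v in variants:
        k_p, n_p, f_p = fraction_regions_with_motif(peak_regions, genome, v,
                                                    window_half)
        k_b, n_b, f_b = fraction_regions_with_motif(background_regions, genome,
                                                    v, window_half)
        if f_b == 0.0:
            ratio = math.inf if f_p > 0 else 1.0
            p = math.nan
        else:
            ratio = f_p / f_b
            p = binomial_enrichment(k_p, n_p, f_b, tail="greater")
        rows.append(SurveyRow(v, k_p, n_p, f_p, f_b, ratio, p))
    rows.sort(key=lambda r: (math.isnan(r.p_value), r.p_value, -r.ratio))

    top = [r.variant for r in rows[:top_k]]
    consensus_parts = []
    for i, base in enumerate(core.upper()):
        alts = sorted({v[i] for v in top if v[i] != base})
        if alts:
            consensus_parts.append(f"{base}/{''.join(a.lower() for a in alts)}")
        else:
            consensus_parts.append(base)
    return rows, " ".join(consensus_parts)


def motif_binding_saturation(genome: Genome, pattern: str,
                             bound_regions: Sequence) -> tuple[int, int, float]:
    """(genome-wide instance count, instances starting inside a bound region,
    fraction). Both strands, palindromes counted once."""
    hits = scan_motif(genome, pattern, strands="both")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in bound_regions:
        iv = r.interval if isinstance(r, Peak) else r
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    import bisect
    import itertools
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        max_ends = list(itertools.accumulate((e for _, e in ivs), max))
        index[chrom] = (starts, max_ends)
    n_in = 0
    for h in hits:
        if h.chrom not in index:
            continue
        starts, max_ends = index[h.chrom]
        i = bisect.bisect_right(starts, h.start)
        if i > 0 and max_ends[i - 1] > h.start:
            n_in += 1
    n_total = len(hits)
    return n_total, n_in, (n_in / n_total if n_total else 0.0)
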