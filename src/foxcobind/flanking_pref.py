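"""Monte-Carlo flanking-nucleotide preference statistic.

Base composition is tallied at offsets -flank_span..-1 and +1..+flank_span
around core-motif occurrences found near peak summits, and compared with the
composition of equally sized samples of core-motif occurrences drawn from the
whole genome. The comparison is repeated (default 1000 resamples), and a cell
(offset, base) is called significantly preferred when its observed count lies
more than `sd_threshold` standard deviations above the resampled mean.

All occurrences are handled in motif orientation: a minus-strand occurrence
contributes reverse-complemented flanks, so "upstream" always means 5' of the
motif as written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import Genome
from .motif_analysis import revcomp, scan_motif

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}  # N and friends -> -1


@dataclass(frozen=True)
class MotifOccurrence:
    """A core-motif instance with its oriented flanking bases."""

    chrom: str
    start: int          # genome coordinate of the motif's left end
    strand: str
    upstream: str       # 5' flank in motif orientation, length = flank_span
    downstream: str     # 3' flank in motif orientation


def _offsets(flank_span: int) -> list[int]:
    return list(range(-flank_span, 0)) + list(range(1, flank_span + 1))


@dataclass
class FlankProfile:
    core_motif: str
    flank_span: int
    offsets: list[int]
    observed_counts: np.ndarray        # (n_offsets, 4)
    n_observed: int
    n_excluded: np.ndarray             # per offset, instances with N there
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    z: np.ndarray | None = None
    significant: np.ndarray | None = None   # enriched cells (z > threshold)
    depleted: np.ndarray | None = None      # z < -threshold, reported apart
    sd_threshold: float = 13.0
    n_sim: int = 0
    seed: int | None = None

    def observed_fraction(self) -> np.ndarray:
        totals = self.observed_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.observed_counts / totals, np.nan)


def _flank_codes(occurrences: Sequence[MotifOccurrence],
                 flank_span: int) -> np.ndarray:
    """(n, 2*flank_span) int8 matrix of base codes, -1 for N."""
    n = len(occurrences)
    codes = np.full((n, 2 * flank_span), -1, dtype=np.int8)
    for i, occ in enumerate(occurrences):
        for j, b in enumerate(occ.upstream):
            codes[i, j] = _BASE_CODE.get(b, -1)
        for j, b in enumerate(occ.downstream):
            codes[i, flank_span + j] = _BASE_CODE.get(b, -1)
    return codes


def _count_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset base counts and per-offset N-exclusion tallies."""
    n_off = codes.shape[1]
    counts = np.zeros((n_off, 4), dtype=np.int64)
    excluded = np.zeros(n_off, dtype=np.int64)
    for j in range(n_off):
        col = codes[:, j]
        valid = col >= 0
        counts[j] = np.bincount(col[valid], minlength=4)
        excluded[j] = int((~valid).sum())
    return counts, excluded


def genome_motif_index(genome: Genome, core_motif: str,
                       flank_span: int = 5) -> list[MotifOccurrence]:
    """All core-motif occurrences genome-wide (both strands) that have at
    least flank_span bases of sequence on each side in motif orientation."""
    if flank_span < 1:
        raise ValueError("flank_span must be >= 1")
    core_motif = core_motif.upper()
    m = len(core_motif)
    out = []
    for hit in scan_motif(genome, core_motif, strands="both"):
        seq = genome[hit.chrom]
        lo = hit.start - flank_span
        hi = hit.start + m + flank_span
        if lo < 0 or hi > len(seq):
            continue
        left = seq[lo:hit.start]
        right = seq[hit.start + m:hi]
        if hit.strand == "+":
            up, down = left, right
        else:
            up, down = revcomp(right), revcomp(left)
        out.append(MotifOccurrence(hit.chrom, hit.start, hit.strand, up, down))
    return out


def observed_flanks(summits: Sequence[tuple[str, int]], genome: Genome,
                    core_motif: str, window_total: int = 200,
                    flank_span: int = 5) -> tuple[FlankProfile,
                                                  list[MotifOccurrence]]:
    """Observed flank composition for motif occurrences near peak summits.

    Occurrences are those from the genome-wide index whose start falls in
    [summit - window_total/2, summit + window_total/2) of any given summit.
    """
    index = genome_motif_index(genome, core_motif, flank_span)
    half = window_total // 2
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, summit in summits:
        by_chrom.setdefault(chrom, []).append((summit - half, summit + half))

    import bisect
    import itertools
    windows: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ws in by_chrom.items():
        ws.sort()
        starts = [s for s, _ in ws]
        max_ends = list(itertools.accumulate((e for _, e in ws), max))
        windows[chrom] = (starts, max_ends)

    selected = []
    for occ in index:
        if occ.chrom not in windows:
            continue
        starts, max_ends = windows[occ.chrom]
        i = bisect.bisect_right(starts, occ.start)
        if i > 0 and max_ends[i - 1] > occ.start:
            selected.append(occ)

    if not selected:
        raise ValueError(
            f"no {core_motif} occurrence within {window_total} bp windows of "
            f"{len(list(summits))} summits (genome-wide index size "
            f"{len(index)})"
        )
    codes = _flank_codes(selected, flank_span)
    counts, excluded = _count_matrix(codes)
    profile = FlankProfile(
        core_motif=core_motif, flank_span=flank_span,
        offsets=_offsets(flank_span), observed_counts=counts,
        n_observed=len(selected), n_excluded=excluded,
    )
    return profile, selected


def monte_carlo_null(genome_index: Sequence[MotifOccurrence], n_sample: int,
                     flank_span: int = 5, n_reps: int = 1000,
                     seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Resampled null composition: per rep, draw n_sample occurrences from the
    genome-wide index without replacement and tally flank bases; return the
    per-cell mean and population SD over reps."""
    n_index = len(genome_index)
    if n_sample > n_index:
        raise ValueError(
            f"cannot sample {n_sample} occurrences from an index of size "
            f"{n_index}"
        )
    rng = np.random.default_rng(seed)
    codes = _flank_codes(genome_index, flank_span)
    n_off = codes.shape[1]
    reps = np.zeros((n_reps, n_off, 4), dtype=np.int64)
    onehot = (codes[:, :, None] == np.arange(4, dtype=np.int8)).astype(np.int32)
    for r in range(n_reps):
        pick = rng.choice(n_index, size=n_sample, replace=False)
        reps[r] = onehot[pick].sum(axis=0)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0)  # population SD: reps fully enumerate the simulation
    return mean, sd


SENTINEL_Z = float("inf")


def flank_zscores(profile: FlankProfile, null_mean: np.ndarray,
                  null_sd: np.ndarray, sd_threshold: float = 13.0,
                  n_sim: int = 0, seed: int | None = None) -> FlankProfile:
    """Complete a profile with z-scores and significance calls.

    Significance is one-sided (enrichment); depletion beyond -sd_threshold is
    flagged separately. A cell with zero null SD but a deviating observation
    gets a sentinel infinite z (any deviation from a constant null is
    infinitely extreme); zero SD with a matching observation gives z = 0.
    """
    obs = profile.observed_counts.astype(float)
    z = np.zeros_like(obs)
    nonzero = null_sd > 0
    z[nonzero] = (obs[nonzero] - null_mean[nonzero]) / null_sd[nonzero]
    degenerate = (~nonzero) & (obs != null_mean)
    z[degenerate] = np.sign(obs[degenerate] - null_mean[degenerate]) * SENTINEL_Z
    profile.null_mean = null_mean
    profile.null_sd = null_sd
    profile.z = z
    profile.significant = z > sd_threshold
    profile.depleted = z < -sd_threshold
    profile.sd_threshold = sd_threshold
    profile.n_sim = n_sim
    profile.seed = seed
    return profile


def flank_preference_analysis(summits: Sequence[tuple[str, int]],
                              genome: Genome, core_motif: str = "GTAAACA",
                              window_total: int = 200, flank_span: int = 5,
                              n_reps: int = 1000, sd_threshold: float = 13.0,
                              seed: int | None = None) -> FlankProfile:
    """End-to-end flanking-preference statistic for one set of summits."""
    profile, _ = observed_flanks(summits, genome, core_motif,
                                 window_total=window_total,
                                 flank_span=flank_span)
    index = genome_motif_index(genome, core_motif, flank_span)
    mean, sd = monte_carlo_null(index, n_sample=profile.n_observed,
                                flank_span=flank_span, n_reps=n_reps,
                                seed=seed)
    return flank_zscores(profile, mean, sd, sd_threshold=sd_threshold,
                         n_sim=n_reps, seed=seed)


def flank_matrix_export(profile: FlankProfile) -> "pd.DataFrame":
    """Position-frequency matrix over flank offsets and core positions,
    columns A,C,G,T summing to 1 per row, with the enrichment mask attached
    for flank rows (core rows carry the fixed core base)."""
    import pandas as pd

    rows = []
    frac = profile.observed_fraction()
    span = profile.flank_span
    core = profile.core_motif

    def flank_row(offset_idx: int, position_label: str) -> dict:
        row = {"position": position_label}
        for b_i, b in enumerate(BASES):
            row[b] = float(frac[offset_idx, b_i])
        if profile.significant is not None:
            row["significant"] = "".join(
                b for b_i, b in enumerate(BASES)
                if profile.significant[offset_idx, b_i]
            )
        else:
            row["significant"] = ""
        return row

    for j in range(span):
        rows.append(flank_row(j, str(profile.offsets[j])))
    for i, base in enumerate(core):
        row = {"position": f"core{i + 1}", "significant": ""}
        for b in BASES:
            row[b] = 1.0 if b == base else 0.0
        rows.append(row)
    for j in range(span, 2 * span):
        rows.append(flank_row(j, f"+{profile.offsets[j]}"))
    df = pd.DataFrame(rows, columns=["position", *BASES, "significant"])
    return df
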