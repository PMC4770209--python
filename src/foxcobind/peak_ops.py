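"""Consensus peak retention, n-way overlap partitioning and summit statistics.

Two peaks overlap iff they share at least one base. Co-binding categories are
the connected components of the overlap graph over all factors' peaks: each
component becomes one merged region labelled by the exact subset of factors
contributing at least one peak. Chained overlaps therefore join peaks that do
not themselves touch — the same transitive behaviour as merge-then-intersect
interval toolchains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GenomicInterval, Peak, PeakSet


def overlap(a: GenomicInterval | Peak, b: GenomicInterval | Peak) -> bool:
    """True iff the two intervals share >= 1 bp (same chromosome)."""
    ai = a.interval if isinstance(a, Peak) else a
    bi = b.interval if isinstance(b, Peak) else b
    return ai.chrom == bi.chrom and max(ai.start, bi.start) < min(ai.end, bi.end)


def consensus_peaks(primary_set: PeakSet, confirm_set: PeakSet) -> PeakSet:
    """Retain primary-caller peaks confirmed by >= 1 bp overlap with any
    confirming-caller peak; primary coordinates and summits are kept."""
    import bisect
    import itertools

    # per chromosome: starts sorted, with the running max of ends alongside;
    # some interval with start < q_end overlaps [q_start, q_end) iff the max
    # end over that prefix exceeds q_start
    index: dict[str, tuple[list[int], list[int]]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in confirm_set:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        max_ends = list(itertools.accumulate((e for _, e in ivs), max))
        index[chrom] = (starts, max_ends)

    kept = []
    for p in primary_set:
        if p.chrom not in index:
            continue
        starts, max_ends = index[p.chrom]
        i = bisect.bisect_left(starts, p.end)
        if i > 0 and max_ends[i - 1] > p.start:
            kept.append(p)
    return PeakSet(label=primary_set.label, peaks=kept)


@dataclass
class CategoryRegion:
    """One merged region: the union span of a connected overlap component."""

    interval: GenomicInterval
    factors: frozenset[str]
    peaks: dict[str, list[Peak]] = field(default_factory=dict)

    def representative_peak(self, factor: str) -> Peak:
        """Highest-score peak of the factor; ties broken by leftmost summit."""
        if factor not in self.peaks:
            raise KeyError(f"factor {factor!r} absent from region")
        return min(self.peaks[factor], key=lambda p: (-p.score, p.summit, p.start))

    def summit(self, factor: str) -> int:
        return self.representative_peak(factor).summit

    def merged_events(self, factor: str) -> int:
        """Number of within-factor merged peaks (overlapping same-factor
        peaks count as a single event)."""
        ivs = sorted((p.start, p.end) for p in self.peaks.get(factor, ()))
        n = 0
        cur_end = -1
        for s, e in ivs:
            if s >= cur_end:
                n += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
        return n


@dataclass
class CategoryPartition:
    """Merged regions grouped by the exact subset of bound factors."""

    factors: tuple[str, ...]
    regions: list[CategoryRegion]

    def by_category(self) -> dict[frozenset[str], list[CategoryRegion]]:
        out: dict[frozenset[str], list[CategoryRegion]] = {}
        for r in self.regions:
            out.setdefault(r.factors, []).append(r)
        return out

    def category(self, *factors: str) -> list[CategoryRegion]:
        want = frozenset(factors)
        return [r for r in self.regions if r.factors == want]

    def counts(self) -> dict[frozenset[str], int]:
        """Merged-region count per category."""
        return {cat: len(rs) for cat, rs in self.by_category().items()}

    def venn_table(self) -> list[dict]:
        """Per category: region count plus raw-peak and merged-event counts
        per member factor (the two countings a Venn diagram may use)."""
        rows = []
        for cat, regions in sorted(self.by_category().items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            row: dict = {
                "category": "+".join(sorted(cat)),
                "n_regions": len(regions),
            }
            for f in sorted(cat):
                row[f"{f}_raw_peaks"] = sum(len(r.peaks.get(f, ())) for r in regions)
                row[f"{f}_merged_events"] = sum(r.merged_events(f) for r in regions)
            rows.append(row)
        return rows


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def partition(factor_sets: list[PeakSet]) -> CategoryPartition:
    """Partition all peaks into co-binding categories.

    Builds the >=1-bp overlap graph over every peak of every factor (within-
    and between-factor edges alike) by a sorted sweep, takes connected
    components, and reports each component as one merged region labelled by
    the set of factors present.
    """
    labels = [ps.label for ps in factor_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate factor labels: {labels}")

    entries: list[tuple[Peak, str]] = []
    for ps in factor_sets:
        for p in ps:
            entries.append((p, ps.label))

    order = sorted(range(len(entries)),
                   key=lambda i: (entries[i][0].chrom, entries[i][0].start,
                                  entries[i][0].end))
    uf = _UnionFind(len(entries))

    # sweep per chromosome: any peak overlapping the current merged run is
    # unioned with it; transitivity makes components = merged runs
    prev_chrom = None
    run_end = -1
    run_rep = -1
    for i in order:
        p = entries[i][0]
        if p.chrom != prev_chrom or p.start >= run_end:
            prev_chrom, run_end, run_rep = p.chrom, p.end, i
        else:
            uf.union(run_rep, i)
            run_end = max(run_end, p.end)

    components: dict[int, list[int]] = {}
    for i in range(len(entries)):
        components.setdefault(uf.find(i), []).append(i)

    regions = []
    for members in components.values():
        peaks_by_factor: dict[str, list[Peak]] = {}
        for i in members:
            p, lab = entries[i]
            peaks_by_factor.setdefault(lab, []).append(p)
        chrom = entries[members[0]][0].chrom
        start = min(entries[i][0].start for i in members)
        end = max(entries[i][0].end for i in members)
        regions.append(CategoryRegion(
            interval=GenomicInterval(chrom, start, end),
            factors=frozenset(peaks_by_factor),
            peaks=peaks_by_factor,
        ))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return CategoryPartition(factors=tuple(labels), regions=regions)


def summit_distances(part: CategoryPartition, factor_a: str,
                     factor_b: str) -> list[int]:
    """|summit_a - summit_b| per region bound by both factors, using one
    representative peak per factor (highest score, tie -> leftmost summit)."""
    shared = [r for r in part.regions
              if factor_a in r.factors and factor_b in r.factors]
    if not shared:
        raise ValueError(
            f"no region bound by both {factor_a!r} and {factor_b!r}"
        )
    return [abs(r.summit(factor_a) - r.summit(factor_b)) for r in shared]


def fraction_within(distances: list[int], cutoff: int) -> float:
    """Fraction of distances <= cutoff (boundary inclusive)."""
    if not distances:
        raise ValueError("no distances given")
    return sum(d <= cutoff for d in distances) / len(distances)
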