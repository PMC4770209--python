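"""Synthetic study generator with recorded ground truth.

Emulates a three-factor ChIP-seq co-binding study: a random genome, planted
binding-region architectures with controlled factor-specific / pairwise /
triple-shared classes, core motifs with configurable flanking-base
preferences, strand-aware tag pileups over summits, gene models whose TSSs
capture their region, and an expression table in which regulation direction
depends on the binding class. Every generator is deterministic under a fixed
seed, and the returned TruthTable is sufficient to score downstream recovery
without re-reading the genome.

Planted regions never overlap one another: regions are laid out on a slot
grid (default 10 kb spacing) so that class recovery by overlap partitioning,
and gene-to-region assignment, are exact by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (ExpressionRecord, GeneModel, Genome, GenomicInterval,
                         Peak, PeakSet, RunConfig, TagTrack)

BASES = "ACGT"

FACTORS = ("K2", "O3", "J3")


@dataclass
class ArchitectureSpec:
    """Counts per co-binding class plus peak-geometry parameters.

    class_counts maps a factor subset (e.g. frozenset({"K2","O3"})) to the
    number of regions of that class. motif_prob gives, per class, the
    probability that a region carries a planted core motif.
    """

    class_counts: dict[frozenset[str], int]
    width_range: tuple[int, int] = (200, 400)
    summit_jitter: int = 40
    motif_prob: Mapping[frozenset[str], float] | float = 1.0
    slot_spacing: int = 10_000

    def __post_init__(self) -> None:
        for cls, n in self.class_counts.items():
            if n < 0:
                raise ValueError(f"negative count for class {sorted(cls)}")
            if not cls:
                raise ValueError("empty factor subset is not a class")
        if self.summit_jitter < 0:
            raise ValueError("summit_jitter must be >= 0")
        lo, hi = self.width_range
        if not (0 < lo <= hi):
            raise ValueError("bad width_range")
        if self.summit_jitter >= lo // 2:
            raise ValueError(
                "summit_jitter must stay below half the minimum width so that "
                "same-region peaks always overlap"
            )

    def motif_probability(self, cls: frozenset[str]) -> float:
        if isinstance(self.motif_prob, Mapping):
            p = self.motif_prob.get(cls, 0.0)
        else:
            p = float(self.motif_prob)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"motif probability {p} outside [0, 1]")
        return p

    @property
    def n_regions(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class FlankPrefSpec:
    """Base probabilities per flank offset (-span..-1, +1..+span)."""

    probs: dict[int, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for off, vec in self.probs.items():
            if off == 0:
                raise ValueError("offset 0 is inside the core motif")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"probabilities at offset {off} must sum to 1")

    @classmethod
    def uniform(cls, span: int = 5) -> "FlankPrefSpec":
        offs = list(range(-span, 0)) + list(range(1, span + 1))
        return cls({o: (0.25, 0.25, 0.25, 0.25) for o in offs})

    def with_preference(self, offset: int, base: str,
                        weight: float) -> "FlankPrefSpec":
        """Copy with `base` at `offset` given probability `weight`, the rest
        shared equally."""
        rest = (1.0 - weight) / 3.0
        vec = tuple(weight if b == base else rest for b in BASES)
        probs = dict(self.probs)
        probs[offset] = vec  # type: ignore[assignment]
        return FlankPrefSpec(probs)

    @property
    def span(self) -> int:
        return max(abs(o) for o in self.probs)


@dataclass
class RegionTruth:
    region_id: str
    chrom: str
    anchor: int                     # planted region anchor (class summit)
    cls: frozenset[str]
    summits: dict[str, int]         # per-factor planted summit
    motif_planted: bool = False
    motif_start: int | None = None


@dataclass
class TruthTable:
    regions: list[RegionTruth] = field(default_factory=list)
    genes: dict[str, tuple[str, str]] = field(default_factory=dict)
    # gene_id -> (class label "K2+O3" or "unbound", planted direction)

    def class_counts(self) -> dict[frozenset[str], int]:
        out: dict[frozenset[str], int] = {}
        for r in self.regions:
            out[r.cls] = out.get(r.cls, 0) + 1
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "regions": [
                {**dataclasses.asdict(r), "cls": sorted(r.cls)}
                for r in self.regions
            ],
            "genes": {g: list(v) for g, v in self.genes.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        regions = [RegionTruth(**{**r, "cls": frozenset(r["cls"])})
                   for r in data["regions"]]
        genes = {g: tuple(v) for g, v in data["genes"].items()}
        return cls(regions=regions, genes=genes)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genome(n_chroms: int, chrom_len: int,
                    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                    seed: int | None = None) -> Genome:
    """I.i.d. random genome; chromosomes named chr1..chrN."""
    if chrom_len <= 0:
        raise ValueError("chrom_len must be > 0")
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("base_probs must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seqs = {}
    for i in range(n_chroms):
        draw = rng.choice(4, size=chrom_len, p=probs)
        seqs[f"chr{i + 1}"] = base_arr[draw].tobytes().decode()
    return Genome(seqs)


def _slot_anchors(genome: Genome, n_needed: int, spacing: int,
                  margin: int, rng: np.random.Generator
                  ) -> list[tuple[str, int]]:
    """Shuffled anchor positions on a slot grid, >= spacing apart."""
    slots = []
    for chrom, length in genome.lengths.items():
        pos = margin
        while pos + margin <= length:
            slots.append((chrom, pos))
            pos += spacing
    if n_needed > len(slots):
        raise ValueError(
            f"genome too small: {n_needed} regions requested but only "
            f"{len(slots)} slots of spacing {spacing} available"
        )
    order = rng.permutation(len(slots))
    return [slots[i] for i in order[:n_needed]]


def simulate_architecture(genome: Genome, spec: ArchitectureSpec,
                          seed: int | None = None
                          ) -> tuple[dict[str, PeakSet], TruthTable]:
    """Plant non-overlapping regions of the requested co-binding classes.

    For a region of class S each factor in S receives one peak whose summit
    deviates from the region anchor by at most summit_jitter; factors outside
    S get nothing there.
    """
    rng = np.random.default_rng(seed)
    margin = spec.width_range[1] + spec.summit_jitter + 300
    anchors = _slot_anchors(genome, spec.n_regions, spec.slot_spacing,
                            margin, rng)

    factors = sorted({f for cls in spec.class_counts for f in cls})
    peaks: dict[str, list[Peak]] = {f: [] for f in factors}
    truth = TruthTable()
    i = 0
    for cls, count in sorted(spec.class_counts.items(),
                             key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        for _ in range(count):
            chrom, anchor = anchors[i]
            rid = f"region_{i:05d}"
            summits = {}
            for f in sorted(cls):
                jitter = int(rng.integers(-spec.summit_jitter,
                                          spec.summit_jitter + 1)) \
                    if spec.summit_jitter else 0
                summit = anchor + jitter
                width = int(rng.integers(spec.width_range[0],
                                         spec.width_range[1] + 1))
                start = summit - width // 2
                end = start + width
                peaks[f].append(Peak(
                    interval=GenomicInterval(chrom, start, end),
                    summit=summit,
                    score=float(rng.uniform(10, 100)),
                    name=f"{rid}_{f}",
                    source=f,
                ))
                summits[f] = summit
            truth.regions.append(RegionTruth(
                region_id=rid, chrom=chrom, anchor=anchor, cls=cls,
                summits=summits,
            ))
            i += 1
    peak_sets = {f: PeakSet(label=f, peaks=ps) for f, ps in peaks.items()}
    return peak_sets, truth


def simulate_confirm_sets(peak_sets: Mapping[str, PeakSet], genome: Genome,
                          coord_jitter: int = 30,
                          false_peak_rate: float = 0.1,
                          slot_spacing: int = 10_000,
                          seed: int | None = None
                          ) -> tuple[dict[str, PeakSet], dict[str, PeakSet]]:
    """Emulate a second, independent peak caller plus caller-specific noise.

    Returns (primary_with_false, confirm): the confirming caller re-reports
    every true peak with jittered coordinates, and each caller additionally
    gains `false_peak_rate` caller-specific peaks placed on otherwise empty
    slots (so they can never be rescued by chance overlap).
    """
    rng = np.random.default_rng(seed)
    # candidate sites for caller-specific false peaks: a 1-kb grid kept clear
    # of every true peak (padded by the jitter plus maximum false-peak width)
    used: dict[str, set[int]] = {}
    for ps in peak_sets.values():
        for p in ps:
            lo = (p.start - coord_jitter - 500) // 1_000
            hi = (p.end + coord_jitter + 500) // 1_000
            used.setdefault(p.chrom, set()).update(range(lo, hi + 1))
    free_slots = []
    for chrom, length in genome.lengths.items():
        blocked = used.get(chrom, set())
        for k in range(1, (length - 500) // 1_000):
            if k not in blocked:
                free_slots.append((chrom, k * 1_000))
    order = rng.permutation(len(free_slots))
    free_iter = iter(order)

    def next_free() -> tuple[str, int]:
        try:
            return free_slots[next(free_iter)]
        except StopIteration:
            raise ValueError("genome too small for requested false peaks")

    primary, confirm = {}, {}
    for label, ps in peak_sets.items():
        conf_peaks, prim_peaks = [], list(ps.peaks)
        for p in ps:
            shift = int(rng.integers(-coord_jitter, coord_jitter + 1))
            width = p.end - p.start
            start = max(0, p.start + shift)
            end = start + width
            summit = min(max(p.summit + shift, start), end - 1)
            conf_peaks.append(Peak(
                interval=GenomicInterval(p.chrom, start, end),
                summit=summit, score=p.score, name=p.name + "_B",
                source=label + "_B",
            ))
        n_false = int(round(false_peak_rate * len(ps)))
        for caller_peaks, tag in ((prim_peaks, "_falseA"),
                                  (conf_peaks, "_falseB")):
            for j in range(n_false):
                chrom, pos = next_free()
                width = int(rng.integers(200, 401))
                start = pos
                end = pos + width
                caller_peaks.append(Peak(
                    interval=GenomicInterval(chrom, start, end),
                    summit=start + width // 2,
                    score=float(rng.uniform(10, 100)),
                    name=f"{label}{tag}_{j}", source=label,
                ))
        primary[label] = PeakSet(label=label, peaks=prim_peaks)
        confirm[label] = PeakSet(label=label + "_B", peaks=conf_peaks)
    return primary, confirm


def plant_motifs(genome: Genome, truth: TruthTable, core_motif: str,
                 flank_spec: FlankPrefSpec, spec: ArchitectureSpec,
                 seed: int | None = None) -> Genome:
    """Write one core motif (plus preference-drawn flanks) into each region
    selected by its class's motif probability; positions recorded in truth.

    Motifs are planted on the + strand, centred on the region anchor.
    """
    rng = np.random.default_rng(seed)
    span = flank_spec.span
    m = len(core_motif)
    seqs = {c: bytearray(genome[c].encode()) for c in genome.chroms}
    core_b = core_motif.upper().encode()

    for region in truth.regions:
        p = spec.motif_probability(region.cls)
        if rng.random() >= p:
            continue
        start = region.anchor - m // 2
        lo = start - span
        hi = start + m + span
        if lo < 0 or hi > len(seqs[region.chrom]):
            raise ValueError(
                f"motif plant for {region.region_id} collides with a "
                f"chromosome edge"
            )
        buf = seqs[region.chrom]
        buf[start:start + m] = core_b
        for off in sorted(flank_spec.probs):
            vec = flank_spec.probs[off]
            base = BASES[int(rng.choice(4, p=vec))]
            pos = start + off if off < 0 else start + m + off - 1
            buf[pos:pos + 1] = base.encode()
        region.motif_planted = True
        region.motif_start = start
    return Genome({c: bytes(b).decode() for c, b in seqs.items()})


def simulate_tags(genome: Genome, peaks: PeakSet, n_signal: int,
                  n_background: int, placement_sd: float = 50.0,
                  fragment_len: int = 200, weights: Sequence[float] | None = None,
                  seed: int | None = None) -> TagTrack:
    """Tag track with signal fragments piled over peak summits.

    Signal fragments are centred at summit + N(0, placement_sd); strands are
    assigned so fragments point toward the summit (+ anchors 5' of it,
    - anchors 3'). Background anchors are uniform over the genome with random
    strand. Optional per-peak weights skew signal allocation (e.g. occupancy
    proportional to the number of co-binding factors). Anchors falling off a
    chromosome are dropped; the count is returned as the n_dropped attribute.
    """
    if n_signal < 0 or n_background < 0:
        raise ValueError("tag counts must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    chroms = list(lengths)
    tags: list[tuple[str, int, str]] = []
    dropped = 0

    summits = [(p.chrom, p.summit) for p in peaks]
    if n_signal and not summits:
        raise ValueError("signal tags requested but peak set is empty")
    if n_signal:
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if w.shape != (len(summits),) or (w < 0).any() or w.sum() == 0:
                raise ValueError("weights must be nonnegative, one per peak")
            pick = rng.choice(len(summits), size=n_signal, p=w / w.sum())
        else:
            pick = rng.integers(0, len(summits), size=n_signal)
        offsets = rng.normal(0.0, placement_sd, size=n_signal)
        strands = rng.integers(0, 2, size=n_signal)
        for idx, off, s in zip(pick, offsets, strands):
            chrom, summit = summits[idx]
            center = summit + int(round(off))
            if s == 0:
                anchor, strand = center - fragment_len // 2, "+"
            else:
                anchor, strand = center + fragment_len // 2 - 1, "-"
            if 0 <= anchor < lengths[chrom]:
                tags.append((chrom, int(anchor), strand))
            else:
                dropped += 1
    if n_background:
        total = sum(lengths.values())
        weights = np.array([lengths[c] / total for c in chroms])
        pick = rng.choice(len(chroms), size=n_background, p=weights)
        strands = rng.integers(0, 2, size=n_background)
        for ci, s in zip(pick, strands):
            chrom = chroms[ci]
            anchor = int(rng.integers(0, lengths[chrom]))
            tags.append((chrom, anchor, "+" if s == 0 else "-"))
    track = TagTrack(label=peaks.label, tags=tags)
    track.n_dropped = dropped  # type: ignore[attr-defined]
    return track


@dataclass
class AssociationSpec:
    """Per-class regulation probabilities: class label -> (P(up), P(down))."""

    class_probs: dict[frozenset[str], tuple[float, float]]
    unbound_probs: tuple[float, float] = (0.0, 0.0)
    n_filler_genes: int = 50
    tss_offset_max: int = 1500

    def __post_init__(self) -> None:
        for cls, (pu, pd) in self.class_probs.items():
            if pu < 0 or pd < 0 or pu + pd > 1:
                raise ValueError(
                    f"bad probabilities for class {sorted(cls)}: {(pu, pd)}"
                )
        pu, pd = self.unbound_probs
        if pu < 0 or pd < 0 or pu + pd > 1:
            raise ValueError("bad unbound probabilities")


def simulate_genes_and_expression(genome: Genome, truth: TruthTable,
                                  assoc: AssociationSpec,
                                  config: RunConfig | None = None,
                                  seed: int | None = None
                                  ) -> tuple[list[GeneModel],
                                             list[ExpressionRecord]]:
    """One gene per planted region (TSS placed so the region anchor sits in
    the assignment window) plus unbound filler genes; expression direction is
    drawn per class and recorded in the truth table."""
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    genes: list[GeneModel] = []
    records: list[ExpressionRecord] = []
    lo_w, hi_w = config.tss_window  # (-5000, +2000)

    def draw_direction(probs: tuple[float, float]) -> str:
        u = rng.random()
        if u < probs[0]:
            return "up"
        if u < probs[0] + probs[1]:
            return "down"
        return "unchanged"

    def expression_row(gene_id: str, direction: str) -> ExpressionRecord:
        if direction == "up":
            fc = float(rng.uniform(config.fc_threshold + 0.1,
                                   config.fc_threshold + 3.5))
            fdr = float(rng.uniform(1e-4, config.fdr_threshold * 0.9))
        elif direction == "down":
            fc = -float(rng.uniform(config.fc_threshold + 0.1,
                                    config.fc_threshold + 3.5))
            fdr = float(rng.uniform(1e-4, config.fdr_threshold * 0.9))
        else:
            fc = float(rng.choice([-1, 1]) * rng.uniform(1.0, 1.4))
            fdr = float(rng.uniform(config.fdr_threshold + 1e-6, 1.0))
        return ExpressionRecord(gene_id, fc, fdr)

    for region in truth.regions:
        gene_id = f"gene_{region.region_id}"
        strand = "+" if rng.random() < 0.5 else "-"
        off = int(rng.integers(-assoc.tss_offset_max,
                               assoc.tss_offset_max + 1))
        # TSS such that the anchor lies inside the strand-aware window
        tss = region.anchor + off
        tss = min(max(tss, 0), lengths[region.chrom] - 1)
        # sanity: anchor within [tss + lo_w, tss + hi_w] strand-aware
        if strand == "+":
            if not (tss + lo_w <= region.anchor <= tss + hi_w):
                raise ValueError("TSS placement violates the assignment window")
        else:
            if not (tss - hi_w <= region.anchor <= tss - lo_w):
                raise ValueError("TSS placement violates the assignment window")
        genes.append(GeneModel(gene_id=gene_id, chrom=region.chrom, tss=tss,
                               strand=strand))
        probs = assoc.class_probs.get(region.cls, (0.0, 0.0))
        direction = draw_direction(probs)
        records.append(expression_row(gene_id, direction))
        truth.genes[gene_id] = ("+".join(sorted(region.cls)), direction)

    # filler genes far enough from every region anchor that no planted summit
    # can fall in their assignment window (and no region's gene is displaced)
    import bisect
    anchors_by_chrom: dict[str, list[int]] = {}
    for r in truth.regions:
        anchors_by_chrom.setdefault(r.chrom, []).append(r.anchor)
    for v in anchors_by_chrom.values():
        v.sort()
    # a filler gene is "unbound" iff no planted summit falls in its window;
    # the widest window arm is max(|lo_w|, |hi_w|), plus jitter headroom
    min_clearance = max(abs(lo_w), abs(hi_w)) + 100

    def clear_of_regions(chrom: str, pos: int) -> bool:
        anchors = anchors_by_chrom.get(chrom, [])
        i = bisect.bisect_left(anchors, pos)
        for j in (i - 1, i):
            if 0 <= j < len(anchors) and abs(anchors[j] - pos) < min_clearance:
                return False
        return True

    free = []
    for chrom, length in lengths.items():
        pos = 5_000
        while pos < length - 5_000:
            if clear_of_regions(chrom, pos):
                free.append((chrom, pos))
            pos += 10_000
    if assoc.n_filler_genes > len(free):
        raise ValueError("genome too small for requested filler genes")
    order = rng.permutation(len(free))
    for j in range(assoc.n_filler_genes):
        chrom, pos = free[order[j]]
        gene_id = f"gene_filler_{j:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=gene_id, chrom=chrom, tss=pos,
                               strand=strand))
        direction = draw_direction(assoc.unbound_probs)
        records.append(expression_row(gene_id, direction))
        truth.genes[gene_id] = ("unbound", direction)
    return genes, records
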