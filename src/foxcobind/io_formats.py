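"""Readers, writers and domain types shared by every analysis stage.

All coordinates are 0-based, half-open (BED semantics). One-based tabular
inputs must be converted at the boundary by the caller; nothing downstream
ever sees 1-based positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called binding region with its summit (base of maximal signal)."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError("score must be nonnegative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PeakSet:
    """Sorted, de-duplicated peaks for one factor (and optionally one caller)."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        key = lambda p: (p.chrom, p.start, p.end, p.summit)
        self.peaks = sorted(self.peaks, key=key)
        seen: set[tuple] = set()
        deduped = []
        for p in self.peaks:
            k = key(p)
            if k in seen:
                continue
            seen.add(k)
            deduped.append(p)
        self.peaks = deduped

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


class Genome:
    """In-memory genome: chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            self._seqs[name] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); raises if out of bounds."""
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"bounds [0, {len(seq)})"
            )
        return seq[start:end]

    def items(self):
        return self._seqs.items()


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be nonnegative")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon block [{s}, {e})")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fold_change: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")


@dataclass
class TagTrack:
    """Read 5' anchors: (chrom, position, strand)."""

    label: str
    tags: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tags)


@dataclass
class RunConfig:
    """All analysis constants in one place (defaults follow the study design)."""

    fragment_len: int = 200          # bp, assumed ChIP fragment size
    tss_window: tuple[int, int] = (-5000, 2000)  # summit-to-TSS assignment
    summit_motif_window_half: int = 200   # ±200 bp motif-fraction windows
    summit_scan_window_total: int = 200   # window spanning summit for flanks
    flank_span: int = 5              # bases examined each side of the core
    n_sim: int = 1000                # Monte-Carlo resampling repetitions
    sd_threshold: float = 13.0       # z cut for flanking-base significance
    fc_threshold: float = 1.5        # linear fold-change cut (strict)
    fdr_threshold: float = 0.05      # FDR cut (strict)
    summit_dist_cutoff: int = 160    # bp, summit co-localization cut
    profile_bin: int = 10            # bp, tag-density bin width
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fragment_len", "summit_motif_window_half",
                     "summit_scan_window_total", "flank_span", "profile_bin",
                     "summit_dist_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.fc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        self.tss_window = tuple(self.tss_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tss_window"] = list(self.tss_window)
        return d


# ---------------------------------------------------------------------------
# peak files
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, dialect: str = "narrowPeak",
               label: str | None = None) -> PeakSet:
    """Read a BED or ENCODE narrowPeak file into a sorted PeakSet.

    narrowPeak: summit = start + column-10 offset; an offset of -1 falls back
    to the interval midpoint. BED (3-6 columns): summit = floor((start+end)/2).
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    label = label if label is not None else path.stem
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                peaks.append(_parse_peak_line(fields, dialect, label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label=label, peaks=peaks)


def _parse_peak_line(fields: Sequence[str], dialect: str, label: str) -> Peak:
    if len(fields) < 3:
        raise ValueError(f"expected >= 3 columns, got {len(fields)}")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else ""
    score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
    if dialect == "narrowPeak":
        if len(fields) < 10:
            raise ValueError(f"narrowPeak needs 10 columns, got {len(fields)}")
        offset = int(fields[9])
        if offset == -1:
            summit = (start + end) // 2
        else:
            summit = start + offset
            if not (start <= summit < end):
                raise ValueError(
                    f"summit offset {offset} places summit outside "
                    f"[{start}, {end})"
                )
    else:
        summit = (start + end) // 2
    interval = GenomicInterval(chrom, start, end)
    return Peak(interval=interval, summit=summit, score=score, name=name,
                source=label)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write as 10-column narrowPeak (summit as offset in column 10)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            name = p.name or f"{peakset.label}_{i}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t.\t"
                f"0\t-1\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """TSV with header: gene_id, chrom, tss, strand[, exons].

    exons is an optional comma-separated list of start-end blocks.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        exons: tuple[tuple[int, int], ...] = ()
        if "exons" in df.columns:
            raw = getattr(row, "exons")
            if isinstance(raw, str) and raw.strip():
                exons = tuple(
                    tuple(int(x) for x in block.split("-"))  # type: ignore
                    for block in raw.split(",")
                )
        genes.append(GeneModel(gene_id=str(row.gene_id), chrom=str(row.chrom),
                               tss=int(row.tss), strand=str(row.strand),
                               exons=exons))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\texons\n")
        for g in genes:
            blocks = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{blocks}\n")


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """TSV with header: gene_id, fold_change, fdr."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "fold_change", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return [ExpressionRecord(str(r.gene_id), float(r.fold_change), float(r.fdr))
            for r in df.itertuples(index=False)]


def write_expression_table(records: Iterable[ExpressionRecord],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfold_change\tfdr\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fold_change:.6g}\t{r.fdr:.6g}\n")


def log2_to_signed_fold_change(log2_fc: float) -> float:
    """Convert a log2 fold change to the signed linear convention
    (magnitude >= 1; sign encodes direction)."""
    if log2_fc >= 0:
        return 2.0 ** log2_fc
    return -(2.0 ** (-log2_fc))


def classify_regulation(records: Iterable[ExpressionRecord],
                        config: RunConfig | None = None,
                        log2_input: bool = False) -> dict[str, str]:
    """Label each gene up / down / unchanged.

    A gene is "up" iff fold_change > fc_threshold and fdr < fdr_threshold,
    "down" iff fold_change < -fc_threshold and fdr < fdr_threshold; both
    inequalities are strict, so boundary values are "unchanged".
    """
    config = config or RunConfig()
    out: dict[str, str] = {}
    for rec in records:
        fc = rec.fold_change
        if log2_input:
            fc = log2_to_signed_fold_change(fc)
        if rec.fdr < config.fdr_threshold and fc > config.fc_threshold:
            out[rec.gene_id] = "up"
        elif rec.fdr < config.fdr_threshold and fc < -config.fc_threshold:
            out[rec.gene_id] = "down"
        else:
            out[rec.gene_id] = "unchanged"
    return out


# ---------------------------------------------------------------------------
# tag tracks (BED6 of read 5' anchors)
# ---------------------------------------------------------------------------

def read_tags(path: str | Path, label: str | None = None) -> TagTrack:
    path = Path(path)
    label = label if label is not None else path.stem
    tags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: tag BED needs 6 columns")
            chrom, pos, strand = fields[0], int(fields[1]), fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            tags.append((chrom, pos, strand))
    return TagTrack(label=label, tags=tags)


def write_tags(track: TagTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(track.tags):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttag_{i}\t0\t{strand}\n")
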