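"""Summit-to-gene assignment, genomic-location classes and the
binding-category x regulation association tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneModel, Genome, Peak, TagTrack
from .peak_ops import CategoryPartition
from .tag_profile import average_profile, density_matrix


def assign_peak_to_gene(peak: Peak | tuple[str, int],
                        gene_models: Sequence[GeneModel],
                        window: tuple[int, int] = (-5000, 2000)) -> str | None:
    """Gene whose strand-aware TSS window contains the summit, or None.

    For a + gene with TSS t the genomic window is [t + window[0],
    t + window[1]]; for a - gene it is mirrored to [t - window[1],
    t - window[0]]. Boundaries are inclusive. Among qualifying genes the
    nearest |summit - TSS| wins; exact ties go to the lexicographically
    smallest gene_id.
    """
    if isinstance(peak, Peak):
        chrom, summit = peak.chrom, peak.summit
    else:
        chrom, summit = peak
    lo_w, hi_w = window
    best: tuple[int, str] | None = None
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            lo, hi = g.tss + lo_w, g.tss + hi_w
        else:
            lo, hi = g.tss - hi_w, g.tss - lo_w
        if lo <= summit <= hi:
            key = (abs(summit - g.tss), g.gene_id)
            if best is None or key < best:
                best = key
    return best[1] if best else None


def genomic_location_classify(peak: Peak | tuple[str, int],
                              gene_models: Sequence[GeneModel],
                              promoter_window: tuple[int, int] = (-1000, 100)
                              ) -> str:
    """Summit location class with precedence promoter > exon > intron >
    intergenic. Promoter = strand-aware TSS window; gene body (for
    exon/intron calls) = span of the exon blocks when present."""
    if isinstance(peak, Peak):
        chrom, summit = peak.chrom, peak.summit
    else:
        chrom, summit = peak
    lo_w, hi_w = promoter_window
    in_exon = in_intron = False
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            lo, hi = g.tss + lo_w, g.tss + hi_w
        else:
            lo, hi = g.tss - hi_w, g.tss - lo_w
        if lo <= summit <= hi:
            return "promoter"
        if g.exons:
            body_lo = min(s for s, _ in g.exons)
            body_hi = max(e for _, e in g.exons)
            if body_lo <= summit < body_hi:
                if any(s <= summit < e for s, e in g.exons):
                    in_exon = True
                else:
                    in_intron = True
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    return "intergenic"


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact test for a difference in two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be > 0")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class RegulationTable:
    """Per binding category: counts / percentages of up, down and unchanged
    associated genes."""

    rows: list[dict] = field(default_factory=list)
    multi_category_genes: int = 0  # genes counted in more than one category

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def category_regulation_table(partition: CategoryPartition,
                              gene_models: Sequence[GeneModel],
                              regulation: Mapping[str, str],
                              window: tuple[int, int] = (-5000, 2000),
                              dedupe_within_category: bool = True
                              ) -> RegulationTable:
    """Associate each merged region's representative summits with genes and
    tabulate regulation per binding category.

    A gene inherits the category of every region assigned to it; a gene hit
    by regions of multiple categories is counted once per category (the
    multiplicity is reported). Percentages are over each category's
    associated genes.
    """
    for label in regulation.values():
        if label not in ("up", "down", "unchanged"):
            raise ValueError(f"bad regulation label {label!r}")

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    per_category: dict[frozenset[str], set[str]] = {}
    gene_categories: dict[str, set[frozenset[str]]] = {}
    for region in partition.regions:
        # one representative summit per member factor; any hit associates
        assigned: set[str] = set()
        for f in region.factors:
            summit = region.summit(f)
            gid = assign_peak_to_gene(
                (region.interval.chrom, summit),
                genes_by_chrom.get(region.interval.chrom, ()), window)
            if gid is not None:
                assigned.add(gid)
        for gid in assigned:
            per_category.setdefault(region.factors, set()).add(gid)
            gene_categories.setdefault(gid, set()).add(region.factors)

    multi = sum(1 for cats in gene_categories.values() if len(cats) > 1)
    rows = []
    for cat in sorted(per_category, key=lambda c: (len(c), sorted(c))):
        gene_ids = sorted(per_category[cat])
        counts = {"up": 0, "down": 0, "unchanged": 0}
        for gid in gene_ids:
            counts[regulation.get(gid, "unchanged")] += 1
        n = len(gene_ids)
        row = {"category": "+".join(sorted(cat)), "n_genes": n}
        for k in ("up", "down", "unchanged"):
            row[f"n_{k}"] = counts[k]
            row[f"pct_{k}"] = 100.0 * counts[k] / n if n else float("nan")
        rows.append(row)
    return RegulationTable(rows=rows, multi_category_genes=multi)


def tss_group_profile(track: TagTrack, gene_models: Sequence[GeneModel],
                      regulation: Mapping[str, str],
                      half_width: int = 1000, bin_size: int = 10,
                      fragment_len: int = 200,
                      chrom_lengths: dict[str, int] | None = None,
                      seed: int | None = None) -> dict[str, np.ndarray]:
    """Average tag-density profiles around the TSSs of up-, down-regulated
    and randomly selected non-inducible control genes.

    The control group is sampled (seeded) from genes labelled unchanged, with
    size equal to the mean of the up/down group sizes.
    """
    from .tag_profile import extend_tags

    rng = np.random.default_rng(seed)
    groups: dict[str, list[GeneModel]] = {"up": [], "down": [], "unchanged": []}
    for g in gene_models:
        label = regulation.get(g.gene_id)
        if label in groups:
            groups[label].append(g)
    if not groups["up"] or not groups["down"]:
        raise ValueError("empty up or down gene group")
    n_control = int(round((len(groups["up"]) + len(groups["down"])) / 2))
    pool = groups["unchanged"]
    if not pool:
        raise ValueError("no unchanged genes available for the control group")
    n_control = min(n_control, len(pool))
    pick = rng.choice(len(pool), size=n_control, replace=False)
    control = [pool[i] for i in sorted(pick)]

    fragments = extend_tags(track, fragment_len, chrom_lengths)
    out = {}
    for name, members in (("up", groups["up"]), ("down", groups["down"]),
                          ("random_control", control)):
        anchors = [(g.gene_id, g.chrom, g.tss, g.strand) for g in members]
        dm = density_matrix(fragments, anchors, half_width, bin_size,
                            chrom_lengths=chrom_lengths)
        out[name] = average_profile(dm)
    return out


def co_association_summary(acetylation_peaks: Sequence[Peak],
                           fox_partition: CategoryPartition, genome: Genome,
                           core_motif: str = "GTAAACA"
                           ) -> dict[str, float]:
    """Histone-acetylation regions vs FOX binding: how many acetylated
    regions carry >= 1 FOX peak, and the core-motif frequency in the
    FOX-bound vs FOX-free acetylated regions (whole-region scan)."""
    from .motif_analysis import scan_motif
    import bisect
    import itertools

    fox_ivs: dict[str, list[tuple[int, int]]] = {}
    for r in fox_partition.regions:
        fox_ivs.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end))
    index = {}
    for chrom, ivs in fox_ivs.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        max_ends = list(itertools.accumulate((e for _, e in ivs), max))
        index[chrom] = (starts, max_ends)

    def touches_fox(p: Peak) -> bool:
        if p.chrom not in index:
            return False
        starts, max_ends = index[p.chrom]
        i = bisect.bisect_left(starts, p.end)
        return i > 0 and max_ends[i - 1] > p.start

    def has_motif(p: Peak) -> bool:
        seq = genome.fetch(p.chrom, p.start, p.end)
        return bool(scan_motif(seq, core_motif, strands="both"))

    n_total = len(acetylation_peaks)
    n_with_fox = k_overlap = k_only = n_only = 0
    for p in acetylation_peaks:
        bound = touches_fox(p)
        motif = has_motif(p)
        if bound:
            n_with_fox += 1
            k_overlap += motif
        else:
            n_only += 1
            k_only += motif
    return {
        "n_acetyl": n_total,
        "n_acetyl_with_fox": n_with_fox,
        "fraction_motif_in_overlap": (k_overlap / n_with_fox
                                      if n_with_fox else 0.0),
        "fraction_motif_in_acetyl_only": (k_only / n_only if n_only else 0.0),
    }
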