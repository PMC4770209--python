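"""Summit-to-gene assignment, location classes, Fisher test, regulation
association."""

import math

import numpy as np
import pytest

from foxcobind.annotate_assoc import (assign_peak_to_gene,
                                      category_regulation_table,
                                      co_association_summary,
                                      genomic_location_classify,
                                      proportion_test, tss_group_profile)
from foxcobind.io_formats import (GeneModel, Genome, GenomicInterval, Peak,
                                  PeakSet)
from foxcobind.peak_ops import partition
from foxcobind.synthetic_data import simulate_genome, simulate_tags


def gene(gid, tss, strand="+", chrom="c1", exons=()):
    return GeneModel(gene_id=gid, chrom=chrom, tss=tss, strand=strand,
                     exons=exons)


class TestAssignPeakToGene:
    def test_plus_strand_boundaries_inclusive(self):
        g = [gene("g1", 10_000)]
        assert assign_peak_to_gene(("c1", 12_000), g) == "g1"  # +2k edge
        assert assign_peak_to_gene(("c1", 5_000), g) == "g1"   # -5k edge
        assert assign_peak_to_gene(("c1", 12_001), g) is None
        assert assign_peak_to_gene(("c1", 4_999), g) is None

    def test_minus_strand_window_mirrored(self):
        g = [gene("g1", 10_000, strand="-")]
        assert assign_peak_to_gene(("c1", 8_000), g) == "g1"   # -2k genomic
        assert assign_peak_to_gene(("c1", 15_000), g) == "g1"  # +5k genomic
        assert assign_peak_to_gene(("c1", 7_999), g) is None
        assert assign_peak_to_gene(("c1", 15_001), g) is None

    def test_nearest_tss_wins_then_lexicographic(self):
        genes = [gene("b", 10_000), gene("a", 10_500)]
        assert assign_peak_to_gene(("c1", 10_400), genes) == "a"
        # exact tie at midpoint 10_250
        assert assign_peak_to_gene(("c1", 10_250), genes) == "a"

    def test_matches_exhaustive_oracle(self, rng):
        genes = [gene(f"g{i:03d}", int(rng.integers(0, 200_000)),
                      strand="+" if rng.random() < 0.5 else "-")
                 for i in range(100)]
        for _ in range(1_000):
            summit = int(rng.integers(0, 200_000))
            got = assign_peak_to_gene(("c1", summit), genes)
            candidates = []
            for g in genes:
                lo = g.tss - 5000 if g.strand == "+" else g.tss - 2000
                hi = g.tss + 2000 if g.strand == "+" else g.tss + 5000
                if lo <= summit <= hi:
                    candidates.append((abs(summit - g.tss), g.gene_id))
            expected = min(candidates)[1] if candidates else None
            assert got == expected


class TestLocationClassify:
    GENES = [
        gene("g1", 10_000, exons=((10_000, 10_500), (11_000, 12_000))),
    ]

    def test_promoter_upstream_of_plus_tss(self):
        assert genomic_location_classify(("c1", 9_800), self.GENES) == \
            "promoter"

    def test_exon(self):
        assert genomic_location_classify(("c1", 11_500), self.GENES) == "exon"

    def test_intron(self):
        assert genomic_location_classify(("c1", 10_700), self.GENES) == \
            "intron"

    def test_intergenic(self):
        assert genomic_location_classify(("c1", 50_000), self.GENES) == \
            "intergenic"

    def test_promoter_precedence_over_exon(self):
        # summit in both the promoter window (TSS+100) and the first exon
        assert genomic_location_classify(("c1", 10_050), self.GENES) == \
            "promoter"

    def test_every_summit_receives_exactly_one_label(self, rng):
        for _ in range(500):
            label = genomic_location_classify(
                ("c1", int(rng.integers(0, 60_000))), self.GENES)
            assert label in ("promoter", "exon", "intron", "intergenic")


def fisher_oracle(k1, n1, k2, n2):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    K = k1 + k2
    N = n1 + n2
    def prob(x):
        return (math.comb(n1, x) * math.comb(n2, K - x)) / math.comb(N, K)
    p_obs = prob(k1)
    total = 0.0
    for x in range(max(0, K - n2), min(K, n1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestProportionTest:
    def test_identical_proportions_give_p_one(self):
        assert proportion_test(50, 100, 50, 100) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        got = proportion_test(10, 10, 0, 10)
        assert got == pytest.approx(fisher_oracle(10, 10, 0, 10), rel=1e-9)
        assert got == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            assert proportion_test(k1, n1, k2, n2) == pytest.approx(
                fisher_oracle(k1, n1, k2, n2), rel=1e-9, abs=1e-12)

    def test_symmetric_in_group_order(self, rng):
        assert proportion_test(3, 10, 8, 12) == pytest.approx(
            proportion_test(8, 12, 3, 10))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0, 1, 10)


def make_region(chrom, center, label, width=300):
    return Peak(GenomicInterval(chrom, center - width // 2,
                                center + width // 2),
                summit=center, score=10, name=f"{label}_{center}")


class TestCategoryRegulationTable:
    def test_counts_and_percentages(self):
        # 10 regions of one category, each with its own gene: 6 up, 4 down
        peaks = [make_region("c1", 10_000 + i * 20_000, "K2")
                 for i in range(10)]
        part = partition([PeakSet("K2", peaks)])
        genes = [gene(f"g{i}", 10_000 + i * 20_000 + 500) for i in range(10)]
        regulation = {f"g{i}": ("up" if i < 6 else "down") for i in range(10)}
        table = category_regulation_table(part, genes, regulation)
        row = table.rows[0]
        assert row["category"] == "K2" and row["n_genes"] == 10
        assert (row["pct_up"], row["pct_down"], row["pct_unchanged"]) == \
            (60.0, 40.0, 0.0)

    def test_no_associated_genes_gives_empty_table(self):
        peaks = [make_region("c1", 10_000, "K2")]
        part = partition([PeakSet("K2", peaks)])
        table = category_regulation_table(part, [gene("g1", 500_000)], {})
        assert table.rows == []

    def test_percentages_invariant_to_order(self, rng):
        peaks = [make_region("c1", 10_000 + i * 20_000, "K2")
                 for i in range(8)]
        genes = [gene(f"g{i}", 10_000 + i * 20_000 + 100) for i in range(8)]
        regulation = {f"g{i}": ["up", "down", "unchanged"][i % 3]
                      for i in range(8)}
        a = category_regulation_table(
            partition([PeakSet("K2", peaks)]), genes, regulation)
        b = category_regulation_table(
            partition([PeakSet("K2", peaks[::-1])]), genes[::-1], regulation)
        assert a.rows == b.rows

    def test_bad_regulation_label_rejected(self):
        peaks = [make_region("c1", 10_000, "K2")]
        part = partition([PeakSet("K2", peaks)])
        with pytest.raises(ValueError):
            category_regulation_table(part, [], {"g": "sideways"})


class TestTssGroupProfile:
    def _setup(self, seed=3):
        genome = simulate_genome(1, 400_000, seed=seed)
        up = [gene(f"up{i}", 50_000 + i * 30_000, chrom="chr1")
              for i in range(4)]
        down = [gene(f"dn{i}", 60_000 + i * 30_000, chrom="chr1")
                for i in range(4)]
        unchanged = [gene(f"un{i}", 70_000 + i * 30_000, chrom="chr1")
                     for i in range(6)]
        regulation = {g.gene_id: "up" for g in up}
        regulation |= {g.gene_id: "down" for g in down}
        regulation |= {g.gene_id: "unchanged" for g in unchanged}
        return genome, up + down + unchanged, regulation

    def test_signal_planted_at_up_tss_raises_up_profile(self):
        genome, genes, regulation = self._setup()
        up_peaks = [Peak(GenomicInterval("chr1", g.tss - 200, g.tss + 200),
                         summit=g.tss)
                    for g in genes if regulation[g.gene_id] == "up"]
        track = simulate_tags(genome, PeakSet("t", up_peaks), n_signal=5_000,
                              n_background=1_000, seed=4)
        profiles = tss_group_profile(track, genes, regulation, seed=11,
                                     chrom_lengths=genome.lengths)
        mid = len(profiles["up"]) // 2
        assert profiles["up"][mid] > 3 * profiles["random_control"][mid]

    def test_control_sampling_is_seeded(self):
        genome, genes, regulation = self._setup()
        track = simulate_tags(genome, PeakSet("t", []), 0, 2_000, seed=5)
        a = tss_group_profile(track, genes, regulation, seed=42,
                              chrom_lengths=genome.lengths)
        b = tss_group_profile(track, genes, regulation, seed=42,
                              chrom_lengths=genome.lengths)
        assert np.array_equal(a["random_control"], b["random_control"])

    def test_empty_group_errors(self):
        genome, genes, regulation = self._setup()
        regulation = {k: ("down" if v == "up" else v)
                      for k, v in regulation.items()}
        track = simulate_tags(genome, PeakSet("t", []), 0, 1_000, seed=6)
        with pytest.raises(ValueError, match="empty"):
            tss_group_profile(track, genes, regulation,
                              chrom_lengths=genome.lengths)


class TestCoAssociation:
    def test_no_acetylation_peaks(self, uniform_genome_100kb):
        part = partition([PeakSet("K2", [make_region("chr1", 5_000, "K2")])])
        out = co_association_summary([], part, uniform_genome_100kb)
        assert out["n_acetyl"] == 0 and out["n_acetyl_with_fox"] == 0

    def test_identical_peak_sets_fully_co_associated(self, uniform_genome_100kb):
        peaks = [make_region("chr1", 5_000 + i * 10_000, "K2")
                 for i in range(9)]
        part = partition([PeakSet("K2", peaks)])
        out = co_association_summary(peaks, part, uniform_genome_100kb)
        assert out["n_acetyl_with_fox"] == out["n_acetyl"] == 9

    def test_motif_fraction_in_overlap_class(self):
        genome = simulate_genome(1, 300_000, seed=9)
        seq = bytearray(genome["chr1"].encode())
        fox_peaks, acetyl = [], []
        for i in range(20):
            center = 5_000 + i * 10_000
            if i < 10:  # acetyl regions overlapping FOX, half with motif
                fox_peaks.append(make_region("chr1", center, "K2"))
                if i % 2 == 0:
                    seq[center:center + 7] = b"GTAAACA"
                else:
                    # scrub chance hits from the acetyl window
                    w = bytes(seq[center - 150:center + 150])
                    for pat in (b"GTAAACA", b"TGTTTAC"):
                        j = w.find(pat)
                        while j >= 0:
                            seq[center - 150 + j:center - 150 + j + 7] = b"C" * 7
                            w = bytes(seq[center - 150:center + 150])
                            j = w.find(pat)
            acetyl.append(make_region("chr1", center, "ac"))
        genome = Genome({"chr1": bytes(seq).decode()})
        part = partition([PeakSet("K2", fox_peaks)])
        out = co_association_summary(acetyl, part, genome)
        assert out["n_acetyl"] == 20 and out["n_acetyl_with_fox"] == 10
        assert out["fraction_motif_in_overlap"] == pytest.approx(0.5)

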