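"""Motif scanning and enrichment statistics against independent oracles."""

import math

import numpy as np
import pytest

from foxcobind.io_formats import Genome, GenomicInterval
from foxcobind.motif_analysis import (binomial_enrichment, expand_iupac,
                                      fraction_regions_with_motif,
                                      motif_binding_saturation,
                                      motif_count_per_region,
                                      permuted_motif_survey, revcomp,
                                      scan_motif,
                                      single_substitution_variants, IUPAC)
from foxcobind.synthetic_data import simulate_genome

# EMSA probe sequences from the CYP27C1 locus used as fixed scan fixtures
OLIGO_FWD = "CTAGAACATGTTAATGTAAACAAGGAAGCCTG"
OLIGO_REV = "CTAGCAGGCTTCCTTGTTTACATTAACATGTT"


def naive_scan(seq, pattern, strands="both"):
    """Position-by-position oracle over explicit IUPAC expansions."""
    fwd = expand_iupac(pattern)
    rev = {revcomp(s) for s in fwd}
    m = len(pattern)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i:i + m]
        plus = window in fwd
        minus = strands == "both" and window in rev
        if plus:
            hits.append((i, "+"))
        elif minus:
            hits.append((i, "-"))
    return hits


class TestExpandIupac:
    def test_broad_motif_s_degeneracy(self):
        assert expand_iupac("ATGTAAACAAS") == {"ATGTAAACAAC", "ATGTAAACAAG"}

    def test_no_degeneracy(self):
        assert expand_iupac("GTAAACA") == {"GTAAACA"}

    def test_ry(self):
        assert expand_iupac("RY") == {"AC", "AT", "GC", "GT"}

    def test_expansion_size_is_product_of_degeneracies(self):
        pattern = "RYAAAYA"
        size = math.prod(len(IUPAC[c]) for c in pattern)
        assert len(expand_iupac(pattern)) == size == 8

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            expand_iupac("AXT")


class TestScanMotif:
    def test_forward_oligo_has_one_plus_strand_core_hit(self):
        hits = scan_motif(OLIGO_FWD, "GTAAACA")
        assert len(hits) == 1 and hits[0].strand == "+"
        assert hits[0].matched == "GTAAACA"

    def test_reverse_oligo_has_one_minus_strand_core_hit(self):
        hits = scan_motif(OLIGO_REV, "GTAAACA")
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].matched == "GTAAACA"
        # the genome slice itself is the reverse complement
        assert OLIGO_REV[hits[0].start:hits[0].end] == revcomp("GTAAACA")

    def test_genome_n_never_matches_but_pattern_n_is_wildcard(self):
        assert scan_motif("GTANACA", "GTAAACA") == []
        assert scan_motif("GTANACA", "GTANACA") == []  # genome N still blocks
        assert len(scan_motif("GTAAACA", "GTANACA", strands="plus")) == 1

    def test_palindrome_reported_once_on_plus(self):
        hits = scan_motif("AACGTT", "AACGTT")
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_same_window_both_strand_match_collapsed(self):
        # ACGT is its own reverse complement
        hits = scan_motif("TACGTA", "ACGT")
        assert [(h.start, h.strand) for h in hits] == [(1, "+")]

    def test_pattern_longer_than_sequence_is_empty(self):
        assert scan_motif("ACG", "GTAAACA") == []

    def test_overlapping_occurrences_all_reported(self):
        hits = scan_motif("AAAA", "AA", strands="plus")
        assert [h.start for h in hits] == [0, 1, 2]

    @pytest.mark.parametrize("pattern", ["GTAAACA", "ATGTAAACAAS", "RYAAAYA"])
    def test_matches_naive_oracle(self, pattern):
        genome = simulate_genome(1, 10_000, seed=3)
        seq = genome["chr1"]
        got = [(h.start, h.strand) for h in scan_motif(seq, pattern)]
        assert got == naive_scan(seq, pattern)

    @pytest.mark.parametrize("pattern", ["GTAAACA", "RYAAAYA"])
    def test_strand_symmetry(self, pattern):
        """Scanning the reverse-complemented sequence yields equally many
        hits, mirrored in coordinates."""
        genome = simulate_genome(1, 20_000, seed=9)
        seq = genome["chr1"]
        fwd_hits = scan_motif(seq, pattern)
        rc_hits = scan_motif(revcomp(seq), pattern)
        assert len(fwd_hits) == len(rc_hits)
        mirrored = sorted(len(seq) - h.end for h in rc_hits)
        assert mirrored == sorted(h.start for h in fwd_hits)


class TestRegionFractions:
    def _planted_genome(self, n_regions, with_motif, seed=5):
        genome = simulate_genome(1, 2_000 * (n_regions + 1), seed=seed)
        seq = bytearray(genome["chr1"].encode())
        summits = []
        for i in range(n_regions):
            pos = 1_000 + i * 2_000
            if with_motif[i]:
                seq[pos:pos + 7] = b"GTAAACA"
            else:  # scrub any chance occurrence near the summit
                window = seq[pos - 210:pos + 211].decode()
                for pat in ("GTAAACA", "TGTTTAC"):
                    idx = window.find(pat)
                    while idx >= 0:
                        seq[pos - 210 + idx:pos - 210 + idx + 7] = b"CCCCCCC"
                        window = seq[pos - 210:pos + 211].decode()
                        idx = window.find(pat)
            summits.append(("chr1", pos))
        return Genome({"chr1": bytes(seq).decode()}), summits

    def test_all_planted_gives_fraction_one(self):
        genome, summits = self._planted_genome(10, [True] * 10)
        k, n, frac = fraction_regions_with_motif(summits, genome, "GTAAACA")
        assert (k, n, frac) == (10, 10, 1.0)

    def test_absent_pattern_gives_zero(self):
        genome, summits = self._planted_genome(10, [False] * 10)
        _, _, frac = fraction_regions_with_motif(summits, genome, "GTAAACA")
        assert frac == 0.0

    def test_planted_mixture_recovered(self):
        flags = [i % 10 < 3 for i in range(300)]  # 30% planted
        genome, summits = self._planted_genome(300, flags, seed=7)
        k, n, frac = fraction_regions_with_motif(summits, genome, "GTAAACA")
        se = math.sqrt(0.3 * 0.7 / 300)
        assert abs(frac - 0.3) <= 3 * se

    def test_monotone_in_window_half(self):
        genome = simulate_genome(1, 50_000, seed=13)
        summits = [("chr1", p) for p in range(1_000, 49_000, 2_000)]
        fracs = [fraction_regions_with_motif(summits, genome, "RYAAAYA", w)[2]
                 for w in (50, 100, 200, 400)]
        assert fracs == sorted(fracs)

    def test_empty_region_list_errors(self, uniform_genome_100kb):
        with pytest.raises(ValueError):
            fraction_regions_with_motif([], uniform_genome_100kb, "GTAAACA")

    def test_count_histogram_single_plants(self):
        genome, summits = self._planted_genome(10, [True] * 10)
        hist = motif_count_per_region(summits, genome, "GTAAACA")
        assert hist == {1: 10}

    def test_count_histogram_no_motifs(self):
        genome, summits = self._planted_genome(5, [False] * 5)
        assert motif_count_per_region(summits, genome, "GTAAACA") == {0: 5}


def binom_tail_oracle(k, n, p0, tail):
    """Direct summation of binomial pmf terms."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    if tail == "greater":
        return sum(pmf[k:])
    if tail == "less":
        return sum(pmf[:k + 1])
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))


class TestBinomialEnrichment:
    def test_all_successes_closed_form(self):
        assert binomial_enrichment(10, 10, 0.5, "greater") == pytest.approx(
            2.0 ** -10)

    def test_no_successes_less_tail(self):
        assert binomial_enrichment(0, 5, 0.5, "less") == pytest.approx(2.0 ** -5)

    @pytest.mark.parametrize("tail", ["greater", "less", "two_sided"])
    def test_matches_direct_summation(self, tail, rng):
        for _ in range(50):
            n = int(rng.integers(1, 31))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            got = binomial_enrichment(k, n, p0, tail)
            assert got == pytest.approx(binom_tail_oracle(k, n, p0, tail),
                                        abs=1e-12)

    def test_degenerate_p0_rejected(self):
        for p0 in (0.0, 1.0):
            with pytest.raises(ValueError):
                binomial_enrichment(1, 2, p0)


class TestPermutedSurvey:
    def test_variant_count_is_twenty_two(self):
        assert len(single_substitution_variants("GTAAACA")) == 22

    def test_core_ranks_first_when_planted(self):
        genome = simulate_genome(1, 200_000, seed=21)
        seq = bytearray(genome["chr1"].encode())
        summits = []
        for i in range(50):
            pos = 2_000 + i * 3_000
            seq[pos:pos + 7] = b"GTAAACA"
            summits.append(("chr1", pos))
        genome = Genome({"chr1": bytes(seq).decode()})
        rng = np.random.default_rng(2)
        background = [("chr1", int(rng.integers(500, 199_500)))
                      for _ in range(500)]
        rows, _ = permuted_motif_survey(summits, background, genome)
        assert rows[0].variant == "GTAAACA"

    def test_null_when_peaks_equal_background(self):
        genome = simulate_genome(1, 300_000, seed=22)
        rng = np.random.default_rng(3)
        pts = [("chr1", int(rng.integers(500, 299_500))) for _ in range(200)]
        rows, _ = permuted_motif_survey(pts, pts, genome)
        for row in rows:
            if not math.isnan(row.p_value):
                # identical sets: observed rate equals reference rate
                assert row.ratio == pytest.approx(1.0)

    def test_planted_mixture_consensus_reports_secondary_base(self):
        genome = simulate_genome(1, 400_000, seed=30)
        seq = bytearray(genome["chr1"].encode())
        summits = []
        for i in range(100):
            pos = 2_000 + i * 3_500
            motif = b"GTAAACA" if i % 10 < 7 else b"GTCAACA"
            seq[pos:pos + 7] = motif
            summits.append(("chr1", pos))
        genome = Genome({"chr1": bytes(seq).decode()})
        rng = np.random.default_rng(4)
        background = [("chr1", int(rng.integers(500, 399_500)))
                      for _ in range(1_000)]
        rows, consensus = permuted_motif_survey(summits, background, genome)
        top4 = {r.variant for r in rows[:4]}
        assert {"GTAAACA", "GTCAACA"} <= top4
        assert consensus.split()[2].startswith("A/") and \
            "c" in consensus.split()[2]


class TestSaturation:
    def test_planted_coverage_fraction(self):
        genome = simulate_genome(1, 100_000, seed=40)
        seq = bytearray(genome["chr1"].encode())
        # scrub chance occurrences, then plant exactly 10
        for pat in (b"GTAAACA", b"TGTTTAC"):
            idx = bytes(seq).find(pat)
            while idx >= 0:
                seq[idx:idx + 7] = b"CCCCCCC"
                idx = bytes(seq).find(pat)
        positions = [3_000 + i * 5_000 for i in range(10)]
        for pos in positions:
            seq[pos:pos + 7] = b"GTAAACA"
        genome = Genome({"chr1": bytes(seq).decode()})
        bound = [GenomicInterval("chr1", p - 50, p + 50)
                 for p in positions[:4]]
        n_total, n_in, frac = motif_binding_saturation(genome, "GTAAACA",
                                                       bound)
        assert (n_total, n_in, frac) == (10, 4, 0.4)

    def test_no_bound_regions(self, uniform_genome_100kb):
        n_total, n_in, frac = motif_binding_saturation(
            uniform_genome_100kb, "GTAAACA", [])
        assert n_in == 0 and frac == 0.0

    def test_counts_equal_scan_oracle(self, uniform_genome_100kb):
        n_total, _, _ = motif_binding_saturation(uniform_genome_100kb,
                                                 "GTAAACA", [])
        assert n_total == len(naive_scan(uniform_genome_100kb["chr1"],
                                         "GTAAACA"))
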