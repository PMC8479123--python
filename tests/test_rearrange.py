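"""Breakpoint calling, derivative construction and coordinate maps."""

import random

import pysam
import pytest

import hijackscan as h
from hijackscan.rearrange import (
    Breakpoint,
    DerivativeChromosome,
    PairRecord,
    Segment,
)


def make_pair(name, c1, s1, rev1, c2, s2, rev2, length=100):
    return PairRecord(name, c1, s1, s1 + length, rev1, c2, s2, s2 + length, rev2)


def sam_pair(header, name, c1, s1, rev1, c2, s2, rev2, length=50, mapq=60):
    out = []
    for idx, (c, s, rev) in enumerate([(c1, s1, rev1), (c2, s2, rev2)]):
        a = pysam.AlignedSegment(header=header)
        a.query_name = name
        a.reference_id = header.get_tid(c)
        a.reference_start = s
        a.cigarstring = f"{length}M"
        a.query_sequence = "A" * length
        a.mapping_quality = mapq
        a.is_paired = True
        a.is_read1 = idx == 0
        a.is_read2 = idx == 1
        a.is_reverse = rev
        out.append(a)
    return out


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"},
         "SQ": [{"SN": "chrT3", "LN": 100_000}, {"SN": "chrT8", "LN": 100_000}]}
    )


class TestFindDiscordant:
    def test_interchromosomal_pair_is_discordant(self, header):
        reads = sam_pair(header, "p", "chrT3", 100, False, "chrT8", 200, True)
        pairs, stats = h.find_discordant(reads, 1000, 10)
        assert len(pairs) == 1 and stats["discordant"] == 1

    def test_fr_pair_within_insert_is_concordant(self, header):
        reads = sam_pair(header, "p", "chrT3", 100, False, "chrT3", 350, True)
        pairs, stats = h.find_discordant(reads, 1000, 10)
        assert pairs == [] and stats["concordant"] == 1

    def test_oversized_insert_is_discordant(self, header):
        reads = sam_pair(header, "p", "chrT3", 100, False, "chrT3", 5000, True)
        pairs, _ = h.find_discordant(reads, 1000, 10)
        assert len(pairs) == 1

    def test_wrong_orientation_is_discordant(self, header):
        reads = sam_pair(header, "p", "chrT3", 100, False, "chrT3", 350, False)
        pairs, _ = h.find_discordant(reads, 1000, 10)
        assert len(pairs) == 1

    def test_low_mapq_dropped(self, header):
        reads = sam_pair(header, "p", "chrT3", 100, False, "chrT8", 200, True, mapq=5)
        pairs, stats = h.find_discordant(reads, 1000, 10)
        assert pairs == [] and stats["low_mapq"] == 2

    def test_unpaired_input_rejected(self, header):
        a = sam_pair(header, "p", "chrT3", 100, False, "chrT8", 200, True)[0]
        a.is_paired = False
        with pytest.raises(ValueError, match="unpaired"):
            h.find_discordant([a], 1000, 10)


class TestClusterCandidates:
    def test_hand_cluster_innermost_edges(self):
        # forward a-mates ending at {4980, 4990, 4995}: innermost = 4995
        pairs = [
            make_pair("a", "chrA", 4880, False, "chrB", 7000, True, length=100),
            make_pair("b", "chrA", 4890, False, "chrB", 7010, True, length=100),
            make_pair("c", "chrA", 4895, False, "chrB", 7030, True, length=100),
        ]
        cands = h.cluster_candidates(pairs, 1000, 2)
        assert len(cands) == 1
        bp = cands[0]
        assert bp.support_pairs == 3
        assert bp.pos_a == 4995
        assert bp.pos_b == 7000  # reverse mates: innermost = min start
        assert bp.side_a == "right-of" and bp.side_b == "left-of"

    def test_min_support_filters_singletons(self):
        pairs = [make_pair("a", "chrA", 100, False, "chrB", 7000, True)]
        assert h.cluster_candidates(pairs, 1000, 2) == []

    def test_distant_clusters_split(self):
        pairs = [
            make_pair("a", "chrA", 1000, False, "chrB", 7000, True),
            make_pair("b", "chrA", 1100, False, "chrB", 7050, True),
            make_pair("c", "chrA", 11_000, False, "chrB", 7000, True),
            make_pair("d", "chrA", 11_100, False, "chrB", 7050, True),
        ]
        cands = h.cluster_candidates(pairs, 1000, 2)
        assert len(cands) == 2
        assert cands[0].pos_a < cands[1].pos_a

    def test_order_invariant_under_shuffling(self):
        rng = random.Random(7)
        pairs = [
            make_pair(f"p{i}", "chrA", 5000 + 10 * i, False, "chrB", 7000 + 7 * i, True)
            for i in range(20)
        ]
        ref = h.cluster_candidates(pairs, 1000, 2)
        for _ in range(5):
            shuffled = pairs[:]
            rng.shuffle(shuffled)
            assert h.cluster_candidates(shuffled, 1000, 2) == ref


class TestRefineJunction:
    def test_no_spanning_reads_leaves_candidate(self, hf80_translocation):
        genome, _, _ = hf80_translocation
        cand = Breakpoint("chr3", 168_917_000, "chr8", 130_487_000, support_pairs=5)
        out = h.refine_junction(cand, [], genome)
        assert out.resolution == "interval" and out.pos_a == 168_917_000

    def test_modal_junction_wins(self, hf80_translocation):
        genome, der, (bp3, bp8) = hf80_translocation
        der_seq = der.sequence(genome)
        junction = der.junctions[0]
        true_reads = [der_seq[junction - off : junction - off + 80] for off in
                      (20, 25, 30, 35, 40, 45, 50)]
        # three reads from a junction shifted 100 bp left (minor allele)
        alt = der_seq[: junction - 100] + der_seq[junction:]
        alt_reads = [alt[junction - 100 - off : junction - 100 - off + 80]
                     for off in (20, 30, 40)]
        cand = Breakpoint("chr3", bp3 - 500, "chr8", bp8 + 500, support_pairs=10)
        out = h.refine_junction(cand, true_reads + alt_reads, genome)
        assert out.resolution == "exact"
        assert out.report_coords() == (bp3, bp8)
        assert out.support_split == 7

    def test_end_to_end_recovery(self, hf80_translocation):
        """capture pairs -> discordant -> cluster -> refine recovers the
        simulated junction at base-pair exactness."""
        genome, der, (bp3, bp8) = hf80_translocation
        cfg = h.SimulationConfig(seed=7, n_reads=200, read_length=75,
                                 junction_span_fraction=0.2)
        cp = h.simulate_capture_pairs(genome, der, cfg)
        pairs, _ = h.find_discordant(cp.alignments, 1000, 10)
        assert sorted(p.name for p in pairs) == sorted(cp.straddling_names)
        cands = h.cluster_candidates(pairs, 1000, 2)
        assert len(cands) == 1
        refined = h.refine_junction(cands[0], [s for _, s in cp.spanning_reads], genome)
        assert refined.resolution == "exact"
        assert refined.support_split >= 3
        assert refined.report_coords() == (bp3, bp8)


class TestBuildDerivative:
    SIZES = {"chrT3": (0, 200), "chrT8": (0, 200)}

    def test_toy_junction_length(self):
        bp = Breakpoint("chrT3", 100, "chrT8", 50)
        der = h.build_derivative(bp, self.SIZES)
        assert len(der) == 100 + 150

    def test_patient_style_segments(self, hf80_translocation):
        genome, expected_der, (bp3, bp8) = hf80_translocation
        sizes = {c.name: (c.start, c.end) for c in genome}
        bp = Breakpoint("chr3", bp3, "chr8", bp8 - 1)
        der = h.build_derivative(bp, sizes, "der3")
        assert der.segments == expected_der.segments

    def test_inversion_style_length_conserved(self):
        bp = Breakpoint("chrT3", 100, "chrT3", 150, side_b="left-of")
        der = h.build_derivative(bp, self.SIZES, orientation_b="-")
        assert len(der) == 100 + 50

    def test_degenerate_segment_rejected(self):
        bp = Breakpoint("chrT3", 0, "chrT8", 50)
        with pytest.raises(ValueError, match="degenerate"):
            h.build_derivative(bp, self.SIZES)

    def test_reciprocal_products_partition_genome(self):
        bp = Breakpoint("chrT3", 100, "chrT8", 50)
        der, rec = h.build_derivative(bp, self.SIZES, reciprocal=True)
        assert len(der) + len(rec) == 400


class TestCoordinateMaps:
    def test_forward_segment_offset(self):
        der = DerivativeChromosome("d", [Segment("c1", 0, 100), Segment("c2", 50, 150)])
        assert der.map_to("c2", 60) == 110

    def test_reverse_segment_reflection(self):
        der = DerivativeChromosome(
            "d", [Segment("c1", 0, 100), Segment("c2", 50, 150, "-")]
        )
        assert der.map_to("c2", 60) == 189

    def test_not_covered_returns_none(self):
        der = DerivativeChromosome("d", [Segment("c1", 0, 100)])
        assert der.map_to("c1", 100) is None
        assert der.map_to("cX", 5) is None
        assert der.map_from(100) is None

    def test_round_trip_identity(self):
        der = DerivativeChromosome(
            "d",
            [Segment("c1", 10, 500), Segment("c2", 100, 400, "-"),
             Segment("c1", 600, 700)],
        )
        rng = random.Random(3)
        for _ in range(1000):
            p = rng.randrange(len(der))
            contig, pos = der.map_from(p)
            assert der.map_to(contig, pos) == p

    def test_sequence_respects_orientation(self, hand_genome):
        der = DerivativeChromosome(
            "d", [Segment("chrT", 0, 4), Segment("chrT", 4, 8, "-")]
        )
        from hijackscan.genome import revcomp

        seq = hand_genome["chrT"].sequence
        assert der.sequence(hand_genome) == seq[0:4] + revcomp(seq[4:8])
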