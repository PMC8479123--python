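"""CTCF convergence, docking-site preservation, module quantification."""

import random

import numpy as np
import pytest

import hijackscan as h
from hijackscan.rearrange import DerivativeChromosome, Segment
from hijackscan.regulatory import CtcfSite, DockingVerdict, EnhancerModule, PromoterAnchor


def brute_convergent(placed, max_span=None):
    """Exhaustive double-loop oracle over placed (site, position) lists."""
    out = []
    for si, pi in placed:
        for sj, pj in placed:
            if (
                si.orientation == "forward"
                and sj.orientation == "reverse"
                and pi < pj
                and (max_span is None or pj - pi <= max_span)
            ):
                out.append((si, sj, pj - pi))
    return sorted(out, key=lambda t: (t[2], t[0].start, t[1].start))


def fwd(pos, contig="c", label=""):
    return CtcfSite(contig, pos - 5, pos + 5, "forward", label=label)


def rev(pos, contig="c", label=""):
    return CtcfSite(contig, pos - 5, pos + 5, "reverse", label=label)


class TestLoadSites:
    def test_forward_site(self):
        sites, skipped = h.load_sites(["chrT\t100\t119\tctcf1\t0\t+"])
        assert skipped == 0
        s = sites[0]
        assert (s.start, s.end, s.orientation) == (100, 119, "forward")

    def test_strandless_skipped_with_count(self):
        sites, skipped = h.load_sites(
            ["chrT\t1\t10\ta\t0\t.", "chrT\t20\t30\tb\t0\t-"]
        )
        assert skipped == 1
        assert [s.orientation for s in sites] == ["reverse"]

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            h.load_sites(["chrT\t1\t10\ta\t0\t+", "chrT\tnope\t10\tb\t0\t+"])

    def test_too_few_columns(self):
        with pytest.raises(ValueError, match="6 BED columns"):
            h.load_sites(["chrT\t1\t10"])


class TestConvergentPairs:
    def test_all_pairs_no_cap(self):
        sites = [fwd(100), fwd(200), rev(300), rev(400)]
        assert len(h.convergent_pairs(sites)) == 4

    def test_span_cap(self):
        sites = [fwd(100), fwd(200), rev(300), rev(400)]
        pairs = h.convergent_pairs(sites, max_span=250)
        assert len(pairs) == 3
        spans = [sp for _, _, sp in pairs]
        assert spans == sorted(spans)

    def test_no_forward_sites(self):
        assert h.convergent_pairs([rev(100), rev(200)]) == []

    def test_mixed_contigs_require_derivative(self):
        with pytest.raises(ValueError, match="derivative"):
            h.convergent_pairs([fwd(100, "a"), rev(200, "b")])

    def test_matches_brute_force_on_random_sets(self):
        rng = random.Random(11)
        for trial in range(20):
            sites = []
            for i in range(rng.randrange(1, 60)):
                pos = rng.randrange(20, 100_000)
                sites.append(fwd(pos) if rng.random() < 0.5 else rev(pos))
            max_span = rng.choice([None, 5_000, 50_000])
            got = h.convergent_pairs(sites, max_span=max_span)
            placed = [(s, s.midpoint) for s in sites]
            assert got == brute_convergent(placed, max_span)

    def test_derivative_reorders_sites(self):
        """A reverse site from the partner contig becomes downstream of the
        docking site once the derivative places it in cis."""
        der = DerivativeChromosome(
            "der", [Segment("cA", 0, 1000), Segment("cB", 500, 1500)]
        )
        dock = fwd(900, "cA")
        partner = rev(700, "cB")
        pairs = h.convergent_pairs([dock, partner], der=der)
        assert len(pairs) == 1
        assert pairs[0][2] == (1000 + (700 - 500)) - 900


class TestDockingPreserved:
    def der(self, junction=500):
        # derivative: cA[0, junction) + cB[2000, 3000)
        return DerivativeChromosome(
            "der", [Segment("cA", 0, junction), Segment("cB", 2000, 3000)]
        )

    def anchor(self, site_lo=890, site_hi=910, promoter=1000, orientation="forward"):
        return PromoterAnchor(
            "cA", promoter, CtcfSite("cA", site_lo, site_hi, orientation, label="dock")
        )

    def test_preserved_when_both_in_one_segment(self):
        # junction upstream of site and promoter, both retained downstream?
        # here: retained segment [0, 1200) holds site [890,910) and promoter 1000
        v = h.docking_preserved(self.anchor(), self.der(junction=1200))
        assert v.preserved

    def der_split(self, junction):
        # both flanks of the junction retained as separate segments
        return DerivativeChromosome(
            "der", [Segment("cA", 0, junction), Segment("cA", junction, 2000)]
        )

    def test_junction_between_site_and_promoter(self):
        v = h.docking_preserved(self.anchor(), self.der_split(junction=950))
        assert not v.preserved and v.covered
        assert "separates" in v.details

    def test_promoter_lost_to_other_derivative(self):
        v = h.docking_preserved(self.anchor(), self.der(junction=950))
        assert not v.preserved and not v.covered

    def test_site_truncated_by_junction(self):
        v = h.docking_preserved(self.anchor(), self.der_split(junction=900))
        assert not v.preserved
        assert "truncated" in v.details

    def test_promoter_not_covered(self):
        v = h.docking_preserved(self.anchor(promoter=5000), self.der(junction=1200))
        assert not v.preserved and not v.covered

    def test_wrong_orientation_fails(self):
        v = h.docking_preserved(
            self.anchor(orientation="reverse"), self.der(junction=1200)
        )
        assert not v.preserved

    def test_convergent_partner_from_joined_segment(self):
        # partner segment cB carries a reverse site downstream of the dock
        # on der coordinates only if dock < junction; site cB:2500 -> der 1700
        partner_sites = [rev(2500, "cB"), fwd(2800, "cB")]
        v = h.docking_preserved(self.anchor(), self.der(1200), partner_sites)
        assert v.preserved and v.convergent_partner_possible
        assert v.pairs and v.pairs[0][1].contig == "cB"

    def test_no_reverse_partner_no_loop(self):
        v = h.docking_preserved(self.anchor(), self.der(1200), [fwd(2500, "cB")])
        assert v.preserved and not v.convergent_partner_possible

    def test_monotone_in_junction_distance(self):
        """Moving the junction farther upstream of the docking site never
        flips preserved from True to False."""
        verdicts = [
            h.docking_preserved(self.anchor(), self.der(junction=j)).preserved
            for j in range(1100, 2000, 50)
        ]
        assert verdicts == sorted(verdicts)  # False never follows True
        assert all(verdicts)


class TestModuleQuantify:
    MODULES = [
        EnhancerModule("C", "c", 100, 300),
        EnhancerModule("D", "c", 400, 500),
    ]

    def test_overlap_counting(self):
        reads = [("c", 90, 110), ("c", 150, 160), ("c", 290, 310), ("c", 420, 430)]
        t = h.module_quantify({"s1": reads}, self.MODULES)
        assert t.set_index("module")["count_s1"].to_dict() == {"C": 3, "D": 1}

    def test_empty_module_and_pseudocount(self):
        t = h.module_quantify(
            {"a": [("c", 120, 130)], "b": [("c", 420, 430)]}, self.MODULES
        )
        row = t.set_index("module").loc["D"]
        assert row["count_a"] == 0 and row["rpkm_a"] == 0
        assert np.isfinite(row["log2_fold_change"])

    def test_identical_samples_zero_fold_change(self):
        reads = [("c", 150, 170), ("c", 440, 460)]
        t = h.module_quantify({"a": list(reads), "b": list(reads)}, self.MODULES)
        assert np.allclose(t["log2_fold_change"], 0)

    def test_rpkm_halves_when_library_doubles(self):
        reads = [("c", 150, 170)]
        t = h.module_quantify(
            {"a": reads, "b": reads}, self.MODULES,
            library_sizes={"a": 100, "b": 200},
        )
        row = t.set_index("module").loc["C"]
        assert row["rpkm_a"] == pytest.approx(2 * row["rpkm_b"])

    def test_permutation_invariance(self):
        rng = random.Random(5)
        reads = [("c", rng.randrange(0, 600), 0) for _ in range(50)]
        reads = [(c, s, s + 20) for c, s, _ in reads]
        t1 = h.module_quantify({"s": list(reads)}, self.MODULES)
        rng.shuffle(reads)
        t2 = h.module_quantify({"s": reads}, self.MODULES)
        assert t1.equals(t2)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="zero library"):
            h.module_quantify({"s": [("c", 1, 2)]}, self.MODULES,
                              library_sizes={"s": 0})

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            h.module_quantify(
                {"s": [("c", 1, 2)]},
                [EnhancerModule("A", "c", 0, 100), EnhancerModule("B", "c", 50, 150)],
            )
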