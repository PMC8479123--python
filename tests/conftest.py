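import pytest

import hijackscan as h
from hijackscan.genome import Contig, ToyGenome

# Hand-worked 22-bp sequence: GATC at 2 and 16, GTAC at 10.
HANDSEQ = "AAGATCTTTTGTACTTGATCAA"


@pytest.fixture
def hand_genome():
    return ToyGenome([Contig("chrT", HANDSEQ)])


@pytest.fixture
def hand_map(hand_genome):
    return h.annotate_secondary(h.digest(hand_genome), hand_genome)


@pytest.fixture(scope="session")
def fourc_locus():
    """One 20 kb contig with a primary site every 400 bp: 50 fragments,
    plus a viewpoint in fragment 0 and its end catalog."""
    spec = h.GenomeSpec(
        [h.ContigSpec("der3", 20000, 0, primary_sites=[400 * i for i in range(1, 50)])],
        seed=2,
    )
    genome, _ = h.make_toy_genome(spec)
    fragmap = h.annotate_secondary(h.digest(genome), genome)
    primer = genome["der3"].slice(384, 404)  # 20-mer ending in the GATC at 400
    viewpoint = h.Viewpoint("EVI1_PR", "der3", 100, primer, exclusion_radius=1)
    catalog = h.end_catalog(fragmap, genome, 20)
    return genome, fragmap, viewpoint, catalog


@pytest.fixture(scope="session")
def loop_locus():
    """An 80 kb contig with 200 x 400 bp fragments, a central viewpoint
    and a 21-fragment loop-anchor zone (enrichment 10) on its right arm,
    emulating a contiguous high-interaction zone at convergent CTCF
    anchors. Returns (genome, fragmap, viewpoint, catalog, anchor_ids)."""
    n_frag = 200
    spec = h.GenomeSpec(
        [h.ContigSpec("der3", 400 * n_frag, 0,
                      primary_sites=[400 * i for i in range(1, n_frag)])],
        seed=41,
    )
    genome, _ = h.make_toy_genome(spec)
    fragmap = h.annotate_secondary(h.digest(genome), genome)
    primer = genome["der3"].slice(40_384, 40_404)  # ends at the GATC at 40,400
    viewpoint = h.Viewpoint("EVI1_PR", "der3", 40_100, primer, exclusion_radius=2)
    catalog = h.end_catalog(fragmap, genome, 20)
    anchors = list(range(140, 161))
    return genome, fragmap, viewpoint, catalog, anchors


@pytest.fixture(scope="session")
def hf80_translocation():
    """Toy two-contig genome carrying the patient-style t(3;8) junction:
    200 kb loci with genome-scale origins, derivative joining
    chr3:...168,917,999 to chr8:130,487,191... (1-based report style)."""
    return h.make_translocation_scenario(seed=5)
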