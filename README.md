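# hijackscan

Toolkit for analysing **enhancer hijacking by chromosomal translocation**,
built around the t(3;8)(q26;q24) configuration found in *EVI1*-driven acute
myeloid leukemia: a *MYC* super-enhancer translocated next to the *EVI1*
promoter, with CTCF-anchored loops wiring the hijacked enhancer to a
preserved promoter-proximal docking site.

It is aimed at computational biologists who want a small, fully tested,
self-contained implementation of the analysis stages such a study needs —
runnable end-to-end on synthetic data, without access to restricted patient
sequencing.

## What it implements

- **`fragments`** — in-silico restriction digestion (primary DpnII `GATC`,
  secondary Csp6I `GTAC`): genome-tiling fragment maps, blind-fragment
  annotation, and k-mer catalogs of fragment ends.
- **`fourc`** — 4C-seq read processing: viewpoint demultiplexing, primer
  clipping to the restriction motif, fragment-end assignment (k-mer lookup or
  aligned-read boundary filtering), and per-fragment contact counting with a
  viewpoint exclusion zone.
- **`signal`** — RPM normalization over kept reads, running-mean smoothing
  (window 21, shrinking edges), WIG/bedGraph export, fixed-bin RPKM coverage,
  and contact-domain extent summaries.
- **`rearrange`** — a minimal structural-variant caller (discordant-pair
  extraction, single-linkage clustering, split-read refinement to base-pair
  exactness) and `DerivativeChromosome` with exact bidirectional coordinate
  maps between native and rearranged genomes.
- **`regulatory`** — CTCF motif-orientation convergence analysis on native or
  derivative coordinates, the enhancer-docking-site preservation rule, and
  RPKM quantification of reads over named enhancer modules.
- **`synthetic`** — toy genomes with planted restriction sites/CTCF motifs,
  4C reads following a power-law contact decay `P(s) ∝ s^(−α)` with loop
  enrichment at anchor fragment pairs, and junction-straddling capture pairs.

The core contact model: the probability of observing a ligation partner at
genomic separation *s* (in cis on the derivative chromosome) is

```
P(partner = f) ∝ s_f^(−α) · E_f
```

where `α` is the distance-decay exponent and `E_f ≥ 1` a loop-enrichment
factor at convergent-CTCF anchor pairs. Breakpoints are called from read
pairs whose mates map to different contigs (or with aberrant insert or
orientation), clustered per orientation class, then refined by finding the
split point of junction-spanning reads that matches both partner flanks.

## Worked example

Call a translocation from simulated capture sequencing over a derivative
chromosome encoding a patient-style t(3;8) junction:

```python
import hijackscan as h

genome, der, _ = h.make_translocation_scenario(seed=5)
cfg = h.SimulationConfig(seed=7, n_reads=300, read_length=75,
                         junction_span_fraction=0.2)
cp = h.simulate_capture_pairs(genome, der, cfg)

pairs, stats = h.find_discordant(cp.alignments, max_concordant_insert=1000,
                                 min_mapq=10)
cands = h.cluster_candidates(pairs, cluster_window=1000, min_support=2)
bp = h.refine_junction(cands[0], [s for _, s in cp.spanning_reads], genome)
print(bp.report_coords(), bp.support_pairs, bp.support_split, bp.resolution)
```

prints

```
(168917999, 130487191) 60 55 exact
```

i.e. the caller recovers the junction at base-pair exactness — chr3 retained
through 168,917,999 joined to chr8 from 130,487,191 (1-based) — from 60
discordant pairs, with 55 split reads agreeing on the exact coordinate.

The same works from the shell:

```
hijackscan sv --sam pairs.sam --fasta toy.fa --spanning-fastq span.fastq \
    --out breakpoints.tsv
```

For 4C signal, `simulate_4c_reads` → `demultiplex_and_clip` →
`map_trimmed_reads` → `count_contacts` → `rpm_normalize` → `smooth_track`
turns reads into a smoothed RPM track; on 50,000 simulated reads with a
21-fragment anchor zone at enrichment 10, the smoothed track shows the zone
at ~10× the distance-matched background median, and log-log regression of
count on separation recovers the decay exponent within 0.01 of its true
value (see `scripts/acceptance.py` output below).

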