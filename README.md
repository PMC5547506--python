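# tricontact

Fragment-level 4C-seq quantification and tripartite chromatin-contact
detection, with a ground-truthed synthetic-library generator, rank-based
differential statistics, and coordinate liftover for engineered
deletion/inversion alleles.

## The problem

Circular chromosome conformation capture (4C-seq) profiles the contacts of
one chosen locus — the viewpoint or bait — against the rest of the genome.
Chromatin is digested with a frequent first cutter (NlaIII, motif `CATG`)
and a second cutter (DpnII, motif `GATC`), religated, and sequenced from
viewpoint-specific primers. Each read captures the restriction fragment that
was ligated to the bait; per-fragment counts, after normalization and
smoothing, give the viewpoint's contact profile. Because contact frequency
decays with genomic distance roughly as a power law (slope −1 in log-log
scale), long-range signal is best examined after dividing out that decay.

Long single-end reads (~250 bp) can span **two** ligation junctions:
`bait–CATG–X–CATG–Y`. Such reads witness a *tripartite* contact — the
viewpoint, fragment X, and fragment Y were simultaneously close in one
nucleus. Detecting them requires splitting each read at internal `CATG`
seams, mapping the 5′ ("mid") and 3′ ("third") segments independently,
discarding undigested products (segments that are merely collinear genomic
continuations), removing PCR duplicates by mapped position and strand, and
binning the surviving unique X–Y pairs into a symmetric 20-kb matrix. This
is the analysis used to show that a regulatory-island "hub" zone of a TAD
engages several enhancers at once, while regions near the target gene are
involved in far fewer three-way contacts.

`tricontact` implements that computational chain end to end, plus:

- **quant4c** — read→fragment assignment, viewpoint exclusion (±2 kb),
  reads-per-million normalization, 11-fragment running-mean smoothing,
  bait ± 1 Mb window scaling, fixed-slope power-law profile correction,
  replicate averaging;
- **multiway** — demultiplexing, viewpoint stripping, quality/GATC
  trimming, junction splitting with third-segment rescue, exact-unique
  mapping, undigested filtering, deduplication, matrix and zone-occupancy
  statistics;
- **diffcontact** — region quantification, log2 ratios against wild-type
  replicate means, Wilcoxon rank-sum + Benjamini–Hochberg, Kruskal–Wallis
  + Dunn post-hoc tests;
- **rearrange** — mutant genomes for deletion/inversion alleles and exact
  mutant↔wild-type coordinate liftover, including profile projection;
- **simulate** — a synthetic-library generator that plants known contacts
  (power-law decay, islands, TAD boundaries, a three-way hub, PCR
  duplicates, undigested products) and records per-read ground truth, so
  every pipeline stage can be checked for exact recovery.

## Worked example

```python
from tricontact.simulate import SimulationConfig, simulate_library, default_primer_tag
from tricontact.quant4c import ViewpointSpec, quantify, decay_slope
from tricontact.multiway import detect_tripartite, build_matrix, zone_fraction

# standard ~100-bp library: 20,000 reads from a 2-Mb chromosome
cfg = SimulationConfig(chrom_length=2_000_000, viewpoint_pos=500_000,
                       n_reads=20_000, seed=11)
genome, fmap, model, reads, truth = simulate_library(cfg)
frag = fmap.fragment_at("chr2", 500_000)
vp = ViewpointSpec("Hoxd13_like", "chr2", frag.start, frag.end,
                   default_primer_tag(genome, fmap, cfg))
stages = quantify(reads, fmap, genome, vp, correct_decay=True)
print(stages["counts"].total_mapped)          # 19345 mapped reads
print(decay_slope(stages["smoothed"]))        # -1.039  (planted exponent: 1)
print(decay_slope(stages["corrected"]))       # -0.039  (flat after correction)

# multi-way ~250-bp library with a planted hub, duplicates, undigested products
cfg2 = SimulationConfig(chrom_length=2_000_000, viewpoint_pos=500_000,
                        n_reads=2_000, seed=11, duplicate_rate=0.2,
                        undigested_rate=0.1, hub_zone=(1_200_000, 1_350_000),
                        hub_prob=0.5)
genome2, fmap2, model2, reads2, truth2 = simulate_library(cfg2, multiway=True)
frag2 = fmap2.fragment_at("chr2", 500_000)
vp2 = ViewpointSpec("Hoxd13_like", "chr2", frag2.start, frag2.end,
                    default_primer_tag(genome2, fmap2, cfg2))
res = detect_tripartite(reads2, {"s1": "ACGTAC"}, vp2, fmap2, genome2)
print(res.qc["s1"])
# {'unassigned': 0, 'no_primer': 0, 'too_short': 0, 'mid_unmapped': 0,
#  'third_unmapped': 0, 'undigested': 197, 'duplicate': 355, 'unique_contact': 1448}

m = build_matrix(res.contacts["s1"], ("chr2", 1_000_000, 1_900_000))
print(zone_fraction(m, (1_200_000, 1_350_000)))   # 100.0  (hub bins touched)
print(zone_fraction(m, (1_400_000, 1_900_000)))   # 8.0    (flank bins touched)
```

Every input read lands in exactly one QC class, the class counts sum to the
library size, and on error-free synthetic libraries the unique-contact set
equals the planted pair set exactly — `{c.key for c in res.contacts["s1"]}
== truth2.unique_pairs()`.

A `tricontact` console command exposes the same steps for shell use
(`digest`, `simulate`, `quant`, `multiway`, `diff`, `lift`); run
`tricontact --help`.

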