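# Methods

## Restriction-fragment model

A genome is digested in silico at every exact occurrence of the first-cutter
motif (`CATG`, NlaIII). The cut is placed immediately *before* each
occurrence, so fragment k spans `[cut_k, cut_{k+1})`, fragments tile each
chromosome exactly, and every fragment except the first begins with `CATG`.
This convention matches the read dialect: the protocol keeps the junction
`CATG` at the 5′ end of every captured segment, so segment prefixes align to
fragment starts. The second cutter (`GATC`, DpnII) is recorded as a
per-fragment boolean only; sub-fragment ("blind-end") modeling is out of
scope because counts are reported per fragment. Both default motifs are
palindromic, so forward scanning covers both strands; non-palindromic
user-supplied motifs are scanned on both strands. `N` never matches a motif.
Coordinates are 0-based half-open everywhere, including BED on disk.

## Standard 4C quantification

Reads are assigned by exact-unique matching of the captured sequence (from
the first `CATG` after the primer tag) against both strands of the genome,
via a 2-bit 16-mer seed table with full verification. Reads matching zero
or ≥2 loci are discarded and tallied; mismatch-tolerant alignment is a
non-goal (counts from an external aligner can be imported instead). The
stage chain is fixed:

1. **exclusion** — fragments overlapping bait ± 2 kb (default) are zeroed
   and masked; the mapped-read total is recomputed over the remaining
   fragments, so the per-million normalizer refers to reads actually used.
   Whether the excluded reads should count toward the library size is
   ambiguous; recomputing after exclusion is the reading adopted here.
2. **normalize** — reads per million of mapped reads.
3. **smooth** — running mean over 11 fragments, centered, with *shrinking*
   windows at chromosome edges (not padding, not NA): every fragment stays
   defined and constant profiles are fixed points. Excluded fragments
   contribute 0 to neighbours and stay at 0 themselves.
4. **bait-window scaling** — divide by the mean score of non-excluded
   fragments whose midpoint lies within bait ± 1 Mb; that window's mean
   becomes exactly 1, making profiles from libraries of different depth
   comparable.
5. **profile correction** (optional branch, applied to smoothed scores) —
   divide by the expected decay `E(d) = exp(c)·d^(−α)` with α = 1 by
   default. Fixing the slope makes the fit a one-parameter mean:
   `c = mean(log s + α·log d)` over fragments with positive score and
   distance in the fit range (5 kb – 2 Mb by default). Natural log; no
   pseudocount — zero-score fragments are excluded from the fit and stay 0.
   Distance is fragment midpoint to bait midpoint. Whether the bait-window
   scaling uses smoothed or raw scores, and the fit range, are not uniquely
   determined by the protocol; both are parameters with the defaults above.
6. **averaging** — element-wise mean across replicates; exclusion masks are
   unioned.

Stages only advance in this order; the profile object refuses regressions,
so downstream consumers always know what a score vector means.

## Multi-way (tripartite) detection

Reads of ~250 bp are demultiplexed by exact barcode prefix (the original
splitter's strict mode), the viewpoint primer is stripped keeping the
junction `CATG`, 3′ ends are quality-trimmed (running-sum rule with
threshold 10: the maximal suffix whose partial sums of `thr − q` from the
3′ end stay positive is removed) and cut at the first `GATC`, mirroring the
second-cutter chemistry. Reads shorter than 24 bp are discarded. Each read
is split at its first internal `CATG` into a mid (X) and a third (Y)
segment; both are mapped exact-unique on either strand with a 20-bp floor
(a proxy for an aligner's reliability threshold; exposed as a flag). An
unmappable third is rescued once by re-splitting at its next internal
`CATG` and mapping the 5′ part. Mids are never rescued; a read with an
unmapped mid is discarded.

"Undigested" products are interpreted strand-awarely as collinear genomic
continuations: same chromosome, same strand, and the third's fragment index
follows the mid's in reading orientation (+1 on plus, −1 on minus) — only
genomic contiguity produces them, and a non-collinear adjacency is a
genuine ligation. A strand-agnostic variant (|Δindex| = 1) is available
behind a flag. Deduplication keys on the exact 6-tuple (X chrom, pos,
strand; Y chrom, pos, strand), not fragment indices, keeping one
representative per group in first-occurrence order. Unique contacts with
both partners inside the analysis region are binned with
`bin(p) = floor((p − start)/binsize)` (20 kb default) into a symmetric
matrix; same-bin pairs increment the diagonal once. Zone occupancy is the
percentage of zone-overlapping bins whose matrix row is non-empty.

Every read is classified into exactly one of eight QC classes (unassigned,
no-primer, too-short, mid-unmapped, third-unmapped/absent, undigested,
duplicate, unique-contact); class counts sum to the library size by
construction. Reads with ≥3 junctions are out of scope: extra `CATG`
content lives inside the third and is handled only by the single rescue.

## Synthetic-library generator

The generator emulates the dual-enzyme proximity-ligation library around a
single viewpoint on one chromosome:

- **Genome** — random background with all accidental `CATG`/`GATC`
  occurrences scrubbed, then motifs injected at Poisson-spaced positions at
  the configured densities (default 2/kb each, giving ~500-bp fragments, the
  scale of typical NlaIII 4C fragments). Injection sites keep a minimum
  spacing and, because the two motifs cannot create each other across
  block boundaries, observed counts equal injected counts.
- **Contact model** — `P_f ∝ w_f · max(d_f, 1 kb)^(−α)` with α = 1 by
  default (the decay the correction step assumes), where `w_f` multiplies
  island weights (midpoint containment) and a factor β per TAD boundary
  between fragment and viewpoint. Fragments overlapping the viewpoint
  ± 2 kb get probability 0, as does the first fragment of the chromosome
  (it has no upstream cut site, so it cannot present a ligation junction).
  The 1-kb distance floor avoids the singularity at the bait and matches
  the excluded-zone scale.
- **Standard reads** — `barcode + 20-bp primer tag + captured`, where the
  captured sequence is the plus-strand genomic continuation from the drawn
  fragment's start, padded to 100 bp by read-through and truncated only at
  chromosome ends. Strand randomization is reserved for the multi-way
  generator, where strand carries information (undigested filtering,
  duplicate keys); for fragment counting it is cosmetic.
- **Multi-way reads** — `barcode + tag + CATG + body_X + CATG + body_Y`,
  truncated to 250 bp. A body is a GATC-free portion of a fragment read
  from its upstream `CATG` (plus) or back from its downstream `CATG` in
  reverse complement (minus) — the second cutter bounds captured segments
  in the real chemistry, and motif palindromy makes the minus presentation
  begin with `CATG` as well. Bodies that would synthesize `GATC` across a
  junction seam (a body starting with `ATC` after the junction's `G`, or a
  mid body ending in `GAT`) are redrawn, as are coincidental collinear
  pairs, which are indistinguishable from undigested products downstream.
  With probability `hub_prob`, X and Y are drawn uniformly from hub-zone
  fragments (correlated three-way contacts); undigested products replace Y
  by X's collinear neighbour at the configured rate; PCR duplicates are
  byte-exact copies of earlier reads (the worst case for deduplication).
  Each planted segment is verified unique in the genome at generation time,
  and the truth table records the exact position and strand the mapper will
  report, so recovery can be asserted set-exactly.

What the generator does **not** emulate: sequencing errors and indels,
trans-chromosomal partners, chimeric artifacts other than undigested
products, fragment-length biases of amplification, and ≥4-way ligations.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic (splitting, mapping rules, filtering, deduplication,
binning) on clean data, not robustness to base-calling noise — which the
exact-match mapper intentionally does not attempt to handle.

## Statistics

Two-group region comparisons use the two-sided Wilcoxon rank-sum test:
exact enumeration when both samples have ≤ 8 observations and no ties,
otherwise the normal approximation with tie and continuity corrections (the
operative path for fragment-score vectors, which are large). Fully tied
data returns p = 1. The Benjamini–Hochberg family is the set of regions
tested in one invocation. For ≥3 groups, Kruskal–Wallis (tie-corrected) is
followed by Dunn's pairwise z tests on pooled mean ranks with the tie term
`Σ(t³−t)/(12(N−1))`, BH-adjusted across pairs. Significance thresholds are
reported alongside q-values, never used to filter rows. log2 ratios against
the wild-type replicate mean mask zeros rather than pseudocounting, since
fold changes are meaningful only where both conditions have signal.

## Rearrangements

Deletions and inversions are exact half-open interval edits in wild-type
coordinates; loxP scars are not modeled (they are far below fragment
resolution). The coordinate map is a bijection: deletion positions map
`p → p` before the breakpoint and `p → p − L` after; inversion positions
inside the interval reflect as `p → start + end − 1 − p` with a flipped
orientation flag that also flips strands when lifting contacts. Profile
liftover splits mutant fragments at breakpoints, carries scores unchanged,
and marks deleted wild-type intervals with NaN. Multi-edit application
requires pairwise-disjoint specs and applies them right-to-left, making the
result order-independent; nested or overlapping specs are rejected rather
than composed, since all engineered alleles of interest are single edits.

## Problem sizes and numerical choices

The verification workflows use sizes chosen to exercise each behaviour
meaningfully: 100 random 100-kb genomes for the digestion oracle; a 250-kb
chromosome (~500 fragments) for the smoothing/scaling/correction
guarantees; a 4-Mb chromosome with 50,000 standard reads for decay-slope
recovery (slope −1 recovered within a few hundredths); 5,000 multi-way
reads (20% duplicates, 10% undigested, 50% hub draws) with a 0.9-Mb
analysis region of 45 20-kb bins — the span of the real tripartite
analysis — for exact truth recovery and the hub/non-hub occupancy contrast;
1,000 null simulations (n = 20 per group) for type-I error calibration;
10,000 random positions for liftover round trips. Acceptance-script
randomness derives entirely from `--seed`; derived generator seeds are
offset so the genome, the standard library and the multi-way library use
independent streams. Tolerances: bait-window mean is exact to 1e-12,
power-law flattening to 1e-9 in log space; equality checks on planted
truth are set-exact, not approximate.

## Known limitations

- The exact-match mapper requires an error-free read dialect; real FASTQ
  data should be aligned externally and imported as counts.
- Only cis (single-chromosome) profiles are quantified.
- The generator's two-junction geometry covers tripartite contacts only;
  quadripartite and higher orders are neither simulated nor called.
- Breakpoint coordinates for real engineered alleles must be supplied
  externally; allele names alone do not determine them.
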