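"""Synthetic proximity-ligation (4C-seq) library generator with ground truth.

Emulates the data a dual-enzyme 4C experiment produces around a single
viewpoint: a genome carrying first-cutter (CATG) and second-cutter (GATC)
motifs at configurable densities, a viewpoint-anchored contact model with
power-law distance decay, regulatory-island enrichment and TAD boundary
attenuation, and two library geometries — ~100-bp standard single-end reads
(one ligation junction) and ~250-bp multi-way reads carrying two junctions
(viewpoint–X–Y triples).  A configurable "hub" zone plants correlated
three-way contacts.  PCR duplicates (byte-exact read copies) and undigested
products (collinear adjacent-fragment pairs) are planted at configurable
rates, and every read is recorded in a :class:`SyntheticTruth` table so
downstream recovery can be checked exactly.

The generated read dialect is::

    barcode + primer_tag + CATG + segment [+ CATG + segment]

where each segment is a GATC-free portion of a restriction fragment, read
either from the fragment's upstream CATG (plus strand) or from its
downstream CATG in reverse complement (minus strand).  Both motifs are
palindromic, so a segment free of a motif is free of it on either strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fragmap import FragmentMap, Genome, digest, reverse_complement
from .reads import RawRead
from .seqindex import GenomeIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

HIGH_QUALITY = 40


@dataclass
class SimulationConfig:
    """Generative parameters; defaults mirror the study conditions.

    Densities are expected motif occurrences per kb; with 2/kb first-cutter
    sites the mean fragment is ~500 bp, the scale of a typical NlaIII 4C
    fragment.  ``chrom_length`` defaults to 0.9 Mb, the span of the
    tripartite analysis region.  ``decay_exponent`` defaults to 1, the
    slope of contact decay in log-log scale used for profile correction.
    """

    chrom_length: int = 900_000
    chrom_name: str = "chr2"
    first_density: float = 2.0
    second_density: float = 2.0
    viewpoint_pos: int = 450_000
    islands: List[Tuple[int, int, float]] = field(default_factory=list)
    tads: List[Tuple[int, int]] = field(default_factory=list)
    boundary_attenuation: float = 1.0
    decay_exponent: float = 1.0
    hub_zone: Optional[Tuple[int, int]] = None
    hub_prob: float = 0.0
    n_reads: int = 10_000
    duplicate_rate: float = 0.0
    undigested_rate: float = 0.0
    read_length: int = 250
    standard_read_length: int = 100
    two_junction_fraction: float = 1.0
    barcodes: List[str] = field(default_factory=lambda: ["ACGTAC"])
    seed: int = 0
    exclusion_radius: int = 2_000
    min_distance: int = 1_000  # decay floor, matches the excluded-zone scale
    primer_tag: Optional[str] = None  # derived from the viewpoint fragment

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not 0 <= self.viewpoint_pos < self.chrom_length:
            raise ValueError("viewpoint_pos outside chromosome")
        for s, e, w in self.islands:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"island ({s},{e}) outside chromosome")
            if w < 1:
                raise ValueError("island weights must be >= 1")
        for s, e in self.tads:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"tad ({s},{e}) outside chromosome")
        if not 0 < self.boundary_attenuation <= 1:
            raise ValueError("boundary_attenuation must be in (0,1]")
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        if self.hub_zone is not None:
            s, e = self.hub_zone
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError("hub_zone outside chromosome")
        if not 0 <= self.hub_prob <= 1:
            raise ValueError("hub_prob must be in [0,1]")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0,1)")
        if not 0 <= self.undigested_rate < 1:
            raise ValueError("undigested_rate must be in [0,1)")
        if not 0 < self.two_junction_fraction <= 1:
            raise ValueError("two_junction_fraction must be in (0,1]")
        if not self.barcodes:
            raise ValueError("at least one barcode is required")
        if len({len(b) for b in self.barcodes}) != 1:
            raise ValueError("barcodes must be equal-length")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be pairwise distinct")
        if self.read_length < 3 * 4 + 20:
            raise ValueError("read_length too short for two-junction reads")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["islands"] = [tuple(x) for x in d.get("islands", [])]
        d["tads"] = [tuple(x) for x in d.get("tads", [])]
        if d.get("hub_zone") is not None:
            d["hub_zone"] = tuple(d["hub_zone"])
        return cls(**d)


@dataclass
class ContactModel:
    """Normalized per-fragment contact probabilities around the viewpoint."""

    fragment_map: FragmentMap
    chrom: str
    weights: np.ndarray
    probs: np.ndarray
    viewpoint_fragment: int

    def __post_init__(self) -> None:
        if abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("contact probabilities must sum to 1")


@dataclass
class TruthRecord:
    read_id: str
    sample: str  # barcode
    x_fragment: Optional[int]
    x_pos: Optional[int]  # leftmost mapped coordinate the pipeline will report
    x_strand: Optional[str]
    y_fragment: Optional[int] = None
    y_pos: Optional[int] = None
    y_strand: Optional[str] = None
    duplicate_of: Optional[str] = None
    undigested: bool = False


@dataclass
class SyntheticTruth:
    chrom: str
    records: List[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def duplicate_ids(self) -> set:
        return {r.read_id for r in self.records if r.duplicate_of is not None}

    def undigested_ids(self) -> set:
        return {
            r.read_id
            for r in self.records
            if r.undigested and r.duplicate_of is None
        }

    def unique_pairs(self, sample: Optional[str] = None) -> set:
        """Distinct (x_chrom,x_pos,x_strand,y_chrom,y_pos,y_strand) tuples
        over kept reads (non-duplicate, non-undigested, two-junction)."""
        pairs = set()
        for r in self.records:
            if r.duplicate_of is not None or r.undigested or r.y_pos is None:
                continue
            if sample is not None and r.sample != sample:
                continue
            pairs.add(
                (self.chrom, r.x_pos, r.x_strand, self.chrom, r.y_pos, r.y_strand)
            )
        return pairs

    def planted_fragment_counts(self, n_fragments: int) -> np.ndarray:
        counts = np.zeros(n_fragments, dtype=int)
        for r in self.records:
            if r.x_fragment is not None:
                counts[r.x_fragment] += 1
        return counts

    def to_tsv(self, path) -> None:
        cols = (
            "read_id sample x_chrom x_pos x_strand y_pos y_strand "
            "duplicate_of undigested"
        ).split()
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fh.write(
                    "\t".join(
                        str(v) if v is not None else "."
                        for v in (
                            r.read_id,
                            r.sample,
                            self.chrom,
                            r.x_pos,
                            r.x_strand,
                            r.y_pos,
                            r.y_strand,
                            r.duplicate_of,
                            int(r.undigested),
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# genome simulation


def _scrub_motifs(seq: bytearray, motifs: Sequence[bytes], rng) -> None:
    # destroy accidental motif occurrences so observed density = injected density
    for _ in range(100):
        dirty = False
        for m in motifs:
            i = bytes(seq).find(m)
            while i != -1:
                mid = i + len(m) // 2
                old = seq[mid]
                choices = [b for b in b"ACGT" if b != old]
                seq[mid] = choices[rng.integers(len(choices))]
                dirty = True
                i = bytes(seq).find(m, i + 1)
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


def simulate_genome(config: SimulationConfig) -> Genome:
    """Random motif-free background with motifs injected at Poisson-spaced
    positions, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    motifs = [b"CATG", b"GATC"]
    densities = [config.first_density, config.second_density]
    mean_injections = sum(d / 1000.0 * L for d in densities)
    gap = max(len(m) for m in motifs)
    if mean_injections * 2 * gap > L:
        raise ValueError("motif densities exceed injection capacity")

    seq = bytearray(_BASES[rng.integers(0, 4, size=L)].tobytes())
    _scrub_motifs(seq, motifs, rng)

    # cell hash over 2*gap-wide cells keeps the min-spacing check O(1)
    cells: Dict[int, List[int]] = {}
    width = 2 * gap

    def blocked(p: int) -> bool:
        c = p // width
        return any(
            abs(p - q) < width for cc in (c - 1, c, c + 1) for q in cells.get(cc, ())
        )

    for motif, density in zip(motifs, densities):
        n = rng.poisson(density / 1000.0 * L)
        placed = 0
        attempts = 0
        while placed < n and attempts < 50 * n + 1000:
            attempts += 1
            p = int(rng.integers(0, L - len(motif) + 1))
            if blocked(p):
                continue
            seq[p : p + len(motif)] = motif
            cells.setdefault(p // width, []).append(p)
            placed += 1
        if placed < n:
            raise ValueError("motif densities exceed injection capacity")
    return Genome(
        sequences={config.chrom_name: seq.decode()}, assembly_label="synthetic"
    )


# ---------------------------------------------------------------------------
# contact model


def _count_boundaries(tads: Sequence[Tuple[int, int]], a: float, b: float) -> int:
    lo, hi = min(a, b), max(a, b)
    return sum(1 for s, e in tads for x in (s, e) if lo < x < hi)


def build_contact_model(fmap: FragmentMap, config: SimulationConfig) -> ContactModel:
    """Per-fragment probabilities P_f ∝ w_f · max(d_f, d_min)^(−α).

    w_f combines the island weight of the fragment's midpoint with a factor
    β per TAD boundary crossed between fragment and viewpoint.  Fragments
    overlapping the viewpoint exclusion zone get probability 0.
    """
    chrom = config.chrom_name
    frags = fmap.fragments[chrom]
    mids = np.array([f.midpoint for f in frags])
    vp_idx = fmap.locate(chrom, config.viewpoint_pos)
    vp_mid = frags[vp_idx].midpoint

    weights = np.ones(len(frags))
    for s, e, w in config.islands:
        weights[(mids >= s) & (mids < e)] *= w
    if config.boundary_attenuation < 1 and config.tads:
        beta = config.boundary_attenuation
        for i, m in enumerate(mids):
            weights[i] *= beta ** _count_boundaries(config.tads, m, vp_mid)

    d = np.abs(mids - vp_mid)
    unnorm = weights * np.maximum(d, config.min_distance) ** (
        -config.decay_exponent
    )

    lo = config.viewpoint_pos - config.exclusion_radius
    hi = config.viewpoint_pos + config.exclusion_radius
    excluded = np.array([f.start < hi and f.end > lo for f in frags])
    unnorm[excluded] = 0.0
    # the first fragment has no upstream first-cutter site, so it can never
    # present a CATG ligation junction and is not a capturable partner
    unnorm[0] = 0.0
    total = unnorm.sum()
    if total <= 0:
        raise ValueError("degenerate contact model: all weights zero")
    return ContactModel(
        fragment_map=fmap,
        chrom=chrom,
        weights=weights,
        probs=unnorm / total,
        viewpoint_fragment=vp_idx,
    )


def default_primer_tag(genome: Genome, fmap: FragmentMap, config: SimulationConfig) -> str:
    """20-bp tag from the start of the viewpoint fragment (its bait end)."""
    frag = fmap.fragment_at(config.chrom_name, config.viewpoint_pos)
    tag = genome[config.chrom_name][frag.start : frag.start + 20]
    if len(tag) < 20:
        raise ValueError("viewpoint fragment too short for a 20-bp primer tag")
    return tag


# ---------------------------------------------------------------------------
# read simulation

_MIN_BODY = 16  # segment body floor so mid/third stay above the 20-bp mappable floor
_MAX_MID_BODY = 100


def _resolve_tag(genome, fmap, config) -> str:
    return (
        config.primer_tag
        if config.primer_tag is not None
        else default_primer_tag(genome, fmap, config)
    )


def simulate_standard_reads(
    model: ContactModel, genome: Genome, config: SimulationConfig
) -> Tuple[List[RawRead], SyntheticTruth]:
    """~100-bp single-junction library: barcode + tag + captured sequence.

    The captured sequence is the genomic continuation from the drawn
    fragment's start (beginning with its CATG), truncated only at the
    chromosome end, so exact matching recovers the planted fragment.
    """
    rng = np.random.default_rng(config.seed + 1)
    fmap = model.fragment_map
    chrom = model.chrom
    seq = genome[chrom]
    tag = _resolve_tag(genome, fmap, config)
    frags = fmap.fragments[chrom]
    truth = SyntheticTruth(chrom=chrom)
    reads: List[RawRead] = []
    if config.n_reads == 0:
        return reads, truth

    cap_len = config.standard_read_length - len(config.barcodes[0]) - len(tag)
    if cap_len < 8:
        raise ValueError("standard_read_length too short for barcode+tag+capture")
    draws = rng.choice(len(frags), size=config.n_reads, p=model.probs)
    bc_draws = rng.integers(0, len(config.barcodes), size=config.n_reads)
    for i in range(config.n_reads):
        f = int(draws[i])
        barcode = config.barcodes[int(bc_draws[i])]
        captured = seq[frags[f].start : frags[f].start + cap_len]
        read_seq = barcode + tag + captured
        rid = f"std_{i}"
        reads.append(RawRead(rid, read_seq, (HIGH_QUALITY,) * len(read_seq)))
        truth.records.append(
            TruthRecord(
                read_id=rid,
                sample=barcode,
                x_fragment=f,
                x_pos=frags[f].start,
                x_strand="+",
            )
        )
    return reads, truth


class _SegmentTable:
    """Per-fragment, per-strand capturable segment bodies.

    The body of fragment f on '+' is the sequence after its leading CATG,
    cut before the first GATC (the second-cutter end); on '-' it is the
    reverse complement read back from the fragment's downstream CATG,
    likewise GATC-cut.  Bodies are CATG-free by construction (fragments lie
    between consecutive CATG sites; both motifs are palindromic).
    """

    def __init__(self, genome: Genome, fmap: FragmentMap, chrom: str):
        self.frags = fmap.fragments[chrom]
        seq = genome[chrom]
        n = len(self.frags)
        self.body: Dict[Tuple[int, str], str] = {}
        for f in range(n):
            s, e = self.frags[f].start, self.frags[f].end
            if f >= 1:
                b = seq[s + 4 : e]
                g = b.find("GATC")
                self.body[(f, "+")] = b if g == -1 else b[:g]
            if f <= n - 2 and seq[e : e + 4] == "CATG":
                b = reverse_complement(seq[s + 4 : e])
                g = b.find("GATC")
                self.body[(f, "-")] = b if g == -1 else b[:g]

    def eligible(self, key: Tuple[int, str]) -> bool:
        b = self.body.get(key)
        if b is None or len(b) < _MIN_BODY:
            return False
        # every body follows a CATG junction; one starting with ATC would
        # synthesize GATC across the seam and be destroyed by the adapter trim
        if b.startswith("ATC"):
            return False
        return True

    def mapped_pos(self, key: Tuple[int, str], body_len: int) -> int:
        f, strand = key
        if strand == "+":
            return self.frags[f].start
        return self.frags[f].end - body_len


def simulate_multiway_reads(
    model: ContactModel, genome: Genome, config: SimulationConfig
) -> Tuple[List[RawRead], SyntheticTruth]:
    """~250-bp two-junction library with planted triples, hub structure,
    PCR duplicates, and undigested (collinear adjacent-fragment) products."""
    rng = np.random.default_rng(config.seed + 2)
    fmap = model.fragment_map
    chrom = model.chrom
    frags = fmap.fragments[chrom]
    tag = _resolve_tag(genome, fmap, config)
    table = _SegmentTable(genome, fmap, chrom)
    truth = SyntheticTruth(chrom=chrom)
    reads: List[RawRead] = []
    index = GenomeIndex(genome)
    mids = np.array([f.midpoint for f in frags])

    def draw_strand() -> str:
        return "+" if rng.integers(2) == 0 else "-"

    eligible_x = eligible_y = table.eligible

    hub_frag_idx: List[int] = []
    if config.hub_zone is not None:
        s, e = config.hub_zone
        hub_frag_idx = [
            i for i in range(len(frags)) if s <= mids[i] < e
        ]
        if not hub_frag_idx:
            raise ValueError("hub_zone contains no fragment")

    cum = np.cumsum(model.probs)

    def draw_from_probs() -> int:
        return int(np.searchsorted(cum, rng.random(), side="right"))

    def draw_pair() -> Tuple[Tuple[int, str], Tuple[int, str], bool]:
        for _ in range(10_000):
            if config.hub_zone is not None and rng.random() < config.hub_prob:
                xf = hub_frag_idx[int(rng.integers(len(hub_frag_idx)))]
                yf = hub_frag_idx[int(rng.integers(len(hub_frag_idx)))]
                x, y = (xf, draw_strand()), (yf, draw_strand())
            else:
                x = (draw_from_probs(), draw_strand())
                y = (draw_from_probs(), draw_strand())
            undig = rng.random() < config.undigested_rate
            collinear_next = (x[0] + 1 if x[1] == "+" else x[0] - 1, x[1])
            if undig:
                # undigested = collinear genomic continuation of X
                y = collinear_next
            elif y == collinear_next:
                # a coincidental collinear draw is indistinguishable from an
                # undigested product downstream; redraw
                continue
            if eligible_x(x) and eligible_y(y):
                return x, y, undig
        raise RuntimeError("could not draw an eligible fragment pair")

    def draw_single() -> Tuple[int, str]:
        for _ in range(10_000):
            x = (draw_from_probs(), draw_strand())
            if eligible_x(x):
                return x
        raise RuntimeError("could not draw an eligible fragment")

    def unique_segment(seg: str) -> bool:
        return index.find_unique(seg) is not None

    budget = config.read_length - len(config.barcodes[0]) - len(tag)
    for i in range(config.n_reads):
        rid = f"mw_{i}"
        if reads and rng.random() < config.duplicate_rate:
            j = int(rng.integers(len(reads)))
            src = truth.records[j]
            reads.append(RawRead(rid, reads[j].sequence, reads[j].qualities))
            truth.records.append(
                TruthRecord(
                    read_id=rid,
                    sample=src.sample,
                    x_fragment=src.x_fragment,
                    x_pos=src.x_pos,
                    x_strand=src.x_strand,
                    y_fragment=src.y_fragment,
                    y_pos=src.y_pos,
                    y_strand=src.y_strand,
                    duplicate_of=src.read_id,
                    undigested=src.undigested,
                )
            )
            continue

        barcode = config.barcodes[int(rng.integers(len(config.barcodes)))]
        two_junction = rng.random() < config.two_junction_fraction
        for _ in range(10_000):
            if two_junction:
                x, y, undig = draw_pair()
            else:
                x, undig = draw_single(), False
            bx = table.body[x]
            tx = int(
                rng.integers(_MIN_BODY, min(len(bx), _MAX_MID_BODY) + 1)
            )
            mid_seg = "CATG" + bx[:tx]
            if not unique_segment(mid_seg):
                continue
            if not two_junction:
                y = None
                third_seg = ""
            else:
                by = table.body[y]
                ty = min(len(by), budget - 4 - tx - 4)
                if ty < _MIN_BODY:
                    continue
                third_seg = "CATG" + by[:ty]
                if not unique_segment(third_seg):
                    continue
            # the random cut can still leave GATC across a junction seam
            # (e.g. a mid body ending in GAT); such inserts would be cut by
            # the adapter trim, so redraw
            if "GATC" in mid_seg + third_seg:
                continue
            break
        else:
            raise RuntimeError("could not assemble a mappable multiway read")

        read_seq = barcode + tag + mid_seg + third_seg
        reads.append(RawRead(rid, read_seq, (HIGH_QUALITY,) * len(read_seq)))
        rec = TruthRecord(
            read_id=rid,
            sample=barcode,
            x_fragment=x[0],
            x_pos=table.mapped_pos(x, tx),
            x_strand=x[1],
            undigested=undig,
        )
        if y is not None:
            rec.y_fragment = y[0]
            rec.y_pos = table.mapped_pos(y, ty)
            rec.y_strand = y[1]
        truth.records.append(rec)
    return reads, truth


def simulate_library(config: SimulationConfig, multiway: bool = False):
    """Convenience end-to-end generation: genome, digest, model, reads."""
    genome = simulate_genome(config)
    fmap = digest(genome)
    model = build_contact_model(fmap, config)
    gen = simulate_multiway_reads if multiway else simulate_standard_reads
    reads, truth = gen(model, genome, config)
    return genome, fmap, model, reads, truth
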