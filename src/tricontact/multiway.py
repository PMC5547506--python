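"""Tripartite-contact detection from long (~250 bp) single-end 4C reads.

A proximity-ligation read carrying two CATG junctions evidences a
three-way contact: viewpoint–X–Y.  The detection chain is

  demultiplex (exact barcode prefix) → strip viewpoint primer (keep the
  junction CATG) → 3' quality trim and cut at the first GATC (second-cutter
  adapter) → split at the first internal CATG into a 5' "mid" (X) and a 3'
  "third" (Y) segment → map both segments exactly and uniquely on either
  strand, with one rescue re-split of an unmappable third → drop undigested
  products (mid and third collinear genomic continuations) → deduplicate on
  mapping position and strand of both segments → bin the unique X–Y pairs
  into a symmetric 20-kb contact matrix.

Every input read ends up in exactly one QC class, so class counts always
sum to the library size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fragmap import FragmentMap, Genome
from .quant4c import ViewpointSpec
from .reads import RawRead
from .seqindex import GenomeIndex

QC_CLASSES = (
    "unassigned",
    "no_primer",
    "too_short",
    "mid_unmapped",
    "third_unmapped",
    "undigested",
    "duplicate",
    "unique_contact",
)


@dataclass(frozen=True)
class SegmentHit:
    role: str  # "mid" or "third"
    chrom: str
    pos: int  # leftmost mapped coordinate, 0-based
    strand: str
    fragment_index: int


@dataclass(frozen=True)
class TripartiteContact:
    viewpoint: str
    x_chrom: str
    x_pos: int
    x_strand: str
    y_chrom: str
    y_pos: int
    y_strand: str

    @property
    def key(self) -> Tuple:
        return (
            self.x_chrom,
            self.x_pos,
            self.x_strand,
            self.y_chrom,
            self.y_pos,
            self.y_strand,
        )


# ---------------------------------------------------------------------------
# read processing


def demultiplex(
    reads: Sequence[RawRead], barcode_table: Dict[str, str]
) -> Dict[str, List[RawRead]]:
    """Exact-prefix barcode assignment; the barcode is removed from the read.

    Reads matching no barcode go to the ``"unassigned"`` bin unmodified.
    """
    barcodes = list(barcode_table.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in table")
    if len({len(b) for b in barcodes}) > 1:
        raise ValueError("barcodes must be equal-length")
    by_prefix = {b: sample for sample, b in barcode_table.items()}
    blen = len(barcodes[0])
    out: Dict[str, List[RawRead]] = {s: [] for s in barcode_table}
    out["unassigned"] = []
    for read in reads:
        sample = by_prefix.get(read.sequence[:blen])
        if sample is None:
            out["unassigned"].append(read)
        else:
            out[sample].append(read.slice(blen))
    return out


def strip_viewpoint(read: RawRead, vp: ViewpointSpec) -> Optional[RawRead]:
    """Remove the leading primer tag; the read then begins at the first
    CATG following it (the kept first-cutter junction).  Reads lacking the
    tag, or lacking any CATG after it, are discarded (None)."""
    if not read.sequence.startswith(vp.primer_tag):
        return None
    j = read.sequence.find("CATG", len(vp.primer_tag))
    if j == -1:
        return None
    return read.slice(j)


def quality_trim_length(qualities: Sequence[int], q_threshold: int) -> int:
    """Length of the maximal 3' suffix whose running sum of
    (q_threshold - q), accumulated from the 3' end, stays positive."""
    best = 0
    s = 0
    for k, q in enumerate(reversed(qualities), start=1):
        s += q_threshold - q
        if s > 0:
            best = k
        else:
            break
    return best


def trim(
    read: RawRead,
    q_threshold: int = 10,
    adapter: str = "GATC",
    min_len: int = 24,
) -> Optional[RawRead]:
    """3' quality trim, then cut at the first adapter (GATC) occurrence;
    reads shorter than ``min_len`` afterwards are discarded (None)."""
    cut = len(read) - quality_trim_length(read.qualities, q_threshold)
    trimmed = read.slice(0, cut)
    a = trimmed.sequence.find(adapter)
    if a != -1:
        trimmed = trimmed.slice(0, a)
    if len(trimmed) < min_len:
        return None
    return trimmed


def split_read(read: RawRead) -> Tuple[RawRead, Optional[RawRead]]:
    """Split at the first CATG occurrence after position 0: the 5' part is
    the "mid" segment, the 3' part (beginning with CATG) the "third"."""
    i = read.sequence.find("CATG", 1)
    if i == -1:
        return read, None
    return read.slice(0, i), read.slice(i)


def map_segment(
    segment: RawRead,
    index: GenomeIndex,
    fmap: FragmentMap,
    role: str,
    min_len: int = 20,
) -> Optional[SegmentHit]:
    """Exact-unique both-strand mapping; 0 or >=2 loci, or a segment below
    ``min_len``, is unmapped (None)."""
    if len(segment) < min_len:
        return None
    hit = index.find_unique(segment.sequence)
    if hit is None:
        return None
    return SegmentHit(
        role=role,
        chrom=hit.chrom,
        pos=hit.pos,
        strand=hit.strand,
        fragment_index=fmap.locate(hit.chrom, hit.pos),
    )


def rescue_third(
    third: RawRead,
    index: GenomeIndex,
    fmap: FragmentMap,
    min_len: int = 20,
) -> Optional[SegmentHit]:
    """Re-split an unmappable third at its first internal CATG and map the
    5' part; no internal CATG or still non-unique → unmapped."""
    i = third.sequence.find("CATG", 1)
    if i == -1:
        return None
    return map_segment(third.slice(0, i), index, fmap, "third", min_len)


def is_undigested(
    mid: SegmentHit, third: SegmentHit, strand_aware: bool = True
) -> bool:
    """True if mid and third are collinear genomic continuations (incomplete
    digestion), i.e. same chromosome, same strand and the third's fragment
    follows the mid's in reading orientation.  With ``strand_aware=False``
    any |Δindex| = 1 on the same chromosome is treated as undigested."""
    if mid.chrom != third.chrom:
        return False
    if not strand_aware:
        return abs(third.fragment_index - mid.fragment_index) == 1
    if mid.strand != third.strand:
        return False
    step = 1 if mid.strand == "+" else -1
    return third.fragment_index == mid.fragment_index + step


def filter_undigested(
    mid: SegmentHit, third: SegmentHit, fmap: FragmentMap, strand_aware: bool = True
) -> str:
    """'drop' for undigested pairs, 'keep' otherwise."""
    return "drop" if is_undigested(mid, third, strand_aware) else "keep"


def deduplicate(contacts: Sequence[TripartiteContact]) -> List[TripartiteContact]:
    """One representative per (X pos/strand, Y pos/strand) 6-tuple, in
    first-occurrence order — the PCR-duplicate removal step."""
    seen = set()
    out: List[TripartiteContact] = []
    for c in contacts:
        if c.key not in seen:
            seen.add(c.key)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class MultiwayResult:
    contacts: Dict[str, List[TripartiteContact]]  # sample -> unique contacts
    qc: Dict[str, Dict[str, int]]  # sample -> class counts
    dropped_undigested: Dict[str, List[TripartiteContact]] = field(
        default_factory=dict
    )

    def all_contacts(self) -> List[TripartiteContact]:
        return [c for cs in self.contacts.values() for c in cs]

    def qc_totals(self) -> Dict[str, int]:
        totals = {k: 0 for k in QC_CLASSES}
        for counts in self.qc.values():
            for k, v in counts.items():
                totals[k] += v
        return totals


def detect_tripartite(
    reads: Sequence[RawRead],
    barcode_table: Dict[str, str],
    vp: ViewpointSpec,
    fmap: FragmentMap,
    genome: Genome,
    q_threshold: int = 10,
    min_trimmed_len: int = 24,
    min_segment_len: int = 20,
    strand_aware_undigested: bool = True,
    index: Optional[GenomeIndex] = None,
) -> MultiwayResult:
    """Run the full detection chain; every read lands in one QC class."""
    if index is None:
        index = GenomeIndex(genome)
    bins = demultiplex(reads, barcode_table)
    result = MultiwayResult(contacts={}, qc={})
    for sample in barcode_table:
        counts = {k: 0 for k in QC_CLASSES}
        raw_contacts: List[TripartiteContact] = []
        dropped: List[TripartiteContact] = []
        for read in bins[sample]:
            stripped = strip_viewpoint(read, vp)
            if stripped is None:
                counts["no_primer"] += 1
                continue
            trimmed = trim(stripped, q_threshold=q_threshold, min_len=min_trimmed_len)
            if trimmed is None:
                counts["too_short"] += 1
                continue
            mid_seg, third_seg = split_read(trimmed)
            mid = map_segment(mid_seg, index, fmap, "mid", min_segment_len)
            if mid is None:
                counts["mid_unmapped"] += 1
                continue
            third = None
            if third_seg is not None:
                third = map_segment(third_seg, index, fmap, "third", min_segment_len)
                if third is None:
                    third = rescue_third(third_seg, index, fmap, min_segment_len)
            if third is None:
                counts["third_unmapped"] += 1
                continue
            contact = TripartiteContact(
                viewpoint=vp.name,
                x_chrom=mid.chrom,
                x_pos=mid.pos,
                x_strand=mid.strand,
                y_chrom=third.chrom,
                y_pos=third.pos,
                y_strand=third.strand,
            )
            if is_undigested(mid, third, strand_aware_undigested):
                counts["undigested"] += 1
                dropped.append(contact)
                continue
            raw_contacts.append(contact)
        unique = deduplicate(raw_contacts)
        counts["duplicate"] = len(raw_contacts) - len(unique)
        counts["unique_contact"] = len(unique)
        result.contacts[sample] = unique
        result.qc[sample] = counts
        result.dropped_undigested[sample] = dropped
    qc_un = {k: 0 for k in QC_CLASSES}
    qc_un["unassigned"] = len(bins["unassigned"])
    result.qc["unassigned"] = qc_un
    return result


# ---------------------------------------------------------------------------
# matrix


@dataclass
class TripartiteMatrix:
    chrom: str
    start: int
    end: int
    binsize: int
    matrix: np.ndarray  # symmetric n_bins x n_bins counts of unique triples
    contacts: List[TripartiteContact]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_start(self, i: int) -> int:
        return self.start + i * self.binsize


def build_matrix(
    contacts: Sequence[TripartiteContact],
    region: Tuple[str, int, int],
    binsize: int = 20_000,
) -> TripartiteMatrix:
    """Symmetric binned count matrix of unique in-region X–Y pairs.

    Only contacts with both X and Y inside ``region`` are kept;
    bin(p) = floor((p - start)/binsize).  Off-diagonal pairs are mirrored;
    same-bin pairs increment the diagonal once.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("region end must be > start")
    n_bins = math.ceil((end - start) / binsize)
    mat = np.zeros((n_bins, n_bins), dtype=int)
    kept: List[TripartiteContact] = []
    for c in contacts:
        if c.x_chrom != chrom or c.y_chrom != chrom:
            continue
        if not (start <= c.x_pos < end and start <= c.y_pos < end):
            continue
        bi = (c.x_pos - start) // binsize
        bj = (c.y_pos - start) // binsize
        mat[bi, bj] += 1
        if bi != bj:
            mat[bj, bi] += 1
        kept.append(c)
    return TripartiteMatrix(
        chrom=chrom, start=start, end=end, binsize=binsize, matrix=mat, contacts=kept
    )


def zone_fraction(matrix: TripartiteMatrix, zone: Tuple[int, int]) -> float:
    """Percentage of zone bins involved in >=1 tripartite interaction.

    A bin belongs to the zone if its interval overlaps it; a bin is
    "involved" if its matrix row has any nonzero entry.
    """
    zs, ze = zone
    bins = [
        i
        for i in range(matrix.n_bins)
        if matrix.bin_start(i) < ze and matrix.bin_start(i) + matrix.binsize > zs
    ]
    if not bins:
        raise ValueError("zone overlaps no bin")
    touched = sum(1 for i in bins if matrix.matrix[i].any())
    return 100.0 * touched / len(bins)


# ---------------------------------------------------------------------------
# I/O


def write_contacts(result: MultiwayResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample\tx_chrom\tx_pos\tx_strand\ty_chrom\ty_pos\ty_strand\n"
        )
        for sample, contacts in result.contacts.items():
            for c in contacts:
                fh.write(
                    f"{sample}\t{c.x_chrom}\t{c.x_pos}\t{c.x_strand}\t"
                    f"{c.y_chrom}\t{c.y_pos}\t{c.y_strand}\n"
                )


def write_matrix(matrix: TripartiteMatrix, path) -> None:
    header = "\t".join(str(matrix.bin_start(i)) for i in range(matrix.n_bins))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in matrix.matrix:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def write_qc(result: MultiwayResult, path) -> None:
    with open(path, "w") as fh:
        json.dump({"per_sample": result.qc, "totals": result.qc_totals()}, fh, indent=2)


def read_barcode_table(path) -> Dict[str, str]:
    table: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, barcode = line.split("\t")[:2]
            table[sample] = barcode
    return table
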