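"""Genome representation and in-silico double restriction digestion.

A 4C-seq library is built with two restriction enzymes applied in sequence:
a frequent first cutter (NlaIII, motif ``CATG``) that defines the fragments
whose contacts are counted, and a second cutter (DpnII, motif ``GATC``) used
for circularisation.  This module digests a genome at every first-cutter
site, producing an ordered map of restriction fragments per chromosome, and
annotates each fragment with a flag for the presence of the second-cutter
motif.  Fragments tile each chromosome exactly; the cut is placed
immediately *before* each motif occurrence, so every non-initial fragment
begins with the first-cutter motif — the orientation in which ligation
junctions appear at the 5' end of captured reads.

Coordinates are 0-based half-open throughout, matching BED on disk.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterator, List

from Bio import SeqIO
from Bio.Seq import Seq

_VALID_BASES = frozenset("ACGTN")
_MOTIF_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class Genome:
    """Ordered chromosome-name -> DNA sequence map (alphabet A,C,G,T,N)."""

    sequences: Dict[str, str]
    assembly_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            if set(seq) - _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {bad}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> List[str]:
        return list(self.sequences)

    @classmethod
    def from_fasta(cls, path, assembly_label: str = "") -> "Genome":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(sequences=sequences, assembly_label=assembly_label)

    def to_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


@dataclass(frozen=True)
class RestrictionFragment:
    chrom: str
    start: int
    end: int
    index: int
    has_second_cutter: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class FragmentMap:
    """Per-chromosome ordered restriction fragments from a double digest."""

    first_motif: str = "CATG"
    second_motif: str = "GATC"
    fragments: Dict[str, List[RestrictionFragment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for motif in (self.first_motif, self.second_motif):
            _check_motif(motif)
        for chrom, frags in self.fragments.items():
            for i, f in enumerate(frags):
                if f.index != i:
                    raise ValueError(
                        f"{chrom}: fragment indices must be consecutive from 0"
                    )
        self._starts = {
            chrom: [f.start for f in frags] for chrom, frags in self.fragments.items()
        }

    def __iter__(self) -> Iterator[RestrictionFragment]:
        for frags in self.fragments.values():
            yield from frags

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom])
        return sum(len(v) for v in self.fragments.values())

    def locate(self, chrom: str, pos: int) -> int:
        """Index of the fragment containing ``pos`` (0-based), by bisection."""
        frags = self.fragments[chrom]  # KeyError on unknown chromosome
        if pos < 0 or pos >= frags[-1].end:
            raise IndexError(f"position {pos} out of range on {chrom}")
        return bisect.bisect_right(self._starts[chrom], pos) - 1

    def fragment_at(self, chrom: str, pos: int) -> RestrictionFragment:
        return self.fragments[chrom][self.locate(chrom, pos)]


def _check_motif(motif: str) -> None:
    if not motif:
        raise ValueError("restriction motif must be non-empty")
    if motif != motif.upper():
        raise ValueError("restriction motif must be upper-case")
    if set(motif) - _MOTIF_BASES:
        raise ValueError(f"motif {motif!r} may only contain A,C,G,T")


def _is_palindromic(motif: str) -> bool:
    return reverse_complement(motif) == motif


def find_motif_occurrences(seq: str, motif: str) -> List[int]:
    """Start positions of every (possibly overlapping) occurrence of ``motif``.

    For non-palindromic motifs the reverse strand is scanned as well;
    CATG and GATC are both palindromic, so forward scanning covers both
    strands.  N bases never match.
    """
    motifs = {motif}
    if not _is_palindromic(motif):
        motifs.add(reverse_complement(motif))
    hits: List[int] = []
    for m in motifs:
        i = seq.find(m)
        while i != -1:
            hits.append(i)
            i = seq.find(m, i + 1)
    hits.sort()
    return hits


def digest(
    genome: Genome, first_motif: str = "CATG", second_motif: str = "GATC"
) -> FragmentMap:
    """Cut each chromosome immediately before every ``first_motif`` occurrence.

    Fragment k spans [cut_k, cut_{k+1}) with cut_0 = 0 and the last end at
    the chromosome length, so fragments tile the chromosome exactly and
    every fragment with index > 0 begins with the motif.  Each fragment is
    flagged if it contains at least one occurrence of ``second_motif``.
    """
    _check_motif(first_motif)
    _check_motif(second_motif)
    fragments: Dict[str, List[RestrictionFragment]] = {}
    for chrom, seq in genome.sequences.items():
        cuts = [0] + [p for p in find_motif_occurrences(seq, first_motif) if p > 0]
        bounds = cuts + [len(seq)]
        frags = []
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            frag_seq = seq[s:e]
            frags.append(
                RestrictionFragment(
                    chrom=chrom,
                    start=s,
                    end=e,
                    index=i,
                    has_second_cutter=bool(
                        find_motif_occurrences(frag_seq, second_motif)
                    ),
                )
            )
        fragments[chrom] = frags
    return FragmentMap(
        first_motif=first_motif, second_motif=second_motif, fragments=fragments
    )


def write_fragments(fmap: FragmentMap, path) -> None:
    """BED6: chrom, start, end, name=index, score=has_second_cutter (0/1), strand=+."""
    with open(path, "w") as fh:
        for frag in fmap:
            fh.write(
                f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.index}\t"
                f"{int(frag.has_second_cutter)}\t+\n"
            )


def read_fragments(
    path, first_motif: str = "CATG", second_motif: str = "GATC"
) -> FragmentMap:
    fragments: Dict[str, List[RestrictionFragment]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {line_no}: expected >=5 BED columns")
            chrom, start, end, index, score = parts[:5]
            frag = RestrictionFragment(
                chrom=chrom,
                start=int(start),
                end=int(end),
                index=int(index),
                has_second_cutter=bool(int(score)),
            )
            frags = fragments.setdefault(chrom, [])
            if frags:
                prev = frags[-1]
                if frag.start < prev.end:
                    raise ValueError(
                        f"line {line_no}: unsorted or overlapping intervals"
                    )
            frags.append(frag)
    return FragmentMap(
        first_motif=first_motif, second_motif=second_motif, fragments=fragments
    )
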