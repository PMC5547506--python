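"""Engineered-allele genomes and wild-type coordinate liftover.

Builds mutant genomes for single deletion or inversion alleles (exact
half-open breakpoints; loxP scars are far below fragment resolution and
not modeled) and provides the deterministic bijection between mutant and
wild-type coordinate frames, including projection of fragment profiles
computed on the mutant genome back onto the wild-type axis, where deleted
intervals carry a no-data marker and inverted intervals appear reflected
with flipped orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragmap import Genome, reverse_complement
from .quant4c import FragmentProfile


@dataclass(frozen=True)
class RearrangementSpec:
    name: str
    kind: str  # "deletion" | "inversion"
    chrom: str
    start: int  # wild-type coordinates, 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "inversion"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError("start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RearrangementSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CoordinateMap:
    """Bijection between wild-type and mutant positions of one chromosome.

    ``forward`` maps wild-type -> mutant (None for deleted positions);
    ``backward`` maps mutant -> (wild-type, orientation_flipped).
    """

    spec: RearrangementSpec
    wt_length: int

    @property
    def mutant_length(self) -> int:
        if self.spec.kind == "deletion":
            return self.wt_length - self.spec.length
        return self.wt_length

    def forward(self, pos: int) -> Optional[int]:
        if not 0 <= pos < self.wt_length:
            raise IndexError(f"wild-type position {pos} out of range")
        s, e = self.spec.start, self.spec.end
        if self.spec.kind == "deletion":
            if pos < s:
                return pos
            if pos < e:
                return None
            return pos - self.spec.length
        if s <= pos < e:
            return s + e - 1 - pos
        return pos

    def backward(self, pos: int) -> Tuple[int, bool]:
        if not 0 <= pos < self.mutant_length:
            raise IndexError(f"mutant position {pos} out of range")
        s, e = self.spec.start, self.spec.end
        if self.spec.kind == "deletion":
            if pos < s:
                return pos, False
            return pos + self.spec.length, False
        if s <= pos < e:
            return s + e - 1 - pos, True
        return pos, False

    def backward_interval(self, start: int, end: int) -> List[Tuple[int, int, bool]]:
        """Map a half-open mutant interval to wild-type intervals.

        The interval is split at rearrangement breakpoints; each piece maps
        to one contiguous wild-type interval with an orientation flag.
        """
        cuts = sorted(
            {start, end}
            | {
                p
                for p in (self.spec.start, self.spec.end)
                if start < p < end and p < self.mutant_length
            }
        )
        # deletions have a single breakpoint on the mutant axis, at spec.start
        if self.spec.kind == "deletion":
            cuts = sorted(
                {start, end} | ({self.spec.start} if start < self.spec.start < end else set())
            )
        out = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            wa, fa = self.backward(a)
            wb, _ = self.backward(b - 1)
            if fa:
                out.append((wb, wa + 1, True))
            else:
                out.append((wa, wb + 1, False))
        return out


def apply_rearrangement(
    genome: Genome, spec: RearrangementSpec
) -> Tuple[Genome, CoordinateMap]:
    """Mutant genome plus the coordinate bijection for one allele."""
    seq = genome[spec.chrom]
    if not 0 <= spec.start < spec.end <= len(seq):
        raise ValueError(
            f"interval {spec.start}-{spec.end} out of bounds on {spec.chrom}"
        )
    if spec.kind == "deletion":
        mutant_seq = seq[: spec.start] + seq[spec.end :]
    else:
        mutant_seq = (
            seq[: spec.start]
            + reverse_complement(seq[spec.start : spec.end])
            + seq[spec.end :]
        )
    sequences = dict(genome.sequences)
    sequences[spec.chrom] = mutant_seq
    mutant = Genome(
        sequences=sequences,
        assembly_label=f"{genome.assembly_label}+{spec.name}".strip("+"),
    )
    return mutant, CoordinateMap(spec=spec, wt_length=len(seq))


def apply_rearrangements(
    genome: Genome, specs: Sequence[RearrangementSpec]
) -> Genome:
    """Apply multiple edits given in wild-type coordinates.

    Specs must be pairwise disjoint (nested or overlapping edits are
    rejected); edits are applied right-to-left so earlier coordinates are
    unaffected, making the result independent of the input order.
    """
    by_chrom: dict = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        ss.sort(key=lambda s: s.start)
        for a, b in zip(ss[:-1], ss[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping rearrangements {a.name!r} and {b.name!r}"
                )
    result = genome
    for chrom, ss in by_chrom.items():
        for s in sorted(ss, key=lambda s: s.start, reverse=True):
            result, _ = apply_rearrangement(result, s)
    return result


def lift_profile(mutant_profile: FragmentProfile, cmap: CoordinateMap) -> pd.DataFrame:
    """Project a mutant-frame fragment profile onto the wild-type axis.

    Each mutant fragment interval is mapped through ``backward`` (split at
    breakpoints when it spans one); scores are unchanged and carried with
    the source fragment index.  The deleted wild-type interval, if any, is
    appended as a row with NaN score (no-data marker).  Rows are sorted by
    wild-type start.
    """
    chrom = mutant_profile.viewpoint.chrom
    if chrom != cmap.spec.chrom:
        raise ValueError("profile chromosome does not match the rearrangement")
    frags = mutant_profile.fragment_map.fragments[chrom]
    if frags[-1].end != cmap.mutant_length:
        raise ValueError("profile fragment map does not match the mutant genome")
    rows = []
    for frag, score in zip(frags, mutant_profile.scores):
        for wt_start, wt_end, flipped in cmap.backward_interval(frag.start, frag.end):
            rows.append(
                dict(
                    chrom=chrom,
                    wt_start=wt_start,
                    wt_end=wt_end,
                    score=score,
                    flipped=flipped,
                    fragment_index=frag.index,
                )
            )
    if cmap.spec.kind == "deletion":
        rows.append(
            dict(
                chrom=chrom,
                wt_start=cmap.spec.start,
                wt_end=cmap.spec.end,
                score=np.nan,
                flipped=False,
                fragment_index=-1,
            )
        )
    df = pd.DataFrame(rows).sort_values(["wt_start", "wt_end"], ignore_index=True)
    return df


def lift_strand(strand: str, flipped: bool) -> str:
    if not flipped:
        return strand
    return "-" if strand == "+" else "+"


def write_chain(cmap: CoordinateMap, path) -> None:
    """Chain-like TSV of collinear blocks:
    wt_start, wt_end, mut_start, mut_end, orientation."""
    s, e, L = cmap.spec.start, cmap.spec.end, cmap.wt_length
    if cmap.spec.kind == "deletion":
        blocks = [(0, s, 0, s, "+"), (e, L, s, s + (L - e), "+")]
    else:
        blocks = [(0, s, 0, s, "+"), (s, e, s, e, "-"), (e, L, e, L, "+")]
    with open(path, "w") as fh:
        fh.write("wt_start\twt_end\tmut_start\tmut_end\torientation\n")
        for b in blocks:
            if b[0] == b[1]:
                continue
            fh.write("\t".join(str(x) for x in b) + "\n")
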