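"""Exact-match genome index (seed-and-verify).

Maps captured 4C sequences and split-read segments back to the genome by
exact substring search on both strands.  A 2-bit encoded k-mer seed table
(sorted uint64 codes + argsort positions, numpy searchsorted lookups) finds
candidate loci in O(log n); candidates are verified by direct string
comparison, so hits are exact and *all* occurrences are enumerated —
required for the unique-mapping rule, where 0 or >=2 occurrences mean the
query is discarded.

Queries shorter than the seed length are handled by a linear scan; queries
containing N never match (N breaks 2-bit encoding and never pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fragmap import Genome, reverse_complement

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

SEED_LEN = 16


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


class _ChromIndex:
    def __init__(self, seq: str, k: int = SEED_LEN):
        self.seq = seq
        self.k = k
        arr = _encode(seq)
        n = len(seq) - k + 1
        if n <= 0:
            self.codes = np.empty(0, dtype=np.uint64)
            self.order = np.empty(0, dtype=np.int64)
            return
        codes = np.zeros(n, dtype=np.uint64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            col = arr[j : j + n]
            codes = codes * np.uint64(4) + np.where(col == 255, 0, col).astype(
                np.uint64
            )
            valid &= col != 255
        # k-mers containing N get a sentinel above any valid 2k-bit code
        codes = np.where(valid, codes, np.uint64(1) << np.uint64(2 * k))
        self.order = np.argsort(codes, kind="stable")
        self.codes = codes[self.order]

    def find_all(self, query: str) -> List[int]:
        """All start positions of exact occurrences of ``query`` (forward)."""
        k = self.k
        if len(query) < k:
            hits, i = [], self.seq.find(query)
            while i != -1:
                hits.append(i)
                i = self.seq.find(query, i + 1)
            return hits
        enc = _encode(query[:k])
        if (enc == 255).any():
            return []
        code = np.uint64(0)
        for v in enc:
            code = code * np.uint64(4) + np.uint64(v)
        lo = int(np.searchsorted(self.codes, code, side="left"))
        hi = int(np.searchsorted(self.codes, code, side="right"))
        hits = [
            int(p)
            for p in self.order[lo:hi]
            if self.seq[p : p + len(query)] == query
        ]
        hits.sort()
        return hits


@dataclass(frozen=True)
class MatchHit:
    chrom: str
    pos: int  # leftmost 0-based coordinate of the genomic match
    strand: str  # '+' if the query matched forward, '-' if its reverse complement


class GenomeIndex:
    """Both-strand exact matcher over all chromosomes of a genome."""

    def __init__(self, genome: Genome, k: int = SEED_LEN):
        self.genome = genome
        self._idx: Dict[str, _ChromIndex] = {
            chrom: _ChromIndex(seq, k) for chrom, seq in genome.sequences.items()
        }

    def find_all(self, query: str) -> List[MatchHit]:
        """Every occurrence of ``query`` on either strand, genome-wide.

        A palindromic query is reported once per locus (forward only).
        """
        rc = reverse_complement(query)
        hits: List[MatchHit] = []
        for chrom, idx in self._idx.items():
            for p in idx.find_all(query):
                hits.append(MatchHit(chrom, p, "+"))
            if rc != query:
                for p in idx.find_all(rc):
                    hits.append(MatchHit(chrom, p, "-"))
        return hits

    def find_unique(self, query: str) -> Optional[MatchHit]:
        """The hit if ``query`` occurs exactly once on one strand, else None."""
        hits = self.find_all(query)
        if len(hits) == 1:
            return hits[0]
        return None
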