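"""Sequencing-read container and FASTQ (Sanger encoding) I/O."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    qualities: tuple  # per-base phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence and qualities lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, stop: int | None = None) -> "RawRead":
        return RawRead(
            self.id, self.sequence[start:stop], self.qualities[start:stop]
        )


def write_fastq(reads: Iterable[RawRead], path) -> None:
    records = (
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description="",
            letter_annotations={"phred_quality": list(r.qualities)},
        )
        for r in reads
    )
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> List[RawRead]:
    return [
        RawRead(
            rec.id,
            str(rec.seq),
            tuple(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]
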