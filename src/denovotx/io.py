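"""Readers and writers for the plain-text formats used across the pipeline.

BED/BED12 and the gapped-FASTA alignment pairs are the only formats with
any parsing subtlety; everything tabular goes through pandas and trees
through dendropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from denovotx.orf_screen import CodonAlignmentPair

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "BedRecord",
    "read_bed",
    "write_bed",
    "read_alignment_pair",
    "write_alignment_pair",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
]


@dataclass(frozen=True)
class BedRecord:
    """A BED6/BED12 feature; ``blocks`` holds exon intervals in genome
    coordinates (0-based, half-open) for BED12 records, otherwise the
    whole span."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    blocks: Tuple[Tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end <= start")
        if not self.blocks:
            object.__setattr__(self, "blocks", ((self.start, self.end),))

    @property
    def exons(self) -> Tuple[Tuple[int, int], ...]:
        return self.blocks

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.start if self.strand != "-" else self.end


def _parse_bed_line(line: str) -> Optional[BedRecord]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError("fewer than 3 columns")
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else "."
    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    strand = fields[5] if len(fields) > 5 else "."
    blocks: Tuple[Tuple[int, int], ...] = ()
    if len(fields) >= 12:
        count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != count or len(starts) != count:
            raise ValueError("block count mismatch")
        blocks = tuple(
            (start + off, start + off + size)
            for off, size in zip(starts, sizes)
        )
    return BedRecord(chrom, start, end, name, score, strand, blocks)


def read_bed(path: PathLike) -> List[BedRecord]:
    """Parse BED/BED12; malformed rows are logged and skipped."""
    records: List[BedRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                record = _parse_bed_line(line)
            except (ValueError, IndexError) as exc:
                logger.warning("%s:%d: malformed BED row (%s)", path, lineno, exc)
                continue
            if record is not None:
                records.append(record)
    return records


def write_bed(records: Iterable[BedRecord], path: PathLike) -> None:
    with open(path, "w") as handle:
        for r in records:
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - r.start) for s, _ in r.blocks)
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom, r.start, r.end, r.name, r.score, r.strand,
                        r.start, r.end, "0", len(r.blocks), sizes, starts,
                    )
                )
                + "\n"
            )


def write_alignment_pair(aln: CodonAlignmentPair, path: PathLike) -> None:
    """Write a two-record gapped FASTA (focal first, out-group second)."""
    records = [
        SeqRecord(Seq(aln.focal_seq), id=aln.focal_id, description="focal"),
        SeqRecord(
            Seq(aln.outgroup_seq),
            id=aln.outgroup_species,
            description="outgroup",
        ),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_pair(path: PathLike) -> CodonAlignmentPair:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, got {len(records)}")
    focal, outgroup = records
    return CodonAlignmentPair(
        focal_id=focal.id,
        outgroup_species=outgroup.id,
        focal_seq=str(focal.seq),
        outgroup_seq=str(outgroup.seq),
    )


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()),
        str(path),
        "fasta",
    )


def read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(frame: pd.DataFrame, path: PathLike, **kwargs) -> None:
    frame.to_csv(path, sep="\t", **kwargs)
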