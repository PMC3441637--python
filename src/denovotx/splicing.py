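"""Splice-junction support classification and splice-site motifs.

A junction is *supported* when spanning reads exist, or — useful for
strand-non-specific public data — when both flanking exonic windows are
covered and the intron carries canonical GT-AG termini.  Junctions whose
flanks lack coverage cannot be assessed at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "JunctionRecord",
    "CoordinateMap",
    "classify_junction",
    "map_junction",
    "junction_motif_matrix",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class JunctionRecord:
    """One intron, half-open on the intron, with its read support."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    spanning_reads: int = 0
    donor_flank_cov: int = 0
    acceptor_flank_cov: int = 0
    dinucleotides: Optional[Tuple[str, str]] = None  # (first2, last2)

    def __post_init__(self) -> None:
        if not (self.intron_end > self.intron_start >= 0):
            raise ValueError("require intron_end > intron_start >= 0")
        if min(self.spanning_reads, self.donor_flank_cov, self.acceptor_flank_cov) < 0:
            raise ValueError("negative read counts")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def with_dinucleotides(self, genome: Mapping[str, str]) -> "JunctionRecord":
        """Fill ``dinucleotides`` from genomic sequence (transcript strand)."""
        seq = genome[self.chrom]
        first2 = seq[self.intron_start : self.intron_start + 2].upper()
        last2 = seq[self.intron_end - 2 : self.intron_end].upper()
        if self.strand == "-":
            first2, last2 = _revcomp(last2), _revcomp(first2)
        return replace(self, dinucleotides=(first2, last2))


def classify_junction(
    j: JunctionRecord,
    min_flank_reads: int = 1,
    min_span_reads: int = 1,
) -> str:
    """Classify one junction's support level.

    ``insufficient_coverage`` when either exonic flank is below
    ``min_flank_reads``; otherwise ``supported`` when spanning reads
    reach ``min_span_reads`` or the flanks are covered and the intron is
    canonical GT-AG; else ``assessable_unsupported``.
    """
    if (
        j.donor_flank_cov < min_flank_reads
        or j.acceptor_flank_cov < min_flank_reads
    ):
        return "insufficient_coverage"
    if j.spanning_reads >= min_span_reads:
        return "supported"
    if j.dinucleotides == ("GT", "AG"):
        return "supported"
    return "assessable_unsupported"


class CoordinateMap:
    """A piecewise-colinear interval map between two genomes.

    Blocks are tuples ``(src_chrom, src_start, src_end, tgt_chrom,
    tgt_start, tgt_end)`` with equal lengths; points map additively
    within a block and fall in a gap otherwise.
    """

    def __init__(self, blocks: Sequence[Tuple[str, int, int, str, int, int]]):
        for b in blocks:
            if b[2] - b[1] != b[5] - b[4]:
                raise ValueError(f"block source/target lengths differ: {b}")
        self.blocks = sorted(blocks, key=lambda b: (b[0], b[1]))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoordinateMap":
        cols = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end"]
        return cls([tuple(row) for row in frame[cols].itertuples(index=False)])

    def map_point(self, chrom: str, pos: int) -> Optional[Tuple[str, int]]:
        for sc, ss, se, tc, ts, _te in self.blocks:
            if sc == chrom and ss <= pos < se:
                return tc, ts + (pos - ss)
        return None

    def inverse(self) -> "CoordinateMap":
        return CoordinateMap(
            [(tc, ts, te, sc, ss, se) for sc, ss, se, tc, ts, te in self.blocks]
        )


def map_junction(
    j: JunctionRecord, coordinate_map: CoordinateMap
) -> Union[JunctionRecord, str]:
    """Project a junction into a target genome; ``"unmapped"`` on any gap
    or order inversion.  Read-support fields are zeroed: support in the
    target species must be measured there."""
    start = coordinate_map.map_point(j.chrom, j.intron_start)
    # half-open end: map the last intron base, then re-extend
    end_base = coordinate_map.map_point(j.chrom, j.intron_end - 1)
    if start is None or end_base is None:
        return "unmapped"
    (sc, sp), (ec, ep) = start, end_base
    if sc != ec or ep < sp:
        return "unmapped"
    return JunctionRecord(
        chrom=sc,
        intron_start=sp,
        intron_end=ep + 1,
        strand=j.strand,
    )


def junction_motif_matrix(
    junctions: Iterable[JunctionRecord],
    genome: Mapping[str, str],
    donor_window: Tuple[int, int] = (-3, 6),
    acceptor_window: Tuple[int, int] = (-6, 3),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Position-frequency matrices around donor and acceptor sites.

    Windows are intron-relative: donor offset +1 is the first intron
    base, -1 the last exonic base; acceptor offset -1 is the last intron
    base, +1 the first exonic base.  Minus-strand junctions are
    reverse-complemented, so canonical introns always show GT at donor
    +1/+2 and AG at acceptor -2/-1.  ``N`` bases are dropped from the
    affected column's denominator; columns sum to 1 where defined.
    """
    donor_offsets = [o for o in range(donor_window[0], donor_window[1] + 1) if o != 0]
    acceptor_offsets = [
        o for o in range(acceptor_window[0], acceptor_window[1] + 1) if o != 0
    ]
    bases = ["A", "C", "G", "T"]
    donor_counts = np.zeros((4, len(donor_offsets)))
    acceptor_counts = np.zeros((4, len(acceptor_offsets)))
    n_junctions = 0

    for j in junctions:
        n_junctions += 1
        seq = genome[j.chrom].upper()

        def base_at(pos: int) -> str:
            if 0 <= pos < len(seq):
                return seq[pos]
            raise IndexError(
                f"window position {pos} outside sequence {j.chrom}"
            )

        for offsets, counts, site in (
            (donor_offsets, donor_counts, "donor"),
            (acceptor_offsets, acceptor_counts, "acceptor"),
        ):
            if j.strand == "+":
                anchor = j.intron_start if site == "donor" else j.intron_end
            else:
                anchor = j.intron_end if site == "donor" else j.intron_start
            for col, off in enumerate(offsets):
                if j.strand == "+":
                    # anchors sit between exon and intron; offsets skip 0
                    pos = anchor + (off - 1 if off > 0 else off)
                    base = base_at(pos)
                else:
                    pos = anchor - (off if off > 0 else off + 1)
                    base = _revcomp(base_at(pos))
                if base in bases:
                    counts[bases.index(base), col] += 1

    if n_junctions == 0:
        raise ValueError("no junctions supplied")

    def to_frame(counts: np.ndarray, offsets: List[int]) -> pd.DataFrame:
        frame = pd.DataFrame(counts, index=bases, columns=[f"{o:+d}" for o in offsets])
        sums = frame.sum(axis=0)
        return frame.div(sums.where(sums > 0))

    return to_frame(donor_counts, donor_offsets), to_frame(acceptor_counts, acceptor_offsets)
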