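"""Per-gene, per-tissue transcription quantification and calling.

Expression is measured as RPKM over *representative regions* — the
exonic intervals of a gene that overlap no other annotated gene on
either strand, so that signal is attributable even for loci embedded in
dense transcriptional neighborhoods.  Transcription calls combine a hard
RPKM cutoff with an empirical Monte-Carlo background built from
intergenic regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from denovotx import intervals as iv
from denovotx.io import BedRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RepresentativeRegion",
    "ExpressionMatrix",
    "QcReport",
    "IntergenicBackground",
    "select_representative_regions",
    "compute_rpkm",
    "intergenic_background",
    "call_transcription",
    "tissue_proportions",
    "density_profile",
    "classify_context",
    "qc_summary",
]


@dataclass(frozen=True)
class RepresentativeRegion:
    gene: str
    intervals: Tuple[Tuple[str, int, int], ...]
    syntenic: Optional[Dict[str, Tuple[Tuple[str, int, int], ...]]] = None

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    @property
    def quantifiable(self) -> bool:
        return self.total_length > 0


@dataclass
class ExpressionMatrix:
    """Genes x tissues RPKM for one species, with the count-side inputs
    needed to recompute it."""

    species: str
    rpkm: pd.DataFrame  # genes x tissues
    library_sizes: pd.Series  # per tissue, mapped reads
    region_lengths: pd.Series  # per gene, bp
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("negative RPKM")
        missing = set(self.rpkm.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for tissues: {missing}")

    @property
    def genes(self) -> List[str]:
        return list(self.rpkm.index)

    @property
    def tissues(self) -> List[str]:
        return list(self.rpkm.columns)


@dataclass(frozen=True)
class QcReport:
    strand_ratio: Dict[str, float]  # per tissue, correct : mislabeled
    region_densities: Dict[str, float]  # exon / intron / intergenic means
    mean_errors_per_read: float
    flags: Tuple[str, ...] = ()


def select_representative_regions(
    gene_model: BedRecord,
    other_genes: Sequence[BedRecord],
    synteny_map: Optional[Mapping[str, Sequence[Tuple[str, int, int]]]] = None,
) -> RepresentativeRegion:
    """Exonic intervals of ``gene_model`` minus every other gene's span.

    Subtraction is strand-agnostic: anti-sense overlap disqualifies a
    region just as sense overlap does.  With a ``synteny_map`` (species
    -> mapped intervals on the same coordinate system), exonic intervals
    lacking a syntenic image in any species are removed too.
    """
    exons = [(s, e) for s, e in gene_model.exons]
    others = [
        (o.start, o.end)
        for o in other_genes
        if o.chrom == gene_model.chrom and o.name != gene_model.name
    ]
    kept = iv.subtract(exons, others)
    if synteny_map is not None:
        for species, mapped in synteny_map.items():
            image = [
                (s, e) for chrom, s, e in mapped if chrom == gene_model.chrom
            ]
            kept = [
                (s, e)
                for s, e in kept
                if any(ms <= s and e <= me for ms, me in iv.merge(image))
            ]
    if not kept:
        logger.info(
            "gene %s has no representative region (un-quantifiable)",
            gene_model.name,
        )
    return RepresentativeRegion(
        gene=gene_model.name,
        intervals=tuple((gene_model.chrom, s, e) for s, e in kept),
    )


def compute_rpkm(count: float, region_length: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / (region_length / 1_000) / (library_size / 1_000_000)


class IntergenicBackground:
    """Empirical null distribution of RPKM in intergenic regions.

    ``p_value`` uses the finite-sample (1 + k) / (1 + n) estimator and
    therefore never returns exactly zero.
    """

    def __init__(self, rpkm_values: np.ndarray) -> None:
        self.values = np.sort(np.asarray(rpkm_values, dtype=float))
        if self.values.size == 0:
            raise ValueError("empty background")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def p_value(self, rpkm: float) -> float:
        k = self.n - np.searchsorted(self.values, rpkm, side="left")
        return float((1 + k) / (1 + self.n))


def intergenic_background(
    region_lengths: Sequence[int],
    counts: Sequence[float],
    library_size: int,
    n: int = 10_000,
    seed: Optional[int] = None,
) -> IntergenicBackground:
    """Build the intergenic RPKM null from sampled regions.

    When fewer than ``n`` regions are supplied they are resampled with
    replacement up to ``n``; at least 100 distinct regions are required.
    """
    if len(region_lengths) != len(counts):
        raise ValueError("lengths and counts differ in size")
    if len(region_lengths) < 100:
        raise ValueError("need >= 100 intergenic regions")
    rpkms = np.array(
        [
            compute_rpkm(c, l, library_size)
            for c, l in zip(counts, region_lengths)
        ]
    )
    if rpkms.size < n:
        rng = np.random.default_rng(seed)
        rpkms = rng.choice(rpkms, size=n, replace=True)
    return IntergenicBackground(rpkms)


def call_transcription(
    rpkm: float,
    background: IntergenicBackground,
    rpkm_cutoff: float = 0.2,
    alpha: float = 0.05,
) -> bool:
    """Transcribed iff above the hard cutoff AND above background."""
    return rpkm > rpkm_cutoff and background.p_value(rpkm) < alpha


def tissue_proportions(rpkm_vector: Sequence[float]) -> Optional[np.ndarray]:
    """Per-tissue share of a gene's total expression; None if all-zero."""
    vec = np.asarray(rpkm_vector, dtype=float)
    if vec.size < 2:
        raise ValueError("need >= 2 tissues")
    if (vec < 0).any():
        raise ValueError("negative RPKM")
    total = vec.sum()
    if total == 0:
        logger.info("all-zero expression vector; gene excluded from profiles")
        return None
    return vec / total


def density_profile(
    coverage: Sequence[float],
    transcript_length: int,
    flank_fraction: float = 0.5,
    bins: int = 100,
) -> Optional[np.ndarray]:
    """Normalized read-density profile over flank + transcript + flank.

    ``coverage`` is per-base over the whole window, with each flank
    ``flank_fraction * transcript_length`` bases long.  The transcript is
    rescaled to ``bins`` bins and each flank to ``bins // 2``; per-bin
    mean coverages are normalized to sum to 1.  Returns None when the
    window carries no reads.
    """
    cov = np.asarray(coverage, dtype=float)
    flank = int(round(flank_fraction * transcript_length))
    if cov.size != transcript_length + 2 * flank:
        raise ValueError(
            f"coverage length {cov.size} != transcript {transcript_length} "
            f"+ 2 x flank {flank}"
        )
    if cov.sum() == 0:
        logger.info("zero total coverage; profile omitted")
        return None
    half = bins // 2
    parts = [
        (cov[:flank], half),
        (cov[flank : flank + transcript_length], bins),
        (cov[flank + transcript_length :], half),
    ]
    means: List[float] = []
    for segment, k in parts:
        for chunk in np.array_split(segment, k):
            means.append(chunk.mean() if chunk.size else 0.0)
    profile = np.array(means)
    return profile / profile.sum()


def classify_context(
    gene: BedRecord,
    annotations: Iterable[BedRecord],
    bidir_window: int = 1000,
) -> frozenset:
    """Multi-label genomic-context classes for a gene.

    Labels: ``same_strand_overlap`` and ``antisense_overlap`` from
    interval intersection by strand; ``bi`` when another gene's TSS lies
    within ``bidir_window`` bp upstream of the focal TSS on the opposite
    strand (divergent orientation); ``none`` when nothing applies.
    """
    labels: set = set()
    for other in annotations:
        if other.name == gene.name or other.chrom != gene.chrom:
            continue
        if iv.overlaps((gene.start, gene.end), (other.start, other.end)):
            if other.strand == gene.strand:
                labels.add("same_strand_overlap")
            else:
                labels.add("antisense_overlap")
        if other.strand != gene.strand:
            if gene.strand == "-":
                distance = other.tss - gene.tss
            else:
                distance = gene.tss - other.tss
            if 0 < distance <= bidir_window:
                labels.add("bi")
    return frozenset(labels) if labels else frozenset({"none"})


def qc_summary(
    strand_counts: Mapping[str, Tuple[int, int]],
    region_class_densities: Mapping[str, float],
    per_position_mismatches: Sequence[float],
    min_ratio: float = 100.0,
) -> QcReport:
    """Library QC: strand fidelity, exon enrichment, sequencing errors.

    ``strand_counts`` maps tissue -> (correct, mislabeled) read counts.
    Flags are raised when any strand ratio or the exon:intron density
    ratio drops to ``min_ratio`` or below; infinite ratios (zero
    denominator) pass without a flag.
    """
    flags: List[str] = []
    ratios: Dict[str, float] = {}
    for tissue, (correct, mislabeled) in strand_counts.items():
        if correct < 0 or mislabeled < 0:
            raise ValueError("negative strand counts")
        ratio = float("inf") if mislabeled == 0 else correct / mislabeled
        ratios[tissue] = ratio
        if ratio <= min_ratio:
            flags.append(f"strand ratio {ratio:.1f} <= {min_ratio:g} in {tissue}")
    exon = region_class_densities.get("exon", 0.0)
    intron = region_class_densities.get("intron", 0.0)
    if intron > 0 and exon / intron <= min_ratio:
        flags.append(f"exon:intron density ratio {exon / intron:.1f} <= {min_ratio:g}")
    return QcReport(
        strand_ratio=ratios,
        region_densities=dict(region_class_densities),
        mean_errors_per_read=float(np.sum(per_position_mismatches)),
        flags=tuple(flags),
    )
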