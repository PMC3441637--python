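"""Per-out-group ORF existence calls from pairwise codon alignments.

The focal coding sequence is aligned (gapped, codon-aware) against the
orthologous region of each out-group genome.  An alignment first passes a
reliability gate (coverage >= 0.70 and identity >= 0.50); reliable
alignments are scanned for *disablers* — premature stop codons read in
the focal frame, or gap runs whose length is not a multiple of three.  An
ORF is called absent in an out-group when at least one disabler exists
and the longest disabler-free stretch of the conceptual peptide falls
below 70% of the focal peptide length.  Disablers recurring at the same
focal codon in two or more out-groups mark the gene as a birth rather
than a loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "STOP_CODONS",
    "CodonAlignmentPair",
    "Disabler",
    "OrfCall",
    "SharedDisabler",
    "ParalogScreenResult",
    "assess_reliability",
    "detect_disablers",
    "call_orf_status",
    "shared_ancestral_disablers",
    "paralog_screen",
    "peptide_evidence",
    "protein_local_alignment",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

GAP = "-"


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Gapped pairwise alignment of a focal CDS against one out-group.

    The focal reading frame is anchored at the first focal (non-gap)
    position; the ungapped focal sequence must be a whole number of
    codons.  ``coverage`` and ``identity`` are derived properties, always
    recomputed from the sequences.
    """

    focal_id: str
    outgroup_species: str
    focal_seq: str
    outgroup_seq: str

    def __post_init__(self) -> None:
        if len(self.focal_seq) != len(self.outgroup_seq):
            raise ValueError(
                f"{self.focal_id}/{self.outgroup_species}: gapped lengths "
                f"differ ({len(self.focal_seq)} vs {len(self.outgroup_seq)})"
            )
        object.__setattr__(self, "focal_seq", self.focal_seq.upper())
        object.__setattr__(self, "outgroup_seq", self.outgroup_seq.upper())
        n = len(self.focal_ungapped)
        if n % 3 != 0:
            raise ValueError(
                f"{self.focal_id}: ungapped focal length {n} not divisible by 3"
            )
        if n == 0:
            raise ValueError(f"{self.focal_id}: empty focal sequence")

    @property
    def focal_ungapped(self) -> str:
        return self.focal_seq.replace(GAP, "")

    @property
    def n_codons(self) -> int:
        """Focal codon count including the terminal stop codon."""
        return len(self.focal_ungapped) // 3

    @property
    def coverage(self) -> float:
        """Fraction of focal CDS bases aligned to an out-group base."""
        aligned = sum(
            1
            for f, o in zip(self.focal_seq, self.outgroup_seq)
            if f != GAP and o != GAP
        )
        return aligned / len(self.focal_ungapped)

    @property
    def identity(self) -> float:
        """Matching fraction over columns where both sequences have bases."""
        aligned = matches = 0
        for f, o in zip(self.focal_seq, self.outgroup_seq):
            if f != GAP and o != GAP:
                aligned += 1
                if f == o:
                    matches += 1
        return matches / aligned if aligned else 0.0


@dataclass(frozen=True, order=True)
class Disabler:
    """A frame-disrupting lesion located at a focal codon.

    ``detail`` carries the stop triplet for premature stops and the indel
    length (in alignment columns) for frameshifts.
    """

    focal_codon: int  # 1-based; excludes the terminal stop codon
    kind: str  # "premature_stop" | "frameshift_indel"
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("premature_stop", "frameshift_indel"):
            raise ValueError(f"unknown disabler kind {self.kind!r}")
        if self.focal_codon < 1:
            raise ValueError("focal_codon is 1-based")


@dataclass(frozen=True)
class OrfCall:
    species: str
    status: str  # "present" | "absent" | "ambiguous"
    max_peptide_fraction: float = 1.0
    disablers: Tuple[Disabler, ...] = ()


@dataclass(frozen=True)
class SharedDisabler:
    focal_codon: int
    kind: str
    species: frozenset


@dataclass(frozen=True)
class ParalogScreenResult:
    passed: bool
    reason: str = ""


def assess_reliability(
    aln: CodonAlignmentPair,
    min_coverage: float = 0.70,
    min_identity: float = 0.50,
) -> str:
    """Gate an alignment; thresholds are inclusive (``>=``)."""
    if aln.coverage >= min_coverage and aln.identity >= min_identity:
        return "reliable"
    return "ambiguous"


def _gap_runs(seq: str, other: str) -> List[Tuple[int, int]]:
    """Maximal runs of columns gapped in ``seq`` but not in ``other``.

    Columns gapped in both sequences carry no sequence and are skipped;
    runs are reported left-to-right as (start_column, length).
    """
    runs: List[Tuple[int, int]] = []
    start = None
    length = 0
    for i, (a, b) in enumerate(zip(seq, other)):
        if a == GAP and b != GAP:
            if start is None:
                start = i
                length = 0
            length += 1
        else:
            if start is not None:
                runs.append((start, length))
                start = None
    if start is not None:
        runs.append((start, length))
    return runs


def detect_disablers(aln: CodonAlignmentPair) -> List[Disabler]:
    """Scan the out-group sequence in the focal reading frame.

    Premature stops are read per focal codon: the three out-group bases
    aligned to a focal codon's columns form an in-frame stop.  Reading
    codon-by-codon re-anchors the frame at every focal codon boundary, so
    a frameshift marks only its own position and does not cascade.  The
    focal terminal stop codon is excluded from the scan.
    """
    f, o = aln.focal_seq, aln.outgroup_seq
    n_codons = aln.n_codons
    last_peptide_codon = n_codons - 1  # terminal stop codon excluded

    # focal ungapped position for every column (position of the focal
    # base at that column; for focal-gap columns, bases consumed so far)
    disablers: List[Disabler] = []

    # --- frameshift indels: gap runs of length not divisible by 3 ---
    focal_before = [0] * (len(f) + 1)
    for i, c in enumerate(f):
        focal_before[i + 1] = focal_before[i] + (c != GAP)

    for start, length in _gap_runs(o, f):  # deletions in the out-group
        if length % 3 == 0:
            continue
        codon = focal_before[start] // 3 + 1  # column holds a focal base
        if codon <= last_peptide_codon:
            disablers.append(
                Disabler(codon, "frameshift_indel", detail=str(length))
            )
    for start, length in _gap_runs(f, o):  # insertions in the out-group
        if length % 3 == 0:
            continue
        codon = focal_before[start] // 3 + 1  # codon open at the insertion
        if codon <= last_peptide_codon:
            disablers.append(
                Disabler(codon, "frameshift_indel", detail=str(length))
            )

    # --- premature stops in the focal frame ---
    codon_cols: List[List[int]] = [[] for _ in range(n_codons)]
    pos = 0
    for i, c in enumerate(f):
        if c != GAP:
            codon_cols[pos // 3].append(i)
            pos += 1
    for codon_idx in range(last_peptide_codon):
        cols = codon_cols[codon_idx]
        triplet = "".join(o[i] for i in cols)
        if len(triplet) == 3 and GAP not in triplet and triplet in STOP_CODONS:
            disablers.append(
                Disabler(codon_idx + 1, "premature_stop", detail=triplet)
            )

    return sorted(disablers, key=lambda d: (d.focal_codon, d.kind))


def call_orf_status(
    aln: CodonAlignmentPair,
    disablers: Sequence[Disabler],
    max_fraction_threshold: float = 0.70,
    length_unit: str = "aa",
) -> OrfCall:
    """Call present/absent from the maximum continuous peptide rule.

    The fraction denominator is the focal peptide length in amino acids
    (codon count minus the terminal stop); ``length_unit="codons"`` uses
    the raw codon count instead.
    """
    if length_unit not in ("aa", "codons"):
        raise ValueError(f"unknown length_unit {length_unit!r}")
    n_codons = aln.n_codons
    n_peptide = n_codons - 1
    denominator = n_peptide if length_unit == "aa" else n_codons

    disabled = {d.focal_codon for d in disablers}
    longest = run = 0
    for codon in range(1, n_peptide + 1):
        if codon in disabled:
            run = 0
        else:
            run += 1
            longest = max(longest, run)
    fraction = longest / denominator if denominator else 0.0

    if disablers and fraction < max_fraction_threshold:
        status = "absent"
    else:
        status = "present"
    return OrfCall(
        species=aln.outgroup_species,
        status=status,
        max_peptide_fraction=fraction,
        disablers=tuple(sorted(disablers)),
    )


def shared_ancestral_disablers(
    calls: Iterable[OrfCall],
) -> List[SharedDisabler]:
    """Disablers of identical kind at the same focal codon in >= 2 species.

    An empty result flags the gene as birth-vs-loss unresolved.
    """
    by_site: Dict[Tuple[int, str], set] = {}
    for call in calls:
        for d in call.disablers:
            by_site.setdefault((d.focal_codon, d.kind), set()).add(call.species)
    shared = [
        SharedDisabler(codon, kind, frozenset(species))
        for (codon, kind), species in by_site.items()
        if len(species) >= 2
    ]
    return sorted(shared, key=lambda s: (s.focal_codon, s.kind))


# --- paralog screen -------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def protein_local_alignment(query: str, subject: str) -> Tuple[float, float]:
    """Local alignment of two proteins; returns (query coverage, identity)."""
    aligner = _protein_aligner()
    try:
        alignment = max(aligner.align(query, subject), key=lambda a: a.score)
    except ValueError:  # no alignment with positive score
        return 0.0, 0.0
    aligned_q = matches = columns = 0
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        aligned_q += qe - qs
        for qi, si in zip(range(qs, qe), range(ss, se)):
            columns += 1
            if query[qi] == subject[si]:
                matches += 1
    coverage = aligned_q / len(query) if query else 0.0
    identity = matches / columns if columns else 0.0
    return coverage, identity


def paralog_screen(
    focal_id: str,
    focal_protein: str,
    hit_rows: Iterable[Sequence],
    other_proteins: Optional[Mapping[str, str]] = None,
    evalue_cutoff: float = 1e-6,
    min_coverage: float = 0.70,
    min_identity: float = 0.50,
) -> ParalogScreenResult:
    """Reject candidates with detectable paralogs.

    ``hit_rows`` is a 12-column tabular homology-hit table (qid, sid,
    pident, length, mismatch, gapopen, qstart, qend, sstart, send,
    evalue, bitscore); malformed rows are skipped with a warning.  A
    secondary local-alignment check against ``other_proteins`` catches
    short proteins whose best hit has a large E-value.
    """
    for row in hit_rows:
        try:
            qid, sid = str(row[0]), str(row[1])
            evalue = float(row[10])
        except (IndexError, ValueError, TypeError):
            logger.warning("paralog_screen: skipping malformed hit row %r", row)
            continue
        if sid == focal_id:
            continue
        if evalue <= evalue_cutoff:
            return ParalogScreenResult(
                False, f"E-value {evalue:g} <= {evalue_cutoff:g} vs {sid}"
            )
    for name, protein in (other_proteins or {}).items():
        if name == focal_id:
            continue
        coverage, identity = protein_local_alignment(focal_protein, protein)
        if coverage >= min_coverage and identity >= min_identity:
            return ParalogScreenResult(
                False,
                f"aligns well with {name} "
                f"(coverage {coverage:.2f}, identity {identity:.2f})",
            )
    return ParalogScreenResult(True)


# --- peptide evidence -----------------------------------------------------

def _min_mismatches(peptide: str, text: str) -> int:
    """Minimum Hamming mismatches of ``peptide`` over windows of ``text``."""
    k = len(peptide)
    best = k
    for i in range(len(text) - k + 1):
        mism = sum(1 for a, b in zip(peptide, text[i : i + k]) if a != b)
        best = min(best, mism)
        if best == 0:
            break
    return best


def peptide_evidence(
    peptide: str,
    target_translation: str,
    decoy_translations: Iterable[str],
    min_second_best_mismatches: int = 2,
) -> str:
    """Accept a peptide only if it uniquely supports the target CDS.

    ``convincing`` requires an exact substring match in the target
    translation and >= 2 mismatches for the best match anywhere else in
    the proteome (or no other match at all).
    """
    peptide = peptide.upper()
    if len(peptide) < 6:
        raise ValueError("peptide shorter than 6 residues")
    if peptide not in target_translation.upper():
        return "rejected"
    best_other = None
    for decoy in decoy_translations:
        decoy = decoy.upper()
        if len(decoy) < len(peptide):
            continue
        mism = _min_mismatches(peptide, decoy)
        best_other = mism if best_other is None else min(best_other, mism)
        if best_other < min_second_best_mismatches:
            return "rejected"
    return "convincing"
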