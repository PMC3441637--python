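"""Ground-truthed simulators for every pipeline input.

Three generators cover the three evidence channels:

* :func:`simulate_orf_history` — an ORF born on a chosen branch of a
  species tree, with shared ancestral disablers injected into chosen
  out-group species at homologous codon positions.
* :func:`simulate_expression` — matched two-species genes x tissues
  expression with a tunable cross-species profile correlation (Gaussian
  copula on Dirichlet profiles) and a focal-side amplification factor;
  counts are negative-binomial and converted to RPKM exactly as the real
  pipeline would.
* :func:`simulate_junction_reads` — Poisson junction-spanning reads with
  a strand-mislabeling error channel and flank coverage tracks.

All randomness flows from one integer seed via deterministic
sub-streams, so fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from denovotx.expression import ExpressionMatrix, compute_rpkm
from denovotx.orf_screen import STOP_CODONS, CodonAlignmentPair
from denovotx.phylo import SpeciesTree
from denovotx.splicing import JunctionRecord

__all__ = [
    "SimTruth",
    "OrfHistory",
    "simulate_orf_history",
    "simulate_expression",
    "simulate_junction_reads",
]

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded next to every simulated dataset."""

    birth_branch: Optional[str] = None
    disabler_positions: Tuple[Tuple[frozenset, int, str], ...] = ()
    profile_correlation: Optional[float] = None
    amplification: Optional[float] = None
    dispersion: Optional[float] = None
    seed: Optional[int] = None
    # latent (noise-free) tissue-proportion matrices, focal then out-group
    latent_profiles: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.profile_correlation is not None and not (
            -1 <= self.profile_correlation <= 1
        ):
            raise ValueError("profile correlation outside [-1, 1]")
        if self.amplification is not None and self.amplification <= 0:
            raise ValueError("amplification must be positive")


@dataclass(frozen=True)
class OrfHistory:
    focal_species: str
    sequences: Dict[str, str]  # per species, ungapped
    alignments: Dict[str, CodonAlignmentPair]  # per out-group species
    truth: SimTruth


def _substream(seed: Optional[int], label: str) -> np.random.Generator:
    """Deterministic per-purpose RNG derived from the global seed.

    The sub-stream key is a stable digest of ``label`` (Python's builtin
    ``hash`` is salted per process and would break reproducibility).
    """
    key = zlib.crc32(label.encode())
    root = np.random.SeedSequence(seed)
    child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(key,))
    return np.random.default_rng(child)


def _random_orf(n_codons: int, rng: np.random.Generator) -> List[str]:
    body = [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    ]
    return ["ATG"] + body + ["TAA"]


def simulate_orf_history(
    tree: SpeciesTree,
    birth_branch: str,
    n_codons: int,
    shared_disablers: Sequence[Tuple[Sequence[str], int, str]] = (),
    seed: Optional[int] = None,
    focal_species: Optional[str] = None,
    disable_all_outgroups: bool = True,
) -> OrfHistory:
    """Simulate an ORF born on ``birth_branch`` with injected disablers.

    ``shared_disablers`` lists ``(species, focal_codon, kind)`` with kind
    ``premature_stop`` or ``frameshift_indel``; each named species must
    lie outside the birth clade and the codon strictly inside the
    peptide (not the start or terminal stop codon).  When
    ``disable_all_outgroups`` is set (the default), out-groups given no
    explicit disabler receive a private premature stop near mid-ORF so
    that, noise-free, the full screen recovers exactly ``birth_branch``.
    """
    if len(tree.leaves) < 3:
        raise ValueError("tree must have >= 3 leaves")
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if not tree.is_branch(birth_branch):
        raise ValueError(f"{birth_branch!r} is not a branch of the tree")
    clade = tree.clade_of(birth_branch)
    outgroups = tree.outgroups(clade)

    planned: List[Tuple[frozenset, int, str]] = []
    for species, codon, kind in shared_disablers:
        species = frozenset(species)
        if kind not in ("premature_stop", "frameshift_indel"):
            raise ValueError(f"unknown disabler kind {kind!r}")
        if not (2 <= codon <= n_codons - 1):
            raise ValueError(
                f"disabler codon {codon} out of range [2, {n_codons - 1}]"
            )
        inside = species & clade
        if inside:
            raise ValueError(
                f"disabler species {sorted(inside)} are inside the birth clade"
            )
        unknown = species - tree.leaves
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")
        planned.append((species, codon, kind))

    rng = _substream(seed, "orf_history")
    focal = focal_species or sorted(clade)[0]
    if focal not in clade:
        raise ValueError(f"focal species {focal!r} not in birth clade")

    codons = _random_orf(n_codons, rng)
    orf = "".join(codons)

    # per-out-group plan: {(codon, kind), ...}
    per_species: Dict[str, set] = {sp: set() for sp in outgroups}
    for species, codon, kind in planned:
        for sp in species:
            per_species[sp].add((codon, kind))
    truth_disablers = list(planned)
    if disable_all_outgroups:
        # every out-group must end up genuinely disabled: keep splitting
        # the longest disabler-free stretch until the maximum continuous
        # peptide falls below the screening threshold
        threshold = 0.70
        n_peptide = n_codons - 1
        for sp in sorted(outgroups):
            while True:
                disabled = sorted(c for c, _ in per_species[sp])
                bounds = [0] + disabled + [n_codons]
                runs = [
                    (bounds[i + 1] - bounds[i] - 1, bounds[i])
                    for i in range(len(bounds) - 1)
                ]
                longest, after = max(runs)
                if longest / n_peptide < threshold:
                    break
                codon = after + (longest + 1) // 2
                codon = min(max(codon, 2), n_codons - 1)
                per_species[sp].add((codon, "premature_stop"))
                truth_disablers.append(
                    (frozenset({sp}), codon, "premature_stop")
                )

    sequences: Dict[str, str] = {}
    alignments: Dict[str, CodonAlignmentPair] = {}
    for sp in sorted(tree.leaves):
        if sp in clade:
            sequences[sp] = orf
            if sp != focal:
                # in-group relatives share the intact ORF; emitting their
                # (trivial) alignments lets the screen call them present
                alignments[sp] = CodonAlignmentPair(
                    focal_id=focal,
                    outgroup_species=sp,
                    focal_seq=orf,
                    outgroup_seq=orf,
                )
            continue
        out_codons = list(codons)
        gapped = [list(c) for c in codons]  # alignment rows per codon
        for codon, kind in sorted(per_species[sp]):
            if kind == "premature_stop":
                stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
                out_codons[codon - 1] = stop
                gapped[codon - 1] = list(stop)
            else:  # 1-nt deletion inside the codon
                within = int(rng.integers(0, 3))
                old = out_codons[codon - 1]
                out_codons[codon - 1] = old[:within] + old[within + 1 :]
                row = list(old)
                row[within] = "-"
                gapped[codon - 1] = row
        sequences[sp] = "".join(out_codons)
        alignments[sp] = CodonAlignmentPair(
            focal_id=focal,
            outgroup_species=sp,
            focal_seq=orf,
            outgroup_seq="".join("".join(row) for row in gapped),
        )

    truth = SimTruth(
        birth_branch=birth_branch,
        disabler_positions=tuple(truth_disablers),
        seed=seed,
    )
    return OrfHistory(
        focal_species=focal,
        sequences=sequences,
        alignments=alignments,
        truth=truth,
    )


def _copula_correlation(rho: float) -> float:
    """Gaussian-copula latent correlation hitting Spearman ``rho``."""
    return 2 * np.sin(np.pi * rho / 6)


def simulate_expression(
    n_genes: int,
    tissues: Sequence[str],
    rho: float,
    lam: float,
    dispersion: float,
    library_sizes: Mapping[str, int],
    seed: Optional[int] = None,
    region_length: int = 1000,
    dirichlet_alpha: float = 0.8,
    mean_total_rpkm: float = 10.0,
    focal_species: str = "human",
    outgroup_species: str = "rhesus",
) -> Tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Two matched genes x tissues expression matrices.

    Per gene, latent tissue profiles are Dirichlet draws coupled across
    species through a Gaussian copula whose latent correlation is chosen
    so the expected Spearman correlation of the profiles is ``rho``.
    The focal species' expected total expression is ``lam`` times the
    out-group's.  Counts are negative-binomial with variance
    ``m + dispersion * m**2`` (Poisson in the ``dispersion -> 0`` limit)
    and converted to RPKM with the supplied library sizes.
    """
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    if not 0 <= rho <= 1:
        raise ValueError("rho outside [0, 1]")
    if lam < 1:
        raise ValueError("amplification must be >= 1")
    for tissue in tissues:
        if library_sizes[tissue] <= 0:
            raise ValueError(f"non-positive library size for {tissue}")

    rng = _substream(seed, "expression")
    n_t = len(tissues)
    r = _copula_correlation(rho)

    z1 = rng.standard_normal((n_genes, n_t))
    eps = rng.standard_normal((n_genes, n_t))
    z2 = r * z1 + np.sqrt(max(0.0, 1 - r * r)) * eps
    u1 = stats.norm.cdf(z1)
    u2 = stats.norm.cdf(z2)
    g1 = stats.gamma.ppf(u1, a=dirichlet_alpha)
    g2 = stats.gamma.ppf(u2, a=dirichlet_alpha)
    prop1 = g1 / g1.sum(axis=1, keepdims=True)
    prop2 = g2 / g2.sum(axis=1, keepdims=True)

    total_out = mean_total_rpkm * rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    total_focal = lam * total_out
    mean_rpkm_focal = total_focal[:, None] * prop1
    mean_rpkm_out = total_out[:, None] * prop2

    genes = [f"gene{i + 1:03d}" for i in range(n_genes)]
    lib = pd.Series({t: int(library_sizes[t]) for t in tissues})
    lengths = pd.Series(region_length, index=genes)

    def draw_counts(mean_rpkm: np.ndarray, stream: str) -> np.ndarray:
        sub = _substream(seed, stream)
        mean_counts = (
            mean_rpkm
            * (region_length / 1_000)
            * (lib.values[None, :] / 1_000_000)
        )
        if dispersion <= 1e-9:
            return sub.poisson(mean_counts).astype(float)
        size = 1.0 / dispersion  # NB shape: var = m + m^2 / size
        p = size / (size + mean_counts)
        return sub.negative_binomial(size, p).astype(float)

    matrices = []
    for species, mean_rpkm, stream in (
        (focal_species, mean_rpkm_focal, "counts_focal"),
        (outgroup_species, mean_rpkm_out, "counts_outgroup"),
    ):
        counts = draw_counts(mean_rpkm, stream)
        rpkm = np.array(
            [
                [
                    compute_rpkm(counts[i, j], region_length, lib.values[j])
                    for j in range(n_t)
                ]
                for i in range(n_genes)
            ]
        )
        matrices.append(
            ExpressionMatrix(
                species=species,
                rpkm=pd.DataFrame(rpkm, index=genes, columns=list(tissues)),
                library_sizes=lib.copy(),
                region_lengths=lengths.copy(),
                counts=pd.DataFrame(counts, index=genes, columns=list(tissues)),
            )
        )

    truth = SimTruth(
        profile_correlation=rho,
        amplification=lam,
        dispersion=dispersion,
        seed=seed,
        latent_profiles=(prop1, prop2),
    )
    return matrices[0], matrices[1], truth


def simulate_junction_reads(
    junctions: Sequence[JunctionRecord],
    depth: float,
    strand_error: float = 0.0,
    seed: Optional[int] = None,
    flank_width: int = 20,
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray]]:
    """Poisson spanning reads plus flank coverage for each junction.

    Each junction draws ``Poisson(depth)`` spanning reads whose strand
    label flips with probability ``strand_error``; donor/acceptor flank
    windows draw Poisson per-base coverage at the same depth.  Returns a
    per-junction table and per-junction coverage tracks (donor flank
    concatenated with acceptor flank).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= strand_error < 1:
        raise ValueError("strand_error outside [0, 1)")
    rng = _substream(seed, "junctions")
    rows = []
    tracks: Dict[str, np.ndarray] = {}
    for idx, j in enumerate(junctions):
        n_reads = int(rng.poisson(depth))
        flipped = int(rng.binomial(n_reads, strand_error)) if n_reads else 0
        donor_track = rng.poisson(depth, size=flank_width)
        acceptor_track = rng.poisson(depth, size=flank_width)
        name = f"{j.chrom}:{j.intron_start}-{j.intron_end}({j.strand})"
        tracks[name] = np.concatenate([donor_track, acceptor_track])
        rows.append(
            {
                "junction": name,
                "chrom": j.chrom,
                "intron_start": j.intron_start,
                "intron_end": j.intron_end,
                "strand": j.strand,
                "spanning_reads": n_reads,
                "correct_strand_reads": n_reads - flipped,
                "mislabeled_reads": flipped,
                "donor_flank_cov": int(donor_track.sum()),
                "acceptor_flank_cov": int(acceptor_track.sum()),
            }
        )
    return pd.DataFrame(rows), tracks
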