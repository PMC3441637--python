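"""Pooled Nei-Gojobori dN/dS over concatenated codon-alignment blocks.

Classical counting: per-codon synonymous/nonsynonymous site fractions,
pathway-averaged difference counts between codon pairs (all mutation
orders weighted equally, pathways through stop codons excluded), pooled
over every block before the ratio is formed, with Jukes-Cantor multiple-
hit correction applied to the pooled proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

__all__ = [
    "DnDsResult",
    "codon_sites",
    "pair_differences",
    "merged_dnds",
    "jukes_cantor",
]

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)


def _translate(codon: str) -> Optional[str]:
    """Amino acid for a codon, None for stops."""
    if codon in _STOPS:
        return None
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class DnDsResult:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def pS(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites else float("nan")

    @property
    def pN(self) -> float:
        return (
            self.nonsyn_diffs / self.nonsyn_sites
            if self.nonsyn_sites
            else float("nan")
        )

    @property
    def dS(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def dN(self) -> float:
        return jukes_cantor(self.pN)

    @property
    def ratio(self) -> Optional[float]:
        """dN/dS, or None when dS is zero or undefined."""
        dS, dN = self.dS, self.dN
        if not math.isfinite(dS) or dS == 0 or not math.isfinite(dN):
            return None
        return dN / dS


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -3/4 ln(1 - 4p/3); inf for p >= 3/4."""
    if math.isnan(p):
        return float("nan")
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1 - 4 * p / 3)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible point
    mutations that are synonymous; mutations creating a stop codon count
    as nonsynonymous.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no defined sites")
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mutant) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pair_differences(codon1: str, codon2: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    All orderings of the differing positions define mutational pathways;
    pathways that pass through a stop codon are excluded and the
    remainder weighted equally.  If every pathway hits a stop, all are
    used (degenerate corner, matching the classical implementations'
    fallback).
    """
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways: List[Tuple[float, float]] = []
    fallback: List[Tuple[float, float]] = []
    for order in itertools.permutations(diff_positions):
        current = codon1
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            mutant = current[:pos] + codon2[pos] + current[pos + 1 :]
            if mutant in _STOPS:
                through_stop = True
            if _translate(current) is not None and _translate(current) == _translate(mutant):
                syn += 1
            else:
                nonsyn += 1
            current = mutant
        fallback.append((syn, nonsyn))
        if not through_stop:
            pathways.append((syn, nonsyn))
    chosen = pathways or fallback
    syn = sum(s for s, _ in chosen) / len(chosen)
    nonsyn = sum(n for _, n in chosen) / len(chosen)
    return syn, nonsyn


def _clean_codon_pairs(
    seq1: str, seq2: str, block_index: int
) -> List[Tuple[str, str]]:
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError(f"block {block_index}: sequence lengths differ")
    if len(seq1) % 3 != 0:
        raise ValueError(f"block {block_index}: length not divisible by 3")
    pairs = []
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(b not in _BASES for b in c1 + c2):
            logger.info(
                "block %d codon %d skipped (gap/ambiguity)", block_index, i // 3 + 1
            )
            continue
        if c1 in _STOPS or c2 in _STOPS:
            logger.info("block %d codon %d skipped (stop)", block_index, i // 3 + 1)
            continue
        pairs.append((c1, c2))
    return pairs


def merged_dnds(blocks: Sequence[Tuple[str, str]]) -> DnDsResult:
    """Pooled Nei-Gojobori counting over concatenated alignment blocks.

    ``blocks`` is a sequence of (sequence1, sequence2) in-frame pairs;
    sites and differences are summed over all blocks before the
    Jukes-Cantor-corrected ratio is formed.
    """
    if not blocks:
        raise ValueError("no alignment blocks")
    syn_sites = nonsyn_sites = syn_diffs = nonsyn_diffs = 0.0
    n_codons = 0
    for idx, (seq1, seq2) in enumerate(blocks):
        for c1, c2 in _clean_codon_pairs(seq1, seq2, idx):
            s1 = codon_sites(c1)
            s2 = codon_sites(c2)
            syn_sites += (s1[0] + s2[0]) / 2
            nonsyn_sites += (s1[1] + s2[1]) / 2
            sd, nd = pair_differences(c1, c2)
            syn_diffs += sd
            nonsyn_diffs += nd
            n_codons += 1
    return DnDsResult(
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
        n_codons=n_codons,
    )
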