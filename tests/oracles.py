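"""Independent brute-force oracles used to validate the implementations.

Each oracle enumerates the underlying combinatorial object directly —
single-gain scenarios on a tree, mutational pathways between codons,
permutations of an ortholog pairing, hypergeometric tables — without
reusing any logic from the package modules it checks.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict, Tuple

import numpy as np
from Bio.Seq import Seq
from scipy import stats


# --- single-gain / zero-loss parsimony ------------------------------------

def dating_status_oracle(tree, states: Dict[str, str]) -> str:
    """Status by exhaustive enumeration of single-gain, zero-loss
    scenarios: a gain on a branch is valid iff every present leaf lies
    below it and no leaf below is unambiguously absent."""
    present = {sp for sp, s in states.items() if s == "present"}
    if not present:
        return "undatable"
    valid = [
        clade
        for clade in tree.clades
        if present <= clade
        and not any(states.get(leaf) == "absent" for leaf in clade)
    ]
    if not valid:
        return "contradictory"
    minimal = min(valid, key=len)
    outside = tree.leaves - minimal
    if not outside:
        return "dated"  # origin on the root branch; nothing older exists
    if any(states.get(leaf) == "absent" for leaf in outside):
        return "dated"
    return "undatable"  # only ambiguous out-groups: older origin possible


# --- Nei-Gojobori pathway counting ----------------------------------------

def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng_sites_oracle(codon: str) -> Tuple[float, float]:
    """Synonymous/nonsynonymous site counts by enumerating all nine
    single-base mutants; mutations to stops are nonsynonymous."""
    aa = _aa(codon)
    syn = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if _aa(mutant) != "*" and _aa(mutant) == aa:
            syn += 1 / 3
    return syn, 3.0 - syn


def ng_differences_oracle(c1: str, c2: str) -> Tuple[float, float]:
    """Pathway-averaged difference counts by explicit enumeration of all
    orderings of the differing positions, dropping stop-crossing paths."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    kept, everything = [], []
    for order in itertools.permutations(positions):
        codon = c1
        syn = nonsyn = 0
        hits_stop = False
        for pos in order:
            nxt = codon[:pos] + c2[pos] + codon[pos + 1 :]
            if _aa(nxt) == "*":
                hits_stop = True
            if _aa(nxt) != "*" and _aa(nxt) == _aa(codon):
                syn += 1
            else:
                nonsyn += 1
            codon = nxt
        everything.append((syn, nonsyn))
        if not hits_stop:
            kept.append((syn, nonsyn))
    chosen = kept or everything
    return (
        sum(s for s, _ in chosen) / len(chosen),
        sum(n for _, n in chosen) / len(chosen),
    )


# --- exhaustive ortholog-shuffle null -------------------------------------

def exhaustive_null_counts(focal: np.ndarray, outgroup: np.ndarray,
                           cutoff: float) -> Dict[int, float]:
    """Exact null distribution of the correlated-pair count over all n!
    permutations of the out-group rows; returns count -> probability."""
    n = focal.shape[0]
    tally: Dict[int, int] = {}
    for perm in itertools.permutations(range(n)):
        count = 0
        for i, j in enumerate(perm):
            x, y = focal[i], outgroup[j]
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            if stats.spearmanr(x, y).statistic > cutoff:
                count += 1
        tally[count] = tally.get(count, 0) + 1
    total = sum(tally.values())
    return {k: v / total for k, v in tally.items()}


# --- one-sided Fisher by hypergeometric enumeration -----------------------

def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c), summed
    term by term from binomial coefficients."""
    N, K, n = a + b + c + d, a + b, a + c
    total = comb(N, n)
    p = 0.0
    for x in range(a, min(K, n) + 1):
        if n - x <= N - K:
            p += comb(K, x) * comb(N - K, n - x) / total
    return p
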