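"""Origination-branch assignment by single-gain, zero-loss parsimony.

A locus or ORF is scored in every species as present, absent, or
ambiguous.  Its origination branch is the branch immediately above the
most recent common ancestor of all "present" leaves — provided no
descendant of that ancestor is scored absent (which would force a loss
and is reported as *contradictory*) and at least one out-group species is
unambiguously absent (otherwise an older origin cannot be excluded and
the profile is *undatable*).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional

from denovotx.phylo import SpeciesTree, branch_id

__all__ = [
    "State",
    "PresenceProfile",
    "AgeAssignment",
    "LineageClass",
    "assign_age",
    "classify_lineage",
]

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"

_STATES = {PRESENT, ABSENT, AMBIGUOUS}


class State(str, enum.Enum):
    PRESENT = PRESENT
    ABSENT = ABSENT
    AMBIGUOUS = AMBIGUOUS


@dataclass(frozen=True)
class PresenceProfile:
    """Per-species presence states for one locus or ORF.

    ``entity`` distinguishes locus-level from ORF-level profiles; the
    dating rule itself is identical for both.
    """

    entity: str  # "locus" | "orf"
    states: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity not in ("locus", "orf"):
            raise ValueError(f"unknown entity {self.entity!r}")
        bad = {s for s in self.states.values() if s not in _STATES}
        if bad:
            raise ValueError(f"unknown presence states: {sorted(bad)}")

    def species_with(self, state: str) -> frozenset:
        return frozenset(k for k, v in self.states.items() if v == state)


@dataclass(frozen=True)
class AgeAssignment:
    """Outcome of dating one presence profile.

    ``presence_support`` counts the informative (non-ambiguous) absent
    out-group species; a dated branch with support 1 rests on a single
    genome and can be filtered downstream.
    """

    branch: Optional[str]
    status: str  # "dated" | "contradictory" | "undatable"
    presence_support: int = 0

    def __post_init__(self) -> None:
        if (self.status == "dated") != (self.branch is not None):
            raise ValueError("status 'dated' iff branch is non-null")


class LineageClass(str, enum.Enum):
    CLASS_I = "ClassI"
    CLASS_II = "ClassII"
    OTHER = "other"
    REJECTED = "rejected"


def assign_age(tree: SpeciesTree, profile: PresenceProfile) -> AgeAssignment:
    """Date a presence profile on a rooted tree.

    Raises
    ------
    KeyError
        If the profile names a species absent from the tree.
    """
    unknown = set(profile.states) - set(tree.leaves)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")

    present = profile.species_with(PRESENT)
    if not present:
        return AgeAssignment(branch=None, status="undatable")

    clade = tree.mrca_clade(present)
    # a loss would be required if any leaf under the candidate origin
    # branch is unambiguously absent
    for leaf in clade:
        if profile.states.get(leaf, AMBIGUOUS) == ABSENT:
            return AgeAssignment(branch=None, status="contradictory")

    outgroups = tree.outgroups(clade)
    support = sum(
        1 for sp in outgroups if profile.states.get(sp, AMBIGUOUS) == ABSENT
    )
    if outgroups and support == 0:
        # every out-group is ambiguous: an older origin cannot be excluded
        return AgeAssignment(branch=None, status="undatable")
    return AgeAssignment(
        branch=branch_id(clade), status="dated", presence_support=support
    )


def classify_lineage(
    orf_age: AgeAssignment,
    locus_age: AgeAssignment,
    tree: SpeciesTree,
    focal_species: str = "human",
    sister_species: str = "chimp",
) -> LineageClass:
    """Bin a gene by where its ORF arose relative to the focal lineage.

    Class I: the ORF is restricted to the focal terminal branch.
    Class II: the ORF arose on the focal+sister ancestral branch.
    Any dated-but-elsewhere combination is ``other``; undated input or a
    locus younger than its ORF is ``rejected``.
    """
    if orf_age.status != "dated" or locus_age.status != "dated":
        return LineageClass.REJECTED
    orf_clade = tree.clade_of(orf_age.branch)
    locus_clade = tree.clade_of(locus_age.branch)
    if not orf_clade <= locus_clade:
        # an ORF cannot predate the transcribed locus that hosts it
        return LineageClass.REJECTED
    if orf_age.branch == branch_id({focal_species}):
        return LineageClass.CLASS_I
    pair = frozenset({focal_species, sister_species})
    if pair in tree.clades and orf_age.branch == branch_id(pair):
        return LineageClass.CLASS_II
    return LineageClass.OTHER
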