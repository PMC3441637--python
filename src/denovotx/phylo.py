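"""Rooted species trees with stable, leaf-set-derived branch identifiers.

Every branch of a rooted tree is named by the sorted, comma-joined set of
leaf labels below it (``"human"`` for a terminal branch,
``"chimp,human"`` for their ancestral branch).  These identifiers are
stable across serialization round-trips and independent of internal node
labels, which Newick files frequently omit.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable

import dendropy

__all__ = ["SpeciesTree", "branch_id"]


def branch_id(leaves: Iterable[str]) -> str:
    """Return the canonical branch identifier for a set of leaf labels."""
    return ",".join(sorted(leaves))


class SpeciesTree:
    """A rooted species tree exposing clade (branch) queries.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.  Leaf taxon labels must be unique
        and non-empty.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in species tree")
        if not labels:
            raise ValueError("species tree has no leaves")
        self._tree = tree
        self._leaves: FrozenSet[str] = frozenset(labels)
        # one clade per node == leaf set below the branch subtending it
        self._clades: set[FrozenSet[str]] = set()
        for node in tree.preorder_node_iter():
            clade = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            self._clades.add(clade)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    @property
    def leaves(self) -> FrozenSet[str]:
        return self._leaves

    @property
    def clades(self) -> set[FrozenSet[str]]:
        """All clades of the tree (each corresponds to one branch)."""
        return set(self._clades)

    @property
    def branch_ids(self) -> set[str]:
        return {branch_id(c) for c in self._clades}

    def is_branch(self, ident: str) -> bool:
        return frozenset(ident.split(",")) in self._clades

    def clade_of(self, ident: str) -> FrozenSet[str]:
        clade = frozenset(ident.split(","))
        if clade not in self._clades:
            raise KeyError(f"{ident!r} is not a branch of the tree")
        return clade

    def mrca_clade(self, leaves: Iterable[str]) -> FrozenSet[str]:
        """Smallest clade containing every leaf in ``leaves``."""
        target = frozenset(leaves)
        unknown = target - self._leaves
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if not target:
            raise ValueError("mrca of an empty leaf set is undefined")
        best = self._leaves
        for clade in self._clades:
            if target <= clade and len(clade) < len(best):
                best = clade
        return best

    def outgroups(self, clade: FrozenSet[str]) -> FrozenSet[str]:
        """Leaves outside ``clade``."""
        return self._leaves - clade

    def __contains__(self, species: str) -> bool:
        return species in self._leaves

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({sorted(self._leaves)})"
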