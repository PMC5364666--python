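"""Taxon trees: Newick reading, clade queries and leaf-to-leaf distances.

The tree orders the bridging walk: when a seed query fails in a distant
clade, orthologs from the phylogenetically nearest species that already
carry a hit are promoted as new queries.  Distances use branch lengths when
the Newick provides them and edge counts otherwise.
"""

from __future__ import annotations

import os
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import dendropy


class TreeConfigError(ValueError):
    """Raised when the tree does not cover the search universe."""


class TaxonTree:
    """A rooted species tree whose leaves are species tags.

    Internal node labels name clades; ``clade(label)`` returns the leaf set
    under that node.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._leaves: List[str] = [
            lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()
        ]
        if len(set(self._leaves)) != len(self._leaves):
            raise TreeConfigError("duplicate leaf labels in tree")
        self._dist: Optional[Dict[Tuple[str, str], float]] = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "TaxonTree":
        kwargs = dict(schema="newick", preserve_underscores=True)
        if is_path:
            tree = dendropy.Tree.get(path=str(source), **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        return cls(tree)

    # -- queries ----------------------------------------------------------
    @property
    def leaves(self) -> List[str]:
        return list(self._leaves)

    def clade(self, label: str) -> FrozenSet[str]:
        """Leaf set under the internal node (or leaf) named ``label``."""
        for node in self._tree.preorder_node_iter():
            node_label = node.label or (node.taxon.label if node.taxon else None)
            if node_label is not None and node_label.replace(" ", "_") == label:
                return frozenset(
                    lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter()
                )
        raise KeyError(f"no clade labeled {label!r} in tree")

    def clade_labels(self) -> List[str]:
        out = []
        for node in self._tree.preorder_internal_node_iter():
            if node.label:
                out.append(node.label.replace(" ", "_"))
        return out

    def validate_universe(self, species: Iterable[str]) -> None:
        """Every searched species must appear as exactly one leaf."""
        missing = sorted(set(species) - set(self._leaves))
        if missing:
            raise TreeConfigError(
                f"species missing from tree: {', '.join(missing)}"
            )

    # -- distances --------------------------------------------------------
    def _distance_table(self) -> Dict[Tuple[str, str], float]:
        if self._dist is None:
            has_lengths = all(
                e.length is not None
                for e in self._tree.preorder_edge_iter()
                if e.head_node.parent_node is not None
            )
            if not has_lengths:
                for e in self._tree.preorder_edge_iter():
                    e.length = 1.0
            pdm = self._tree.phylogenetic_distance_matrix()
            table: Dict[Tuple[str, str], float] = {}
            taxa = list(self._tree.taxon_namespace)
            for i, t1 in enumerate(taxa):
                for t2 in taxa[i:]:
                    d = pdm.patristic_distance(t1, t2)
                    a = t1.label.replace(" ", "_")
                    b = t2.label.replace(" ", "_")
                    table[(a, b)] = d
                    table[(b, a)] = d
            self._dist = table
        return self._dist

    def distance(self, a: str, b: str) -> float:
        """Patristic (path) distance between two leaves."""
        try:
            return self._distance_table()[(a, b)]
        except KeyError:
            raise KeyError(f"unknown species pair ({a!r}, {b!r})")

    def neighbors_by_distance(self, species: str,
                              candidates: Iterable[str]) -> List[Tuple[float, str]]:
        """Candidates sorted by (path distance to ``species``, tag)."""
        out = sorted(
            (self.distance(species, c), c) for c in candidates if c != species
        )
        return out


def read_newick(path: os.PathLike | str) -> TaxonTree:
    return TaxonTree.from_newick(str(path), is_path=True)
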