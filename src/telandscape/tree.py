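"""Dated (ultrametric) species trees.

Thin wrapper around :mod:`dendropy` exposing what the simulator and the
horizontal-transfer test need: leaf depths, pairwise split times in Myr,
and pre-order branch traversal for sequence evolution.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

ULTRAMETRIC_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or non-ultrametric input trees."""


class SpeciesTree:
    """A rooted tree with named leaves and branch lengths in Myr.

    Invariants enforced at construction: at least two leaves, unique leaf
    names, and ultrametricity (all root-to-leaf path sums equal within
    1e-6 Myr), since both insertion dating and split-time lookups assume a
    clock-like tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeError("tree must have at least two leaves")
        if len(set(leaves)) != len(leaves):
            raise TreeError("leaf names must be unique")
        self.leaf_names: list[str] = leaves
        depths = {}
        for leaf in tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        self._depths = depths
        dmax, dmin = max(depths.values()), min(depths.values())
        if dmax - dmin > ULTRAMETRIC_TOL:
            raise TreeError(
                f"tree is not ultrametric: leaf depths span [{dmin:g}, {dmax:g}] Myr"
            )
        self.depth: float = dmax

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise TreeError(f"could not parse Newick tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    def split_time(self, a: str, b: str) -> float:
        """Divergence time (Myr) of two leaves = half their patristic distance."""
        if a == b:
            return 0.0
        pdm = self._pdm()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        if ta is None or tb is None:
            raise TreeError(f"unknown leaf in pair ({a}, {b})")
        return pdm.patristic_distance(ta, tb) / 2.0

    def split_times(self) -> dict[frozenset, float]:
        """All unordered leaf pairs -> split time in Myr."""
        out = {}
        names = self.leaf_names
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                out[frozenset((a, b))] = self.split_time(a, b)
        return out

    def _pdm(self):
        if not hasattr(self, "_pdm_cache"):
            self._pdm_cache = self._tree.phylogenetic_distance_matrix()
        return self._pdm_cache

    def preorder_edges(self):
        """Yield (parent_node, child_node, branch_length_myr) in pre-order.

        Node identity is by dendropy node object; leaves carry taxon labels.
        """
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                yield node.parent_node, node, float(node.edge.length or 0.0)

    @property
    def root(self):
        return self._tree.seed_node

    def newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()
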