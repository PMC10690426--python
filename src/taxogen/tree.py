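"""Rooted species trees with branch lengths and support values.

``TaxonTree`` is a thin wrapper over a :class:`dendropy.Tree` that fixes the
conventions the rest of the package relies on: the tree is rooted, every leaf
label maps to a genome ID, internal node labels (when present) are bootstrap
support percentages, and node depth is counted in edges from the root.
"""

from __future__ import annotations

from pathlib import Path

import dendropy


class TaxonTree:
    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        self._update()

    def _update(self) -> None:
        self.tree.update_bipartitions(suppress_unifurcations=False)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "TaxonTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path, require_lengths: bool = True) -> "TaxonTree":
        t = cls.from_newick(Path(path).read_text())
        if require_lengths:
            missing = [
                e for e in t.tree.preorder_edge_iter()
                if e.head_node.parent_node is not None and e.length is None
            ]
            if missing:
                raise ValueError(
                    f"tree in {path} lacks branch lengths on {len(missing)} edges"
                )
        return t

    # -- serialisation ------------------------------------------------
    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    # -- queries ------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def validate_leaves(self, genome_ids) -> None:
        unmatched = sorted(set(self.leaf_labels) - set(genome_ids))
        if unmatched:
            raise ValueError(f"tree leaves match no genome ID: {unmatched}")

    def leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise KeyError(label)

    def mrca(self, labels) -> dendropy.Node:
        labels = list(labels)
        if len(labels) == 1:
            return self.leaf(labels[0])
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise ValueError(f"no MRCA found for {labels}")
        return node

    def node_depth(self, node: dendropy.Node) -> int:
        """Depth of ``node`` in edges from the root."""
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        return d

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def support(self, node: dendropy.Node) -> float | None:
        if node.is_leaf():
            return None
        if node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    def path_length(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)
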