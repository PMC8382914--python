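"""Phylogenies with a designated foreground branch.

Branch-site models test a single "foreground" edge of an unrooted
phylogeny against the "background" rest of the tree.  The foreground is
identified by the taxon bipartition its edge induces, which is robust to
taxon pruning and to the arbitrary rooting dendropy applies when reading
Newick.  PAML-style ``#1`` edge labels are also accepted on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["LabeledTree", "PruningArrays", "read_labeled_tree", "parse_newick_foreground"]


def _parse_newick(data: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=data, schema="newick", preserve_underscores=True)


class ForegroundError(ValueError):
    """The foreground branch is missing, ambiguous, or unidentifiable."""


def parse_newick_foreground(newick: str) -> tuple[str, frozenset[str] | None]:
    """Strip a PAML-style ``#1`` edge label from a Newick string.

    Returns the cleaned Newick and the set of taxon labels on the
    labeled edge's subtree side (or None if no ``#1`` token is present).
    """
    pos = newick.find("#1")
    if pos == -1:
        return newick, None
    if newick.find("#1", pos + 1) != -1:
        raise ForegroundError("more than one '#1' foreground label in Newick")
    # Walk backwards over whitespace, then over the node's label/length,
    # then (if the node is a clade) over its balanced parentheses.
    i = pos - 1
    while i >= 0 and newick[i].isspace():
        i -= 1
    end = i + 1
    while i >= 0 and newick[i] not in "()," :
        i -= 1
    if i >= 0 and newick[i] == ")":
        depth = 0
        while i >= 0:
            if newick[i] == ")":
                depth += 1
            elif newick[i] == "(":
                depth -= 1
                if depth == 0:
                    break
            i -= 1
        if depth != 0:
            raise ForegroundError("unbalanced parentheses before '#1'")
    else:
        i += 1
    fragment = newick[i:end]
    cleaned = newick[:pos] + newick[pos + 2 :]
    if fragment.startswith("("):
        depth = 0
        for k, ch in enumerate(fragment):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    fragment = fragment[: k + 1]
                    break
    else:
        fragment = fragment.split(":")[0]
    sub = _parse_newick(fragment + ";")
    taxa = frozenset(leaf.taxon.label for leaf in sub.leaf_node_iter())
    return cleaned, taxa


@dataclass
class LabeledTree:
    """An unrooted phylogeny plus an optional foreground bipartition.

    ``foreground`` is one side of the taxon bipartition induced by the
    foreground edge (either side identifies the same unrooted edge).
    """

    tree: dendropy.Tree
    foreground: frozenset[str] | None = None

    def __post_init__(self):
        self._collapse_basal_bifurcation()
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        self._leaves = frozenset(labels)
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        if self.foreground is not None:
            self.foreground = frozenset(self.foreground)
            if not self.foreground or not (self._leaves - self.foreground):
                raise ForegroundError(
                    "foreground bipartition must split the leaf set into two nonempty sides"
                )
            if not self.foreground <= self._leaves:
                raise ForegroundError("foreground taxa absent from tree")
            self.foreground_edge()  # validate it maps to an edge

    def _collapse_basal_bifurcation(self):
        # A Newick file rooted with two basal children duplicates one
        # unrooted edge; merge it so edge<->bipartition is one-to-one.
        seed = self.tree.seed_node
        if len(seed.child_nodes()) == 2 and len(self.tree.leaf_nodes()) > 2:
            self.tree.collapse_basal_bifurcation()

    @property
    def taxon_labels(self) -> frozenset[str]:
        return self._leaves

    def leaf_set(self, edge) -> frozenset[str]:
        head = edge.head_node
        return frozenset(l.taxon.label for l in head.leaf_iter())

    def foreground_edge(self):
        """The dendropy edge realizing the foreground bipartition."""
        if self.foreground is None:
            return None
        want = {self.foreground, self._leaves - self.foreground}
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if self.leaf_set(edge) in want:
                return edge
        raise ForegroundError(
            "foreground bipartition does not correspond to any edge of the tree"
        )

    def copy(self) -> "LabeledTree":
        return LabeledTree(
            tree=self.tree.clone(depth=1),
            foreground=self.foreground,
        )

    def to_newick(self, paml_label: bool = True) -> str:
        """Newick string, optionally with a PAML ``#1`` foreground label."""
        tree = self.tree.clone(depth=1)
        s = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()
        if paml_label and self.foreground is not None:
            labeled = LabeledTree(
                tree=_parse_newick(s),
                foreground=self.foreground,
            )
            edge = labeled.foreground_edge()
            edge.head_node.label = "#1"
            s = labeled.tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
            s = s.replace("'#1'", "#1").replace(")#1", ") #1")
        return s

    def pruning_arrays(self, taxon_order) -> "PruningArrays":
        """Flatten the tree into postorder arrays for likelihood pruning."""
        taxon_order = list(taxon_order)
        if set(taxon_order) != self._leaves:
            missing = self._leaves - set(taxon_order)
            extra = set(taxon_order) - self._leaves
            raise ValueError(
                f"taxon mismatch between tree and alignment (tree-only: {sorted(missing)}, "
                f"alignment-only: {sorted(extra)})"
            )
        leaf_rank = {t: i for i, t in enumerate(taxon_order)}
        fg_edge = self.foreground_edge() if self.foreground is not None else None

        node_index: dict[int, int] = {}
        n_leaves = len(taxon_order)
        next_internal = n_leaves
        child_idx, parent_idx, lengths, is_fg = [], [], [], []
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node_index[id(node)] = leaf_rank[node.taxon.label]
            else:
                node_index[id(node)] = next_internal
                next_internal += 1
            if node.parent_node is not None:
                child_idx.append(node_index[id(node)])
                lengths.append(node.edge.length if node.edge.length is not None else 0.0)
                is_fg.append(fg_edge is not None and node.edge is fg_edge)
        # parents resolved in a second pass (postorder guarantees children first)
        for node in self.tree.postorder_node_iter():
            if node.parent_node is not None:
                parent_idx.append(node_index[id(node.parent_node)])
        return PruningArrays(
            n_leaves=n_leaves,
            n_nodes=next_internal,
            root_index=node_index[id(self.tree.seed_node)],
            child_index=np.array(child_idx, dtype=np.int64),
            parent_index=np.array(parent_idx, dtype=np.int64),
            branch_lengths=np.array(lengths, dtype=float),
            is_foreground=np.array(is_fg, dtype=bool),
        )


@dataclass
class PruningArrays:
    """Postorder edge arrays extracted from a LabeledTree.

    Edge ``k`` connects ``child_index[k]`` (already-visited subtree) to
    ``parent_index[k]``; leaves are indexed 0..n_leaves-1 in the
    caller-supplied taxon order.
    """

    n_leaves: int
    n_nodes: int
    root_index: int
    child_index: np.ndarray
    parent_index: np.ndarray
    branch_lengths: np.ndarray
    is_foreground: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.child_index)

    def with_lengths(self, lengths: np.ndarray) -> "PruningArrays":
        return PruningArrays(
            n_leaves=self.n_leaves,
            n_nodes=self.n_nodes,
            root_index=self.root_index,
            child_index=self.child_index,
            parent_index=self.parent_index,
            branch_lengths=np.asarray(lengths, dtype=float),
            is_foreground=self.is_foreground,
        )


def read_labeled_tree(path, foreground: frozenset[str] | set[str] | None = None) -> LabeledTree:
    """Read a Newick tree; the foreground comes from a ``#1`` label in
    the file or from an explicit taxon-bipartition argument (which wins)."""
    newick = Path(path).read_text()
    cleaned, labeled_fg = parse_newick_foreground(newick)
    tree = _parse_newick(cleaned)
    fg = frozenset(foreground) if foreground is not None else labeled_fg
    return LabeledTree(tree=tree, foreground=fg)
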