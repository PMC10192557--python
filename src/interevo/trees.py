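"""Rooted phylogenetic trees (Newick in/out, validation, rerooting).

Thin wrapper over dendropy that enforces the invariants the likelihood
machinery relies on: a single root, unique leaf names, and finite
non-negative branch lengths on every non-root node.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import dendropy

#: Default species tree for the four-amniote fixture: mouse and human on the
#: mammalian side, zebra finch and turtle on the sauropsid side, rooted at the
#: amniote ancestor.  Branch lengths are free parameters of the simulations
#: (0.1-0.5 expected substitutions per site by default), not literature values.
AMNIOTE_TREE = (
    "((mouse:0.30,human:0.25)mammal_ancestor:0.20,"
    "(zebra_finch:0.35,turtle:0.30)sauropsid_ancestor:0.15)amniote_ancestor;"
)


def node_name(node: dendropy.Node) -> str | None:
    """Taxon label for leaves, node label for internal nodes."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label


class PhyloTree:
    """A rooted tree with branch lengths in expected substitutions per site."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"Newick parse error: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True,
        ).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def _validate(self) -> None:
        root = self._tree.seed_node
        names = [node_name(n) for n in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dups}")
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            t = node.edge.length
            if t is None:
                raise ValueError(f"missing branch length above {node_name(node) or 'an internal node'}")
            if not (t == t and -float("inf") < t < float("inf")) or t < 0:
                raise ValueError(f"branch length above {node_name(node) or 'internal node'} "
                                 f"must be finite and >= 0, got {t}")

    # -- traversal ----------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def preorder(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def leaves(self) -> Iterator[dendropy.Node]:
        return self._tree.leaf_node_iter()

    @property
    def leaf_names(self) -> list[str]:
        return [node_name(n) for n in self.leaves()]

    def internal_nodes(self) -> list[dendropy.Node]:
        return [n for n in self.preorder() if not n.is_leaf()]

    def label_unnamed_internals(self, prefix: str = "anc") -> None:
        """Give unnamed internal nodes stable preorder names anc0, anc1, ..."""
        existing = {node_name(n) for n in self.preorder()}
        i = 0
        for node in self.preorder():
            if node.is_leaf() or node_name(node):
                continue
            while f"{prefix}{i}" in existing:
                i += 1
            node.label = f"{prefix}{i}"
            existing.add(node.label)

    def find_node(self, name: str) -> dendropy.Node:
        for node in self.preorder():
            if node_name(node) == name:
                return node
        avail = sorted(filter(None, (node_name(n) for n in self.internal_nodes())))
        raise KeyError(f"node {name!r} not found; internal nodes: {avail}")

    # -- rerooting (pulley-principle checks) --------------------------------

    def n_edges(self) -> int:
        return sum(1 for n in self.preorder() if n is not self.root)

    def rerooted_at_edge(self, edge_index: int, fraction: float = 0.5) -> "PhyloTree":
        """Return a copy rooted inside the ``edge_index``-th edge (preorder).

        The new root splits that edge into ``fraction`` / ``1 - fraction`` of
        its original length.  Under a reversible model the likelihood is
        invariant to this operation.
        """
        clone = dendropy.Tree(self._tree)
        nodes = [n for n in clone.preorder_node_iter() if n is not clone.seed_node]
        edge = nodes[edge_index].edge
        t = edge.length
        clone.reroot_at_edge(edge, length1=t * (1 - fraction), length2=t * fraction,
                             update_bipartitions=False)
        clone.suppress_unifurcations()
        return PhyloTree(clone)


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths into a PhyloTree."""
    return PhyloTree.from_newick(text)


def amniote_fixture_tree() -> PhyloTree:
    """The default four-species amniote tree used by the simulations."""
    return parse_newick(AMNIOTE_TREE)
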