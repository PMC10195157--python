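"""Rooted phylogenetic trees, Newick I/O, and topology comparison.

Trees are stored rooted; Robinson-Foulds distances are computed on the
unrooted form (the root edge carries no split).  Branch-length units are not
interpreted here: the family-dynamics model reads them as time, the codon
models as expected substitutions per site.  Polytomies are allowed and
treated as hard — a polytomous tree simply contributes fewer bipartitions.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

__all__ = [
    "NewickParseError",
    "PhyloTree",
    "Bipartition",
    "parse_newick",
    "bipartitions",
    "rf_distance",
    "restrict",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input or invariant violations."""


class Bipartition:
    """A two-block split of a leaf-label set, stored canonically.

    The block containing the lexicographically smallest taxon is stored
    first.  Trivial splits (a singleton block) are excluded from RF
    accounting upstream and are representable but never produced by
    :func:`bipartitions`.
    """

    __slots__ = ("first", "second")

    def __init__(self, block_a: Iterable[str], block_b: Iterable[str]):
        a, b = frozenset(block_a), frozenset(block_b)
        if a & b:
            raise ValueError(f"bipartition blocks overlap: {sorted(a & b)}")
        if min(a) <= min(b):
            self.first, self.second = a, b
        else:
            self.first, self.second = b, a

    @property
    def leaf_set(self) -> frozenset:
        return self.first | self.second

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.first == other.first
            and self.second == other.second
        )

    def __hash__(self) -> int:
        return hash((self.first, self.second))

    def __repr__(self) -> str:
        fmt = lambda b: ",".join(sorted(b))
        return f"Bipartition({fmt(self.first)} | {fmt(self.second)})"


class PhyloTree:
    """Rooted, branch-lengthed tree over uniquely labelled taxa.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the package's
    invariants (unique leaf labels, non-negative finite branch lengths) and
    exposes the topology operations downstream stages need.  Missing branch
    lengths are recorded as ``None``, never silently as zero.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._tree.is_rooted = True
        self._validate()

    # -- construction --------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            import re as _re

            m = _re.search(r"Duplicate taxon labels:\s*(\S+)", str(exc))
            if m:
                raise NewickParseError(
                    f"duplicate leaf label {m.group(1)!r}: {exc}"
                ) from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    def _validate(self) -> None:
        seen: dict[str, int] = {}
        for i, leaf in enumerate(self._tree.leaf_node_iter()):
            label = leaf.taxon.label if leaf.taxon is not None else None
            if label is None:
                raise NewickParseError(f"unlabelled leaf at position {i}")
            if label in seen:
                raise NewickParseError(
                    f"duplicate leaf label {label!r} (leaf positions {seen[label]} and {i})"
                )
            seen[label] = i
        if not seen:
            raise NewickParseError("tree has no leaves")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and not (0 <= edge.length < float("inf")):
                raise NewickParseError(
                    f"branch length {edge.length!r} is negative or non-finite"
                )

    # -- basic accessors -----------------------------------------------

    @property
    def dtree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def to_newick(self, *, with_lengths: bool = True) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not with_lengths,
            unquoted_underscores=True,
        )
        return s.strip()

    def __repr__(self) -> str:
        return f"PhyloTree({len(self)} leaves)"

    # -- topology operations -------------------------------------------

    def bipartitions(self) -> set:
        """Non-trivial splits of the unrooted form, one per internal edge."""
        all_leaves = self.leaf_labels
        splits: set = set()
        below: dict[dendropy.Node, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            if node is not self._tree.seed_node:
                block = below[node]
                rest = all_leaves - block
                if len(block) >= 2 and len(rest) >= 2:
                    splits.add(Bipartition(block, rest))
        return splits

    def restrict(self, taxa: Iterable[str]) -> "PhyloTree":
        """Induced tree on ``taxa``; unary nodes suppressed, lengths summed."""
        taxa = set(taxa)
        unknown = taxa - self.leaf_labels
        if unknown:
            raise ValueError(f"unknown taxa: {sorted(unknown)}")
        if len(taxa) < 2:
            raise ValueError("restriction requires at least 2 taxa")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=taxa, suppress_unifurcations=True
        )
        # dendropy may leave a unifurcate root carrying the stem edge; fold it.
        root = sub.seed_node
        while len(root.child_nodes()) == 1 and not root.is_leaf():
            child = root.child_nodes()[0]
            if child.edge.length is not None and root.edge.length is not None:
                child.edge.length += root.edge.length
            sub.seed_node = child
            child.parent_node = None
            root = child
        return PhyloTree(sub)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def bipartitions(tree: PhyloTree) -> set:
    return tree.bipartitions()


def restrict(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    return tree.restrict(taxa)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree.

    Both trees must cover the same leaf set; restrict first if they do not.
    Zero iff the unrooted topologies are identical and equally resolved.
    """
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        only1, only2 = sorted(l1 - l2), sorted(l2 - l1)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())
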