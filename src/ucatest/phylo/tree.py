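"""Leaf-labelled trees with branch lengths.

Unrooted trees are stored with an arbitrary (usually trifurcating) root;
the likelihood of a time-reversible model does not depend on the root
placement.  Branch lengths live on the child end of each edge, in expected
substitutions per site.
"""

from __future__ import annotations

from typing import Iterator, List, Optional, Sequence


class Node:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = float(length)
        self.label = label

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A rooted view of a (possibly unrooted) phylogenetic tree."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -------------------------------------------------

    @classmethod
    def star(cls, labels: Sequence[str], branch_length: float = 1.0) -> "Tree":
        root = Node()
        for lab in labels:
            root.add(Node(lab, branch_length))
        return cls(root)

    @classmethod
    def two_collapsed_quartets(
        cls, labels: Sequence[str], terminal_length: float
    ) -> "Tree":
        """Two quartets with all internal branches collapsed to zero.

        With saturating terminal lengths this is computationally equivalent
        to a star over all eight leaves, i.e. independently originated
        sequences drawn from a common frequency pool.
        """
        if len(labels) != 8:
            raise ValueError("two quartets need exactly 8 labels")
        root = Node()
        for half in (labels[:4], labels[4:]):
            q = root.add(Node(length=0.0))
            for pair in (half[:2], half[2:]):
                cherry = q.add(Node(length=0.0))
                for lab in pair:
                    cherry.add(Node(lab, terminal_length))
        return cls(root)

    @classmethod
    def quartet(
        cls, labels: Sequence[str], terminal_length: float, internal_length: float
    ) -> "Tree":
        """Balanced four-leaf tree; the single internal edge is split in two
        halves around the root, so its unrooted length equals
        ``internal_length``."""
        if len(labels) != 4:
            raise ValueError("a quartet needs exactly 4 labels")
        root = Node()
        for pair in (labels[:2], labels[2:]):
            cherry = root.add(Node(length=internal_length / 2.0))
            for lab in pair:
                cherry.add(Node(lab, terminal_length))
        return cls(root)

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def internal_edges(self) -> List[Node]:
        """Nodes whose parent edge joins two internal nodes."""
        return [
            n
            for n in self.postorder()
            if n.parent is not None and not n.is_leaf and n.parent.children
        ]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_branches(self) -> int:
        """Identifiable branch-length parameters: edges of the unrooted
        tree.  A degree-2 root splits one unrooted edge in two (only their
        sum is identifiable), so it contributes a single parameter."""
        count = sum(1 for n in self.postorder() if n.parent is not None)
        if len(self.root.children) == 2:
            count -= 1
        return count

    def tree_length(self) -> float:
        """Sum of all branch lengths (independent of the root placement)."""
        return float(sum(n.length for n in self.postorder() if n.parent is not None))

    # -- manipulation -------------------------------------------------

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root))

    def set_lengths(self, value: float) -> "Tree":
        for n in self.postorder():
            if n.parent is not None:
                n.length = float(value)
        return self

    # -- serialization ------------------------------------------------

    def newick(self, precision: int = 10) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.parent is None:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.newick()})"


def nni_neighbours(tree: Tree) -> List[Tree]:
    """All nearest-neighbour-interchange rearrangements of a tree.

    For each internal edge (u, v) the two subtrees hanging below v can each
    be exchanged with one subtree on the u side, giving two distinct
    topologies per edge.
    """
    out = []
    base = tree.copy()
    nodes = list(base.postorder())
    for idx, v in enumerate(nodes):
        if v.parent is None or v.is_leaf:
            continue
        u = v.parent
        # one neighbour of u other than v (sibling subtree, or the rest of
        # the tree through u's parent is not swapped here: sibling swaps
        # already enumerate both alternative topologies for this edge)
        siblings = [c for c in u.children if c is not v]
        if not siblings:
            continue
        s = siblings[0]
        for ci in range(min(2, len(v.children))):
            t2 = tree.copy()
            n2 = list(t2.postorder())
            v2, u2 = n2[idx], n2[idx].parent
            s2 = [c for c in u2.children if c is not v2][0]
            c2 = v2.children[ci]
            # exchange s2 and c2
            u2.children[u2.children.index(s2)] = c2
            v2.children[ci] = s2
            c2.parent, s2.parent = u2, v2
            out.append(t2)
    return out


def enumerate_topologies(labels: Sequence[str]) -> List[Tree]:
    """All unrooted binary topologies on the given labels (n <= 6 sensible).

    Built by sequential leaf insertion into every edge; represented with a
    trifurcating root.  All branch lengths start at 0.1.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")

    def insert_everywhere(tree: Tree, label: str) -> List[Tree]:
        res = []
        nodes = list(tree.postorder())
        for idx, n in enumerate(nodes):
            if n.parent is None:
                continue
            t2 = tree.copy()
            n2 = list(t2.postorder())[idx]
            parent = n2.parent
            mid = Node(length=n2.length / 2.0)
            n2.length = n2.length / 2.0
            parent.children[parent.children.index(n2)] = mid
            mid.parent = parent
            mid.add(n2)
            mid.add(Node(label, 0.1))
            res.append(t2)
        return res

    trees = [Tree.star(labels[:3], 0.1)]
    for lab in labels[3:]:
        trees = [t2 for t in trees for t2 in insert_everywhere(t, lab)]
    return trees
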