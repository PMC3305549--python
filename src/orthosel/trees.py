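"""Labeled phylogenetic trees with per-branch rate-class annotations.

A :class:`LabeledTree` is a rooted data structure representing a (usually
unrooted) phylogeny.  Every non-root node carries the length of the branch
connecting it to its parent, an integer branch *class* (0-based; class 0 is
the background) and optionally a bootstrap support value for the split the
branch induces.  Branch classes encode the foreground/background partitions
used by branch and branch-site codon models; on disk they use the PAML-style
``#k`` suffix dialect of Newick (``(a, (b, c) #1);``).

Parsing goes through dendropy (with the ``#k`` tags shuttled through the
labels); writing uses a small emitter because the tag dialect is not
standard Newick.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

_TAG_RE = re.compile(r"\s*@CLS@(\d+)\s*$")
_TAG_IN_RE = re.compile(r"\s*#\s*(\d+)")


@dataclass
class Node:
    """One tree node; ``length``/``label`` describe the edge to the parent."""

    name: str | None = None
    length: float = 0.0
    label: int = 0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LabeledTree:
    """A rooted tree view of a phylogeny with branch-class labels."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        """Parse a Newick string, honouring PAML-style ``#k`` branch tags."""
        # a '#k' tag may follow the node name or the branch length; move the
        # latter form in front of the colon so it lands in the node label
        masked = re.sub(r":\s*([0-9.eE+\-]+)\s*#\s*(\d+)", r"@CLS@\2:\1", newick)
        masked = _TAG_IN_RE.sub(lambda m: f"@CLS@{m.group(1)}", masked)
        dtree = dendropy.Tree.get(
            data=masked,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> Node:
            raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
            label = 0
            name = None
            support = None
            if raw is not None:
                m = _TAG_RE.search(raw)
                if m:
                    label = int(m.group(1))
                    raw = raw[: m.start()]
                raw = raw.strip()
                if raw:
                    if dnode.is_leaf():
                        name = raw
                    else:
                        # internal labels: bootstrap support if numeric
                        try:
                            support = float(raw)
                        except ValueError:
                            name = raw
            node = Node(
                name=name,
                length=float(dnode.edge.length or 0.0),
                label=label,
                support=support,
            )
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(dtree.seed_node))

    # -- basic queries ---------------------------------------------------

    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def branch_classes(self) -> set[int]:
        """Set of branch class ids present (root edge excluded)."""
        nodes = self.postorder()
        return {n.label for n in nodes[:-1]}

    def copy(self) -> "LabeledTree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length, n.label, n.support)
            m.children = [dup(c) for c in n.children]
            return m

        return LabeledTree(dup(self.root))

    def _validate(self) -> None:
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf labels")
        if any(n is None for n in names):
            raise ValueError("unnamed leaf")
        for n in self.postorder():
            if n.length < 0:
                raise ValueError(f"negative branch length on {n.name or 'internal node'}")

    # -- splits and distances -------------------------------------------

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each as the smaller-side leaf set.

        Splits are canonicalised to the lexicographically smaller side so
        that rooted representations of the same unrooted topology compare
        equal.
        """
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset[str]] = set()

        def walk(n: Node) -> frozenset[str]:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return out

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels and the matrix of leaf-to-leaf path lengths."""
        leaves = self.leaves()
        names = [n.name for n in leaves]
        idx = {id(n): i for i, n in enumerate(leaves)}
        dm = np.zeros((len(leaves), len(leaves)))

        def walk(n: Node) -> dict[int, float]:
            if n.is_leaf:
                return {idx[id(n)]: 0.0}
            partial: list[dict[int, float]] = []
            for c in n.children:
                d = walk(c)
                partial.append({k: v + c.length for k, v in d.items()})
            for da, db in itertools.combinations(partial, 2):
                for i, vi in da.items():
                    for j, vj in db.items():
                        dm[i, j] = dm[j, i] = vi + vj
            merged: dict[int, float] = {}
            for d in partial:
                merged.update(d)
            return merged

        walk(self.root)
        return names, dm

    # -- rerooting -------------------------------------------------------

    def rerooted_at(self, name: str) -> "LabeledTree":
        """Return a copy rooted at the named node (leaf or internal).

        The edge set, branch lengths and branch classes are preserved, only
        the direction of traversal changes; for a reversible substitution
        model the likelihood is invariant under this operation.
        """
        tree = self.copy()
        target = None
        parent_of: dict[int, Node | None] = {id(tree.root): None}

        def walk(n: Node) -> None:
            nonlocal target
            if (n.name == name) if n.name is not None else False:
                target = n
            for c in n.children:
                parent_of[id(c)] = n
                walk(c)

        walk(tree.root)
        if target is None:
            raise KeyError(f"no node named {name!r}")
        # re-hang: walk from target up to the old root, flipping edges
        node = target
        edge = (node.length, node.label)  # edge towards old parent
        parent = parent_of[id(node)]
        node.length, node.label = 0.0, 0
        while parent is not None:
            parent.children.remove(node)
            grand = parent_of[id(parent)]
            next_edge = (parent.length, parent.label)
            parent.length, parent.label = edge
            node.children.append(parent)
            node, parent, edge = parent, grand, next_edge
        return LabeledTree(target)

    # -- serialization ---------------------------------------------------

    def to_newick(self, *, support_as_percent: bool = False) -> str:
        """Emit Newick with ``#k`` branch-class tags for classes > 0."""

        def emit(n: Node, is_root: bool) -> str:
            if n.is_leaf:
                body = n.name
            else:
                inner = ",".join(emit(c, False) for c in n.children)
                lab = ""
                if n.support is not None:
                    lab = (
                        f"{round(n.support * 100):d}"
                        if support_as_percent
                        else f"{n.support:g}"
                    )
                elif n.name:
                    lab = n.name
                body = f"({inner}){lab}"
            if is_root:
                return body
            tag = f" #{n.label}" if n.label else ""
            return f"{body}{tag}:{n.length:.10g}"

        return emit(self.root, True) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"LabeledTree({self.to_newick()})"


def balanced_tree(names: list[str], branch_length: float = 1.0) -> LabeledTree:
    """Balanced (caterpillar-free) topology over ``names`` with unit branches.

    Used as the default species tree for genome simulation.
    """
    if len(names) < 2:
        raise ValueError("need at least two leaves")
    nodes = [Node(name=n, length=branch_length) for n in names]
    while len(nodes) > 2:
        nxt = []
        for k in range(0, len(nodes) - 1, 2):
            parent = Node(length=branch_length, children=[nodes[k], nodes[k + 1]])
            nxt.append(parent)
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    root = Node(children=nodes)
    for c in root.children:
        c.length = branch_length
    return LabeledTree(root)
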