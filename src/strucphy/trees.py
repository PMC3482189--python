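"""Phylogeny container and topology operations.

Trees are stored rooted; an unrooted binary tree is represented with a
trifurcating root, the convention used by most ML programs.  Newick
parsing and Robinson–Foulds distances go through dendropy; the in-memory
structure here stays minimal so that likelihood, parsimony and NNI
rearrangement can walk it cheaply.
"""

from __future__ import annotations

import dendropy


class Node:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.label = label
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted (possibly multifurcating) tree with branch lengths and
    optional internal-edge support percentages in [0, 100]."""

    def __init__(self, root: Node):
        self.root = root
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")

    # -- traversal -------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_tip:
                out.append(node)
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    def internal_edges(self) -> list[Node]:
        """Nodes whose parent edge is internal (non-tip, non-root)."""
        return [n for n in self.postorder()
                if not n.is_tip and n.parent is not None]

    # -- copying ---------------------------------------------------------
    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.support = n.support
            for c in n.children:
                m.add(clone(c))
            return m
        return Phylogeny(clone(self.root))

    # -- newick ----------------------------------------------------------
    def to_newick(self, support: bool = False, lengths: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_tip:
                s = n.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if support and n.support is not None:
                    s += format(n.support, "g")
                elif n.label:
                    s += n.label
            if lengths and n.parent is not None:
                s += f":{n.length:.10g}"
            return s
        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, support_as_label: bool = True) -> "Phylogeny":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
        return cls.from_dendropy(dt, support_as_label=support_as_label)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree, support_as_label: bool = True) -> "Phylogeny":
        def conv(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            n = Node(label if dn.is_leaf() else None,
                     dn.edge.length if dn.edge.length is not None else 0.0)
            if not dn.is_leaf() and label is not None:
                if support_as_label:
                    try:
                        n.support = float(label)
                    except ValueError:
                        n.label = label
                else:
                    n.label = label
            for c in dn.child_nodes():
                n.add(conv(c))
            return n
        return cls(conv(dt.seed_node))

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        return dendropy.Tree.get(
            data=self.to_newick(support=True), schema="newick",
            taxon_namespace=tns, suppress_internal_node_taxa=True,
        )

    # -- splits / comparison --------------------------------------------
    def splits(self) -> dict[frozenset[str], Node]:
        """Non-trivial bipartitions of the unrooted topology.

        Each split is identified by the tip set on the side *not*
        containing the alphabetically first tip, so splits compare equal
        across rootings; maps to the child node defining the edge.
        """
        all_tips = set(self.tip_labels())
        ref = min(all_tips)
        out: dict[frozenset[str], Node] = {}
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_tip:
                below[id(n)] = {n.label}
            else:
                below[id(n)] = set().union(*(below[id(c)] for c in n.children))
            if n.parent is None or n.is_tip:
                continue
            side = below[id(n)]
            if ref in side:
                side = all_tips - side
            if 2 <= len(side) <= len(all_tips) - 2:
                out[frozenset(side)] = n
        return out

    def rf_distance(self, other: "Phylogeny") -> int:
        a, b = set(self.splits()), set(other.splits())
        return len(a ^ b)

    # -- NNI -------------------------------------------------------------
    def nni_neighbors(self) -> list["Phylogeny"]:
        """All nearest-neighbour-interchange rearrangements of the
        (implicitly unrooted) topology, as new trees."""
        out = []
        for idx, edge in enumerate(self.internal_edges()):
            parent = edge.parent
            siblings = [c for c in parent.children if c is not edge]
            if not siblings or len(edge.children) < 2:
                continue
            for child_i in range(2):
                t = self.copy()
                v = t.internal_edges()[idx]
                u = v.parent
                c = next(x for x in u.children if x is not v)
                a = v.children[child_i]
                # swap subtrees a and c across the internal edge
                u.children[u.children.index(c)] = a
                v.children[child_i] = c
                a.parent, c.parent = u, v
                out.append(t)
        return out


def cherry(label_a: str, label_b: str, la: float = 0.0, lb: float = 0.0) -> Phylogeny:
    root = Node()
    root.add(Node(label_a, la))
    root.add(Node(label_b, lb))
    return Phylogeny(root)


def unroot(tree: Phylogeny) -> Phylogeny:
    """Collapse a bifurcating root into the trifurcating convention."""
    t = tree.copy()
    root = t.root
    if len(root.children) == 2:
        a, b = root.children
        donor = a if not a.is_tip else b
        if donor.is_tip:
            return t  # two-taxon tree
        keeper = b if donor is a else a
        keeper.length += donor.length
        root.children = [c for c in (a, b) if c is not donor]
        for c in donor.children:
            root.add(c)
    return Phylogeny(t.root)


def is_binary_unrooted(tree: Phylogeny) -> bool:
    if len(tree.root.children) != 3:
        return False
    return all(len(n.children) in (0, 2) for n in tree.postorder()
               if n.parent is not None)


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """RF distance between two newick strings (cross-checkable against
    dendropy's bipartition machinery)."""
    return Phylogeny.from_newick(newick_a).rf_distance(Phylogeny.from_newick(newick_b))
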