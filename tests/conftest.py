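import itertools

import numpy as np
import pytest

from strucphy.trees import Node, Phylogeny


def balanced_quartet(bl: float = 0.1) -> Phylogeny:
    """((A,B),(C,D)) with equal branch lengths."""
    root = Node()
    left, right = root.add(Node(length=bl)), root.add(Node(length=bl))
    for n, lab in ((left, "A"), (left, "B"), (right, "C"), (right, "D")):
        n.add(Node(lab, bl))
    return Phylogeny(root)


def all_topologies(labels: list[str]) -> list[Phylogeny]:
    """Every unrooted binary topology on the given tips (3, 15, 105... )."""

    def grow(trees, label):
        out = []
        for t in trees:
            edges = [n for n in t.postorder() if n.parent is not None]
            for idx in range(len(edges)):
                t2 = t.copy()
                v = [n for n in t2.postorder() if n.parent is not None][idx]
                u = Node(length=v.length / 2)
                parent = v.parent
                parent.children[parent.children.index(v)] = u
                u.parent = parent
                v.length /= 2
                u.add(v)
                u.add(Node(label, 0.1))
                out.append(Phylogeny(t2.root))
        return out

    root = Node()
    for lab in labels[:3]:
        root.add(Node(lab, 0.1))
    trees = [Phylogeny(root)]
    for lab in labels[3:]:
        trees = grow(trees, lab)
    return trees


def enumerate_likelihood(tree: Phylogeny, column: dict[str, int],
                         model) -> float:
    """Brute-force single-site likelihood: sum over all internal-node
    state assignments of products of transition probabilities."""
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_tip]
    k = model.k
    pi = model.frequencies
    rates = model.rate_multipliers
    total = 0.0
    for rate in rates:
        P = {id(n): model.transition_matrix(n.length, rate)
             for n in nodes if n.parent is not None}
        acc = 0.0
        for assign in itertools.product(range(k), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            for n in nodes:
                if n.is_tip:
                    state[id(n)] = column[n.label]
            prob = pi[state[id(nodes[-1])]]
            for n in nodes:
                if n.parent is None:
                    continue
                s = state[id(n)]
                if s == -1:  # missing tip: marginalize
                    prob *= 1.0
                else:
                    prob *= P[id(n)][state[id(n.parent)], s]
            acc += prob
        total += acc / len(rates)
    return total


def enumerate_parsimony(tree: Phylogeny, column: dict[str, int], k: int):
    """Brute-force minimum changes and per-node MPR sets."""
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_tip]
    best = None
    sets: dict[int, set[int]] = {i: set() for i, n in enumerate(nodes)
                                 if not n.is_tip}
    records = []
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assign)}
        for n in nodes:
            if n.is_tip:
                state[id(n)] = column.get(n.label, -1)
        changes = 0
        ok = True
        for n in nodes:
            if n.parent is None:
                continue
            s = state[id(n)]
            if s == -1:
                continue
            ps = state[id(n.parent)]
            changes += int(s != ps)
        # missing tips: choose the parent's state (zero cost), always legal
        records.append((changes, assign))
        if best is None or changes < best:
            best = changes
    for changes, assign in records:
        if changes == best:
            for i, n in enumerate(nodes):
                if not n.is_tip:
                    pos = internal.index(n)
                    sets[i].add(assign[pos])
    return best, sets


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
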