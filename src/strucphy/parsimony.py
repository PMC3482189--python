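"""Unordered (Fitch-type) parsimony: minimum change counts and
most-parsimonious ancestral state sets.

Scoring uses the unit-cost Sankoff dynamic programme, which is exact on
multifurcating trees and with missing data (a missing tip admits every
state at zero cost), and vectorizes cleanly over alignment columns.
The per-node MPR state sets come from combining the upward Sankoff costs
with downward costs, so a state is reported exactly when some globally
minimal reconstruction uses it.
"""

from __future__ import annotations

import warnings

import numpy as np

from .trees import Node, Phylogeny

_BIG = np.int32(10**6)


def _up_costs(tree: Phylogeny, columns: np.ndarray, taxa: list[str], k: int):
    """Upward Sankoff costs for every node.

    ``columns``: (n_taxa, n_cols) state matrix with −1 missing.  Returns
    (postorder nodes, dict node-index -> cost array (n_cols, k)).
    """
    row_of = {name: i for i, name in enumerate(taxa)}
    nodes = tree.postorder()
    node_index = {id(n): i for i, n in enumerate(nodes)}
    n_cols = columns.shape[1]
    cost: dict[int, np.ndarray] = {}
    for idx, n in enumerate(nodes):
        if n.is_tip:
            c = np.full((n_cols, k), _BIG, dtype=np.int32)
            states = columns[row_of[n.label]]
            obs = states >= 0
            c[~obs, :] = 0
            c[np.nonzero(obs)[0], states[obs]] = 0
            cost[idx] = c
        else:
            acc = np.zeros((n_cols, k), dtype=np.int32)
            for ch in n.children:
                ci = node_index[id(ch)]
                child = cost[ci]
                # unit substitution cost: min(child_s, min_child + 1)
                m = child.min(axis=1, keepdims=True)
                acc = acc + np.minimum(child, m + 1)
            cost[idx] = acc
    return nodes, cost


def fitch_score(tree: Phylogeny, column: dict[str, int], k: int | None = None) -> int:
    """Minimum number of state changes for one character on ``tree``.

    ``column`` maps taxon name → state index (missing taxa or −1 allowed).
    Polytomies are handled exactly by the Sankoff recursion.
    """
    states = {t: s for t, s in column.items() if s is not None and s >= 0}
    if not states:
        warnings.warn("all-missing character column; parsimony score is 0")
        return 0
    if k is None:
        k = max(states.values()) + 1
    taxa = tree.tip_labels()
    col = np.array([[column.get(t, -1) if column.get(t, -1) is not None else -1]
                    for t in taxa], dtype=np.int32)
    _, cost = _up_costs(tree, col, taxa, k)
    root_cost = cost[len(tree.postorder()) - 1]
    return int(root_cost.min())


def matrix_score(tree: Phylogeny, taxa: list[str], codes: np.ndarray,
                 k: int, weights: np.ndarray | None = None) -> int:
    """Total parsimony length of a coded matrix (sum over columns)."""
    nodes, cost = _up_costs(tree, np.asarray(codes), taxa, k)
    per_col = cost[len(nodes) - 1].min(axis=1)
    if weights is not None:
        return int(per_col @ weights)
    return int(per_col.sum())


def mpr_sets(tree: Phylogeny, column: dict[str, int], k: int) -> dict[int, set[int]]:
    """Per-internal-node sets of states used by ≥1 most-parsimonious
    reconstruction.

    Returns {postorder node index: state set} for internal nodes.  Computed
    from up-costs plus a downward pass: ``down[v][s]`` is the minimal cost
    of the rest of the tree given state s at v, so v's total cost surface
    is ``up + down`` and the MPR set is its argmin set.
    """
    taxa = tree.tip_labels()
    col = np.array([[column.get(t, -1) if column.get(t, -1) is not None else -1]
                    for t in taxa], dtype=np.int32)
    nodes, up = _up_costs(tree, col, taxa, k)
    index = {id(n): i for i, n in enumerate(nodes)}
    down: dict[int, np.ndarray] = {index[id(nodes[-1])]: np.zeros(k, dtype=np.int32)}
    for n in reversed(nodes):  # preorder
        if n.is_tip:
            continue
        i = index[id(n)]
        # cost of everything outside each child's subtree, per child state
        msgs = []
        for ch in n.children:
            u = up[index[id(ch)]][0]
            msgs.append(np.minimum(u, u.min() + 1))
        total_here = down[i] + sum(msgs, np.zeros(k, dtype=np.int32))
        for ci, ch in enumerate(n.children):
            if ch.is_tip:
                continue
            others = total_here - msgs[ci]  # cost at n excluding child ci
            u = up[index[id(ch)]][0]
            # down[child][s_c] = min_{s_n} others[s_n] + (s_n != s_c)
            down[index[id(ch)]] = np.minimum(others, others.min() + 1)
    result: dict[int, set[int]] = {}
    best = None
    for n in nodes:
        if n.is_tip:
            continue
        i = index[id(n)]
        surface = up[i][0] + down[i]
        m = surface.min()
        if best is None:
            best = m
        result[i] = set(np.nonzero(surface == m)[0].tolist())
    return result
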