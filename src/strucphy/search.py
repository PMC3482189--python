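"""Heuristic tree search (random addition + NNI), nonparametric bootstrap,
and majority-rule consensus with split-frequency annotation.

Both optimality criteria share the same machinery: starting trees come
from seeded random stepwise addition under parsimony, and hill-climbing
proceeds through nearest-neighbour interchanges until no rearrangement
improves the criterion (total parsimony length, or the branch-length-
optimized log-likelihood).  Bootstrap replicates resample coded sites —
a stem doublet site is a single resampling unit, so the compensatory
dependence within a base pair is never split across units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import parsimony
from .likelihood import _Pruner, as_coded, optimize
from .models import SubstitutionModel
from .trees import Node, Phylogeny


@dataclass
class SearchConfig:
    criterion: str = "mp"              # "ml" or "mp"
    n_starts: int = 10
    rearrangement: str = "nni"
    seed: int = 0
    bootstrap_replicates: int = 0

    def __post_init__(self):
        if self.criterion not in ("ml", "mp"):
            raise ValueError("criterion must be 'ml' or 'mp'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")
        if self.rearrangement != "nni":
            raise ValueError("only NNI rearrangement is provided")


def _random_addition_tree(taxa: list[str], codes: np.ndarray, k: int,
                          rng: np.random.Generator) -> Phylogeny:
    """Stepwise addition under parsimony with a random taxon order."""
    order = list(rng.permutation(len(taxa)))
    root = Node()
    for i in order[:3]:
        root.add(Node(taxa[i], 0.1))
    tree = Phylogeny(root)
    for i in order[3:]:
        best, best_tree = None, None
        for edge_idx, _ in enumerate(tree.postorder()[:-1]):
            t = tree.copy()
            nodes = t.postorder()
            v = nodes[edge_idx]
            u = Node(length=v.length / 2)
            parent = v.parent
            parent.children[parent.children.index(v)] = u
            u.parent = parent
            v.length /= 2
            u.add(v)
            u.add(Node(taxa[i], 0.1))
            t2 = Phylogeny(t.root)
            present = set(t2.tip_labels())
            rows = [j for j, name in enumerate(taxa) if name in present]
            sub_taxa = [taxa[j] for j in rows]
            score = parsimony.matrix_score(t2, sub_taxa, codes[rows], k)
            if best is None or score < best:
                best, best_tree = score, t2
        tree = best_tree
    return tree


def _ml_score(tree: Phylogeny, data, model: SubstitutionModel,
              quick: bool) -> tuple[Phylogeny, float]:
    # quick mode scores candidate topologies cheaply; the winner gets a
    # full branch-length optimization afterwards
    cycles, tol, xatol = (3, 1e-3, 1e-5) if quick else (100, 1e-6, 1e-7)
    fitted, _, lnl = optimize(tree, data, model, free=("branch_lengths",),
                              max_cycles=cycles, tol=tol, branch_xatol=xatol)
    return fitted, lnl


def search(data, model: SubstitutionModel | None, cfg: SearchConfig
           ) -> tuple[list[Phylogeny], float]:
    """Best tree(s) under the configured criterion.

    Returns all distinct equally-best topologies found over the random-
    addition starts, and the criterion score (MP: total length, lower is
    better; ML: log-likelihood, higher is better).
    """
    taxa, codes = as_coded(data)
    if len(taxa) < 4:
        raise ValueError("tree search needs at least 4 taxa")
    k = int(codes.max()) + 1
    if model is not None:
        k = model.k
    rng = np.random.default_rng(cfg.seed)
    use_ml = cfg.criterion == "ml"
    if use_ml and model is None:
        raise ValueError("ML search needs a substitution model")

    def mp_score(tree: Phylogeny) -> float:
        return parsimony.matrix_score(tree, taxa, codes, k)

    best_trees: list[Phylogeny] = []
    best_score: float | None = None
    for _ in range(cfg.n_starts):
        tree = _random_addition_tree(taxa, codes, k, rng)
        # parsimony NNI pre-climb: cheap, and an excellent ML starting point
        score = mp_score(tree)
        improved = True
        while improved:
            improved = False
            for nb in tree.nni_neighbors():
                s = mp_score(nb)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
        if use_ml:
            tree, score = _ml_score(tree, data, model, quick=True)
            visited = {frozenset(tree.splits())}
            improved = True
            while improved:
                improved = False
                for nb in tree.nni_neighbors():
                    key = frozenset(nb.splits())
                    if key in visited:
                        continue
                    visited.add(key)
                    nb_opt, s = _ml_score(nb, data, model, quick=True)
                    if s > score + 1e-6:
                        tree, score = nb_opt, s
                        improved = True
                        break
            tree, score = _ml_score(tree, data, model, quick=False)
        key = -score if use_ml else score
        if best_score is None or key < best_score - 1e-6:
            best_score, best_trees = key, [tree]
        elif abs(key - best_score) <= (1e-6 if use_ml else 0):
            if all(tree.rf_distance(t) > 0 for t in best_trees):
                best_trees.append(tree)
    final = -best_score if use_ml else best_score
    return best_trees, float(final)


def bootstrap(data, cfg: SearchConfig, model: SubstitutionModel | None = None
              ) -> list[Phylogeny]:
    """Site-resampling bootstrap; one search (and one tree) per replicate.

    Replicates draw the original number of sites with replacement, seeded
    reproducibly from ``cfg.seed``; ties within a replicate are broken by
    keeping the first best tree.
    """
    if cfg.bootstrap_replicates < 1:
        raise ValueError("bootstrap needs bootstrap_replicates >= 1")
    taxa, codes = as_coded(data)
    n_sites = codes.shape[1]
    rng = np.random.default_rng(cfg.seed)
    out = []
    for rep in range(cfg.bootstrap_replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep_cfg = SearchConfig(criterion=cfg.criterion, n_starts=cfg.n_starts,
                               seed=int(rng.integers(2**31)))
        trees, _ = search((taxa, codes[:, idx]), model, rep_cfg)
        out.append(trees[0])
    return out


def split_frequencies(trees: list[Phylogeny]) -> dict[frozenset[str], float]:
    """Fraction of input trees containing each non-trivial split."""
    taxon_sets = {frozenset(t.tip_labels()) for t in trees}
    if len(taxon_sets) != 1:
        raise ValueError("trees are not on identical taxon sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in t.splits():
            counts[split] = counts.get(split, 0) + 1
    return {s: c / len(trees) for s, c in counts.items()}


def majority_consensus(trees: list[Phylogeny],
                       annotate_onto: Phylogeny | None = None) -> Phylogeny:
    """Strict-majority (>50%) consensus, or split-frequency annotation.

    Without a target, builds the majority-rule consensus tree with each
    retained split's frequency (percent) as its support.  With
    ``annotate_onto``, returns a copy of that tree whose internal edges
    carry the input-set frequency of their split (0 for absent splits).
    """
    freqs = split_frequencies(trees)
    if annotate_onto is not None:
        if frozenset(annotate_onto.tip_labels()) != frozenset(trees[0].tip_labels()):
            raise ValueError("target tree is not on the input taxon set")
        out = annotate_onto.copy()
        for split, node in out.splits().items():
            node.support = 100.0 * freqs.get(split, 0.0)
        return out

    labels = sorted(trees[0].tip_labels())
    majority = sorted(
        (s for s, f in freqs.items() if f > 0.5),
        key=lambda s: (len(s), sorted(s)),
    )
    root = Node()
    tip_nodes = {name: root.add(Node(name)) for name in labels}
    cluster_nodes: list[tuple[frozenset[str], Node]] = []
    for split in majority:  # smallest first => children exist before parents
        node = Node()
        node.support = 100.0 * freqs[split]
        members: list[Node] = []
        taken: set[frozenset[str]] = set()
        for cs, cn in cluster_nodes:
            if cs <= split and cn.parent is root:
                members.append(cn)
                taken.add(cs)
        covered = set().union(*taken) if taken else set()
        for name in split - covered:
            members.append(tip_nodes[name])
        for m in members:
            root.children.remove(m)
            node.add(m)
        root.add(node)
        cluster_nodes.append((split, node))
    return Phylogeny(root)
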