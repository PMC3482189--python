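"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates what the recoding method presumes about real rRNA:
a phylogeny on which unpaired (loop) columns evolve independently under a
4-state model while each base-paired (stem) position pair evolves as a
single 16-state doublet — compensatory change within a pair is therefore
built in, not approximated.  Stems are simulated directly in doublet
space and written out as their two nucleotide columns, so recoding the
emitted alignment with the emitted structure recovers the simulated
doublet states exactly.

All randomness flows from one explicit seed through a named generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .alphabet import BASES
from .models import SubstitutionModel, build_model
from .structure import ColumnAnnotation, PairTable, project_to_alignment
from .trees import Node, Phylogeny


@dataclass
class SimSpec:
    """Simulation settings: tree shape, site counts, models, seed."""

    n_tips: int = 8
    birth_rate: float = 1.0
    #: root-to-tip height in expected substitutions per site; rRNA is
    #: conserved, so even phylum-deep divergences stay well below saturation
    tree_height: float = 0.5
    n_loop_sites: int = 100
    n_stem_pairs: int = 200
    loop_model: SubstitutionModel | None = None   # default JC (4-state)
    stem_model: SubstitutionModel | None = None   # default Poisson (16-state)
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("need at least two tips")
        if self.n_loop_sites < 0 or self.n_stem_pairs < 0:
            raise ValueError("site counts must be >= 0")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be > 0")


def simulate_tree(spec: SimSpec, rng: np.random.Generator | None = None) -> Phylogeny:
    """Seeded Yule (pure-birth) tree with ``n_tips`` tips.

    Lineages split at exponential waiting times until the target tip count
    is reached; tip branches are extended to the final time so the tree is
    ultrametric, then all branch lengths are rescaled so the root-to-tip
    height equals ``tree_height`` substitutions/site.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if spec.n_tips < 2:
        raise ValueError("need at least two tips")
    root = Node()
    active: list[Node] = [root.add(Node()), root.add(Node())]
    birth: dict[int, float] = {id(n): 0.0 for n in active}
    t = 0.0
    while len(active) < spec.n_tips:
        t += rng.exponential(1.0 / (spec.birth_rate * len(active)))
        i = rng.integers(len(active))
        parent = active.pop(int(i))
        parent.length = t - birth[id(parent)]
        for _ in range(2):
            c = parent.add(Node())
            birth[id(c)] = t
            active.append(c)
    t += rng.exponential(1.0 / (spec.birth_rate * len(active)))
    for n in active:
        n.length = t - birth[id(n)]
    scale = spec.tree_height / t if t > 0 else 1.0
    order = 0
    stack = [root]
    while stack:
        n = stack.pop()
        n.length *= scale
        if n.is_tip:
            n.label = f"t{order}"
            order += 1
        stack.extend(reversed(n.children))
    return Phylogeny(root)


def _evolve(tree: Phylogeny, model: SubstitutionModel, n_sites: int,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate ``n_sites`` iid sites down the tree; returns tip states."""
    k = model.k
    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    nodes = tree.postorder()
    index = {id(n): i for i, n in enumerate(nodes)}
    out: dict[str, np.ndarray] = {}
    for n in reversed(nodes):  # parents before children
        i = index[id(n)]
        if n.parent is None:
            states[i] = rng.choice(k, size=n_sites, p=pi)
        else:
            P = model.transition_matrix(n.length)
            parent_states = states[index[id(n.parent)]]
            u = rng.random(n_sites)
            cdf = np.cumsum(P[parent_states], axis=1)
            states[i] = (u[:, None] > cdf).sum(axis=1)
        if n.is_tip:
            out[n.label] = states[i]
    return out


def simulate_alignment(
    tree: Phylogeny, spec: SimSpec, rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str], PairTable, ColumnAnnotation]:
    """Simulate a structure-annotated nucleotide alignment on ``tree``.

    Returns (taxa, aligned rows, true PairTable of the ungapped reference,
    true ColumnAnnotation).  Column layout is a single nested stem: the
    5' halves of all stem pairs first, then the loop block, then the 3'
    halves in reverse — i.e. the dot-bracket ``((( ... )))``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if spec.n_loop_sites + spec.n_stem_pairs == 0:
        raise ValueError("zero total sites")
    loop_model = spec.loop_model or build_model("poisson", 4)
    stem_model = spec.stem_model or build_model("poisson", 16)
    if loop_model.k != 4 or stem_model.k != 16:
        raise ValueError("loop model must have 4 states, stem model 16")
    loops = _evolve(tree, loop_model, spec.n_loop_sites, rng)
    stems = _evolve(tree, stem_model, spec.n_stem_pairs, rng)
    taxa = tree.tip_labels()
    n_cols = spec.n_loop_sites + 2 * spec.n_stem_pairs
    rows = []
    for t in taxa:
        left = [BASES[d // 4] for d in stems[t]]
        right = [BASES[d % 4] for d in reversed(stems[t])]
        middle = [BASES[s] for s in loops[t]]
        rows.append("".join(left + middle + right))
    pairs = frozenset(
        (i, n_cols - 1 - i) for i in range(spec.n_stem_pairs)
    )
    pt = PairTable(length=n_cols, pairs=pairs)
    # simulation is ungapped, so any row serves as the reference row
    ann = project_to_alignment(pt, rows[0])
    return taxa, rows, pt, ann


def dotbracket(pt: PairTable) -> str:
    s = ["."] * pt.length
    for i, j in pt.pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def simulate_character(tree: Phylogeny, k: int, rate: float,
                       seed: int) -> dict[str, int]:
    """Mk-evolved tip states (uniform root), as taxon -> state index."""
    if k < 2:
        raise ValueError("need at least two states")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    if rate == 0:
        root_state = int(rng.integers(k))
        return {t: root_state for t in tree.tip_labels()}
    model = build_model("poisson", k)
    scaled = tree.copy()
    for n in scaled.postorder():
        n.length *= rate
    out = _evolve(scaled, model, 1, rng)
    return {t: int(v[0]) for t, v in out.items()}


def table1_fixture() -> pd.DataFrame:
    """The packaged replica of the study's taxon table.

    66 rows (63 ingroup across 12 Ascomycota classes, 3 outgroup), with
    SSU/LSU species names and GenBank accessions and an ingroup flag.
    """
    path = resources.files("strucphy.data") / "table1.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")
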