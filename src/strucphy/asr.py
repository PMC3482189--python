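"""Ancestral state reconstruction of discrete morphological characters.

Characters (e.g. the ascus dehiscence mechanism, or ascoma shape) are
mapped onto a support-annotated phylogeny.  Weakly supported internal
edges (bootstrap below a threshold, strictly) are collapsed into soft
polytomies first, so reconstructions are not conditioned on unresolved
topology.  Two reconstructions are reported per internal node:

* ML — marginal posterior state probabilities under the one-parameter
  symmetric Markov model (Mk), with the single rate fitted by maximum
  likelihood on the fixed tree;
* MP — the set of states used by at least one most-parsimonious
  reconstruction (unit-cost, exact on polytomies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from . import parsimony
from .models import build_model
from .trees import Node, Phylogeny


@dataclass
class MorphCharacter:
    """A discrete character: ordered state labels plus tip assignments."""

    name: str
    states: list[str]
    definitions: list[str] = field(default_factory=list)
    tip_assignments: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.states)
        for taxon, s in self.tip_assignments.items():
            if s is not None and not (0 <= s < k):
                raise ValueError(f"state {s} of {taxon!r} out of range for {k} states")

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass
class ASRResult:
    """Per-internal-node reconstructions on the (post-collapse) tree.

    Node keys are postorder indices into ``tree.postorder()``; each node
    also reports the tip set below it so results can be matched across
    tree drawings.
    """

    tree: Phylogeny
    character: MorphCharacter
    ml_probabilities: dict[int, np.ndarray]
    mp_sets: dict[int, set[int]]
    mk_rate: float | None = None

    def report_tsv(self) -> str:
        nodes = self.tree.postorder()
        lines = ["node\tclade_tips\t" +
                 "\t".join(f"P({s})" for s in self.character.states) + "\tmp_states"]
        for i, n in enumerate(nodes):
            if n.is_tip or i not in self.ml_probabilities:
                continue
            below = sorted(
                t.label for t in Phylogeny(n).tips()
            ) if n.parent is not None else sorted(self.tree.tip_labels())
            probs = "\t".join(f"{p:.4f}" for p in self.ml_probabilities[i])
            mp = ",".join(self.character.states[s] for s in sorted(self.mp_sets[i]))
            lines.append(f"{i}\t{'|'.join(below)}\t{probs}\t{mp}")
        return "\n".join(lines) + "\n"


def collapse_weak_nodes(tree: Phylogeny, threshold_percent: float = 50.0,
                        assume_unsupported: float | None = None) -> Phylogeny:
    """Contract internal edges with support strictly below the threshold.

    An edge at exactly the threshold is retained.  Contracted edges donate
    their children directly to the parent (branch lengths of the children
    are untouched; the contracted edge's own length disappears with it).
    Edges lacking a support value raise unless ``assume_unsupported``
    supplies a stand-in value.
    """
    t = tree.copy()
    for node in t.postorder():
        if node.is_tip or node.parent is None:
            continue
        support = node.support
        if support is None:
            if assume_unsupported is None:
                raise ValueError("internal edge without support value; "
                                 "pass assume_unsupported to override")
            support = assume_unsupported
        if support < threshold_percent:
            parent = node.parent
            pos = parent.children.index(node)
            parent.children[pos:pos + 1] = node.children
            for c in node.children:
                c.parent = parent
    return Phylogeny(t.root)


def _tip_column(tree: Phylogeny, char: MorphCharacter) -> dict[str, int]:
    missing = [t for t in char.tip_assignments if t not in set(tree.tip_labels())]
    if missing:
        raise ValueError(f"character taxa absent from tree: {sorted(missing)}")
    return {t: (-1 if s is None else s)
            for t, s in char.tip_assignments.items()}


def mk_asr_ml(tree: Phylogeny, char: MorphCharacter,
              fit_rate: bool = True) -> ASRResult:
    """Marginal ML ancestral states under the Mk model.

    The symmetric k-state model has one free parameter, an overall rate
    multiplier applied to the tree's branch lengths; it is fitted by
    Brent search on the Felsenstein likelihood of the character, then
    marginal posteriors are obtained with one up-pass and one down-pass.
    """
    k = char.k
    column = _tip_column(tree, char)
    tips = tree.tip_labels()
    observed = {s for s in column.values() if s >= 0}
    nodes = tree.postorder()
    index = {id(n): i for i, n in enumerate(nodes)}

    def up_partials(rate: float):
        model = build_model("poisson", k)
        P = {i: model.transition_matrix(n.length, rate)
             for i, n in enumerate(nodes) if n.parent is not None}
        up: dict[int, np.ndarray] = {}
        loglik = 0.0
        for i, n in enumerate(nodes):
            if n.is_tip:
                s = column.get(n.label, -1)
                v = np.ones(k) if s < 0 else np.eye(k)[s]
            else:
                v = np.ones(k)
                for c in n.children:
                    ci = index[id(c)]
                    v = v * (P[ci] @ up[ci])
                scal = v.max()
                if scal > 0:
                    v = v / scal
                    loglik += np.log(scal)
            up[i] = v
        pi = np.full(k, 1.0 / k)
        root_l = float(pi @ up[len(nodes) - 1])
        return up, P, loglik + np.log(max(root_l, 1e-300))

    rate = 1.0
    if fit_rate and len(observed) > 1:
        res = minimize_scalar(lambda lr: -up_partials(float(np.exp(lr)))[2],
                              bounds=(np.log(1e-4), np.log(1e4)),
                              method="bounded", options={"xatol": 1e-6})
        rate = float(np.exp(res.x))
    elif len(observed) <= 1:
        warnings.warn("character is constant on the tree; "
                      "ML reconstruction is degenerate")
        rate = 1e-8

    up, P, _ = up_partials(rate)
    pi = np.full(k, 1.0 / k)
    down: dict[int, np.ndarray] = {len(nodes) - 1: pi.copy()}
    for n in reversed(nodes):
        if n.is_tip:
            continue
        i = index[id(n)]
        msgs = {id(c): P[index[id(c)]] @ up[index[id(c)]] for c in n.children}
        for c in n.children:
            if c.is_tip:
                continue
            sib = np.ones(k)
            for b in n.children:
                if b is not c:
                    sib = sib * msgs[id(b)]
            # symmetric model: P is its own transpose up to reversibility
            d = P[index[id(c)]].T @ (down[i] * sib)
            m = d.max()
            down[index[id(c)]] = d / m if m > 0 else d
    ml_probs: dict[int, np.ndarray] = {}
    for n in nodes:
        if n.is_tip:
            continue
        i = index[id(n)]
        joint = up[i] * down[i]
        total = joint.sum()
        ml_probs[i] = joint / total if total > 0 else np.full(k, 1.0 / k)

    mp = parsimony.mpr_sets(tree, column, k)
    return ASRResult(tree=tree, character=char, ml_probabilities=ml_probs,
                     mp_sets=mp, mk_rate=rate)


def fitch_asr_mp(tree: Phylogeny, char: MorphCharacter) -> ASRResult:
    """MP-only reconstruction: per-node most-parsimonious state sets.

    The reported "pie fraction" convention is 1/|set| per member state,
    which the probability vectors here encode directly.
    """
    column = _tip_column(tree, char)
    mp = parsimony.mpr_sets(tree, column, char.k)
    probs = {i: np.array([1.0 / len(s) if j in s else 0.0
                          for j in range(char.k)])
             for i, s in mp.items()}
    return ASRResult(tree=tree, character=char, ml_probabilities=probs,
                     mp_sets=mp, mk_rate=None)


# -- packaged characters of the Ascomycota study ------------------------

ASCUS_STATES = [
    "Schizosaccharomyces-Saccharomyces",
    "Taphrina-Neolecta",
    "Orbilia",
    "Operculate",
    "Bitunicate",
    "Inoperculate",
]
ASCUS_DEFINITIONS = [
    "base and top not differentiated; spore release by ascus wall deliquescence",
    "spore release by an apical slit",
    "spore release by tearing of the flattened apex of the ascal wall",
    "spore release by an apical lid",
    "outer and inner wall differentiated during spore release",
    "spore release through an apical pore",
]
ASCOMA_STATES = ["Absent", "With exposed hymenium", "Ostiolar or sealed"]


def builtin_characters() -> tuple[MorphCharacter, MorphCharacter]:
    """The two packaged morphological characters for the 66-taxon table.

    Ascus dehiscence mechanism (six states) and ascoma shape (three
    states), assigned per taxon from the class-level descriptions with
    the documented exceptions; the three non-ascomycete outgroup taxa are
    missing for the ascus character and 'Absent' for ascoma.
    """
    text = (resources.files("strucphy.data") / "characters.tsv").read_text()
    ascus: dict[str, int | None] = {}
    ascoma: dict[str, int | None] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("taxon\t"):
            continue
        taxon, _cls, a, f = line.split("\t")[:4]
        ascus[taxon] = None if a == "?" else ASCUS_STATES.index(a)
        ascoma[taxon] = None if f == "?" else ASCOMA_STATES.index(f)
    return (
        MorphCharacter("ascus_dehiscence", ASCUS_STATES, ASCUS_DEFINITIONS, ascus),
        MorphCharacter("ascoma_shape", ASCOMA_STATES,
                       ["no fruitbody", "open hymenium (apothecial or clavate)",
                        "perithecial/cleistothecial"], ascoma),
    )
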