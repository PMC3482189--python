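"""Node collapsing and ancestral state reconstruction (Mk ML + MP)."""

import numpy as np
import pytest

from strucphy.asr import (
    ASCOMA_STATES,
    ASCUS_STATES,
    MorphCharacter,
    builtin_characters,
    collapse_weak_nodes,
    fitch_asr_mp,
    mk_asr_ml,
)
from strucphy.models import build_model
from strucphy.trees import Node, Phylogeny

from conftest import all_topologies, enumerate_likelihood


def supported_tree(supports):
    """((A,B)s1,(C,D)s2); with given supports."""
    t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    for node, s in zip(t.internal_edges(), supports):
        node.support = s
    return t


class TestCollapse:
    def test_full_support_unchanged(self):
        t = supported_tree([100, 100])
        assert collapse_weak_nodes(t, 50).rf_distance(t) == 0

    def test_weak_edge_contracted(self):
        t = supported_tree([49, 80])
        c = collapse_weak_nodes(t, 50)
        assert len(c.splits()) == 1
        assert len(c.internal_nodes()) == len(t.internal_nodes()) - 1

    def test_exactly_threshold_retained(self):
        t = supported_tree([50, 50])
        assert collapse_weak_nodes(t, 50).rf_distance(t) == 0

    def test_unsupported_edge_rejected_unless_flagged(self):
        t = supported_tree([None, 90])
        with pytest.raises(ValueError):
            collapse_weak_nodes(t, 50)
        assert collapse_weak_nodes(t, 50, assume_unsupported=100.0)

    def test_tips_and_leaf_set_untouched(self):
        t = supported_tree([10, 10])
        c = collapse_weak_nodes(t, 50)
        assert sorted(c.tip_labels()) == sorted(t.tip_labels())


class TestMkAsr:
    def test_symmetric_tips_give_half_half_root(self):
        t = Phylogeny.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        char = MorphCharacter("c", ["0", "1"],
                              tip_assignments={"A": 0, "B": 1, "C": 0, "D": 1})
        res = mk_asr_ml(t, char)
        root_idx = len(t.postorder()) - 1
        assert np.allclose(res.ml_probabilities[root_idx], [0.5, 0.5], atol=1e-9)

    def test_constant_character_degenerate(self):
        t = Phylogeny.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        char = MorphCharacter("c", ["x", "y", "z"],
                              tip_assignments=dict.fromkeys("ABCD", 1))
        with pytest.warns(UserWarning):
            res = mk_asr_ml(t, char)
        for probs in res.ml_probabilities.values():
            assert np.argmax(probs) == 1 and probs[1] > 1 / 3

    @pytest.mark.parametrize("k", [2, 3])
    def test_marginals_match_enumeration(self, k, rng):
        """Up-down marginals equal brute-force joint summation restricted
        to each node state, on ≤5-tip trees."""
        model = build_model("poisson", k)
        for tree in all_topologies(list("ABCDE"))[::4]:
            for n in tree.postorder():
                if n.parent is not None:
                    n.length = float(rng.uniform(0.05, 0.6))
            tips = tree.tip_labels()
            column = {t: int(rng.integers(0, k)) for t in tips}
            char = MorphCharacter("c", [str(i) for i in range(k)],
                                  tip_assignments=column)
            res = mk_asr_ml(tree, char, fit_rate=False)
            nodes = tree.postorder()
            total = enumerate_likelihood(tree, column, model)
            for i, node in enumerate(nodes):
                if node.is_tip:
                    continue
                marg = []
                for s in range(k):
                    # clamp node to state s by brute force
                    acc = 0.0
                    import itertools
                    internal = [n for n in nodes if not n.is_tip]
                    for assign in itertools.product(range(k), repeat=len(internal)):
                        if assign[internal.index(node)] != s:
                            continue
                        state = {id(n): a for n, a in zip(internal, assign)}
                        for n in nodes:
                            if n.is_tip:
                                state[id(n)] = column[n.label]
                        P = {id(n): model.transition_matrix(n.length)
                             for n in nodes if n.parent is not None}
                        prob = model.frequencies[state[id(nodes[-1])]]
                        for n in nodes:
                            if n.parent is not None:
                                prob *= P[id(n)][state[id(n.parent)], state[id(n)]]
                        acc += prob
                    marg.append(acc / total)
                assert np.allclose(res.ml_probabilities[i], marg, atol=1e-8)

    def test_label_permutation_equivariance(self, rng):
        t = Phylogeny.from_newick("((A:0.3,B:0.2):0.15,(C:0.25,D:0.1):0.2);")
        assign = {"A": 0, "B": 2, "C": 1, "D": 0}
        perm = [2, 0, 1]  # state i -> perm[i]
        char1 = MorphCharacter("c", list("xyz"), tip_assignments=assign)
        char2 = MorphCharacter("c", list("xyz"),
                               tip_assignments={t_: perm[s] for t_, s in assign.items()})
        r1 = mk_asr_ml(t, char1)
        r2 = mk_asr_ml(t, char2)
        for i in r1.ml_probabilities:
            p1 = r1.ml_probabilities[i]
            p2 = r2.ml_probabilities[i]
            assert np.allclose([p1[s] for s in range(3)],
                               [p2[perm[s]] for s in range(3)], atol=1e-6)
            assert {perm[s] for s in r1.mp_sets[i]} == r2.mp_sets[i]


class TestFitchAsr:
    def test_conflicting_quartet_root(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        char = MorphCharacter("c", ["0", "1"],
                              tip_assignments={"A": 0, "B": 1, "C": 0, "D": 1})
        res = fitch_asr_mp(t, char)
        root_idx = len(t.postorder()) - 1
        assert res.mp_sets[root_idx] == {0, 1}
        assert np.allclose(res.ml_probabilities[root_idx], [0.5, 0.5])

    def test_constant_tips(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        char = MorphCharacter("c", ["0", "1"], tip_assignments=dict.fromkeys("ABCD", 0))
        res = fitch_asr_mp(t, char)
        assert all(s == {0} for s in res.mp_sets.values())

    def test_polytomy_after_collapse(self):
        t = supported_tree([30, 90])
        c = collapse_weak_nodes(t, 50)
        char = MorphCharacter("c", ["0", "1"],
                              tip_assignments={"A": 0, "B": 1, "C": 1, "D": 1})
        res = fitch_asr_mp(c, char)
        root_idx = len(c.postorder()) - 1
        assert res.mp_sets[root_idx] == {1}


def supported_tree_with(supports):
    return supported_tree(supports)


class TestBuiltinCharacters:
    def test_state_counts(self):
        ascus, ascoma = builtin_characters()
        assert len(ascus.states) == 6
        assert len(ascoma.states) == 3
        assert ascus.states == ASCUS_STATES
        assert ascoma.states == ASCOMA_STATES

    def test_ingroup_fully_coded(self):
        from strucphy.simulate import table1_fixture
        tbl = table1_fixture()
        ingroup = tbl[tbl.group == "ingroup"].ssu_species
        ascus, ascoma = builtin_characters()
        for taxon in ingroup:
            assert ascus.tip_assignments[taxon] is not None
            assert ascoma.tip_assignments[taxon] is not None

    def test_documented_exceptions(self):
        ascus, ascoma = builtin_characters()
        exposed = ASCOMA_STATES.index("With exposed hymenium")
        sealed = ASCOMA_STATES.index("Ostiolar or sealed")
        assert ascoma.tip_assignments["Leotia lubrica"] == exposed
        assert ascoma.tip_assignments["Caespitotheca forestalis"] == sealed
        assert ascoma.tip_assignments["Erysiphe mori"] == sealed
        # outgroups: no ascus, no fruitbody
        assert ascus.tip_assignments["Mucor racemosus"] is None
        assert ascoma.tip_assignments["Mucor racemosus"] == 0
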