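"""Tree container, NNI moves, search, bootstrap and consensus."""

import dendropy
import numpy as np
import pytest

from strucphy.search import (
    SearchConfig,
    bootstrap,
    majority_consensus,
    search,
    split_frequencies,
)
from strucphy.simulate import SimSpec, simulate_alignment, simulate_tree
from strucphy.structure import recode_alignment
from strucphy.models import build_model
from strucphy.trees import Phylogeny, robinson_foulds

from conftest import all_topologies


class TestPhylogeny:
    def test_newick_roundtrip(self):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.06,E:0.7);"
        t = Phylogeny.from_newick(nwk)
        t2 = Phylogeny.from_newick(t.to_newick())
        assert t.rf_distance(t2) == 0
        assert sorted(t2.tip_labels()) == list("ABCDE")

    def test_support_parsed_from_internal_labels(self):
        t = Phylogeny.from_newick("((A:1,B:1)87:1,C:1,D:1);")
        (node,) = [n for n in t.internal_edges()]
        assert node.support == 87.0

    def test_rf_distance_against_dendropy(self):
        trees = all_topologies(list("ABCDEF"))[:12]
        tns = dendropy.TaxonNamespace()
        for a in trees[::3]:
            for b in trees[1::4]:
                da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                                       taxon_namespace=tns)
                db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                                       taxon_namespace=tns)
                da.encode_bipartitions(); db.encode_bipartitions()
                expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
                assert a.rf_distance(b) == expected

    def test_nni_neighborhood(self):
        # unrooted 4-taxon tree: 1 internal edge, 2 NNI neighbors, which
        # together with the original cover all 3 topologies
        quartets = all_topologies(list("ABCD"))
        t = quartets[0]
        nbs = t.nni_neighbors()
        assert len(nbs) == 2
        seen = {frozenset(x.splits()) for x in nbs} | {frozenset(t.splits())}
        assert seen == {frozenset(q.splits()) for q in quartets}

    def test_nni_preserves_tips(self):
        t = all_topologies(list("ABCDEF"))[10]
        for nb in t.nni_neighbors():
            assert sorted(nb.tip_labels()) == sorted(t.tip_labels())
            assert nb.rf_distance(t) == 2


class TestSearch:
    def test_compatible_matrix_mp(self):
        """A perfectly compatible binary matrix: MP recovers its split
        system at total length = number of characters."""
        taxa = list("ABCDEF")
        splits = [frozenset("DEF"), frozenset("EF"), frozenset("BC")]
        codes = np.array([[1 if t in s else 0 for s in splits] for t in taxa])
        trees, score = search((taxa, codes), None,
                              SearchConfig(criterion="mp", n_starts=5, seed=3))
        assert score == len(splits)
        assert set(trees[0].splits()) == set(splits)

    def test_determinism(self):
        spec = SimSpec(n_tips=6, n_loop_sites=60, n_stem_pairs=40, seed=11)
        tree = simulate_tree(spec)
        taxa, rows, pt, ann = simulate_alignment(tree, spec)
        sa = recode_alignment(taxa, rows, ann)
        cfg = SearchConfig(criterion="mp", n_starts=3, seed=5)
        a, sa_score = search(sa, None, cfg)
        b, sb_score = search(sa, None, cfg)
        assert sa_score == sb_score
        assert a[0].to_newick() == b[0].to_newick()

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            search((list("ABC"), np.zeros((3, 5), int)), None,
                   SearchConfig(criterion="mp", seed=1))

    def test_ml_recovers_simulated_topology(self):
        spec = SimSpec(n_tips=6, n_loop_sites=100, n_stem_pairs=150, seed=97)
        tree = simulate_tree(spec)
        taxa, rows, pt, ann = simulate_alignment(tree, spec)
        sa = recode_alignment(taxa, rows, ann)
        model = build_model("poisson", 20, "empirical", data=sa.codes)
        best, lnl = search(sa, model, SearchConfig(criterion="ml", n_starts=2, seed=2))
        assert best[0].rf_distance(tree) == 0


class TestBootstrap:
    def test_seeded_reproducible(self):
        spec = SimSpec(n_tips=5, n_loop_sites=40, n_stem_pairs=30, seed=8)
        tree = simulate_tree(spec)
        taxa, rows, pt, ann = simulate_alignment(tree, spec)
        sa = recode_alignment(taxa, rows, ann)
        cfg = SearchConfig(criterion="mp", n_starts=1, seed=21, bootstrap_replicates=5)
        a = [t.to_newick() for t in bootstrap(sa, cfg)]
        b = [t.to_newick() for t in bootstrap(sa, cfg)]
        assert a == b

    def test_strong_signal_split_everywhere(self):
        """One long internal branch: its split should appear in ≈ all
        bootstrap replicates."""
        spec = SimSpec(n_tips=6, n_loop_sites=150, n_stem_pairs=150, seed=30)
        tree = simulate_tree(spec)
        # stretch one internal edge hard
        edge = max(tree.internal_edges(), key=lambda n: n.length)
        edge.length = 2.0
        taxa, rows, pt, ann = simulate_alignment(tree, spec)
        sa = recode_alignment(taxa, rows, ann)
        cfg = SearchConfig(criterion="mp", n_starts=1, seed=4, bootstrap_replicates=20)
        boots = bootstrap(sa, cfg)
        freqs = split_frequencies(boots)
        split = next(s for s, n in tree.splits().items() if n is edge)
        assert freqs.get(split, 0.0) >= 0.95


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = all_topologies(list("ABCDE"))[4]
        cons = majority_consensus([t.copy() for _ in range(10)])
        assert cons.rf_distance(t) == 0
        assert all(n.support == 100.0 for n in cons.internal_edges())

    def test_total_disagreement_star(self):
        quartets = all_topologies(list("ABCD"))
        cons = majority_consensus([quartets[0], quartets[1]])
        assert len(cons.splits()) == 0

    def test_split_frequencies_brute_force(self):
        """Hashed split counting equals brute-force pairwise comparison."""
        trees = all_topologies(list("ABCDEF"))[:7]
        freqs = split_frequencies(trees)
        for split, f in freqs.items():
            count = sum(split in t.splits() for t in trees)
            assert f == count / len(trees)

    def test_annotation_onto_target(self):
        trees = all_topologies(list("ABCDE"))
        target = trees[0]
        sample = [trees[0]] * 3 + [trees[1]]
        annotated = majority_consensus(sample, annotate_onto=target)
        supports = sorted(n.support for n in annotated.internal_edges())
        assert all(0 <= s <= 100 for s in supports)
        assert 100.0 in supports or 75.0 in supports

    def test_consensus_against_dendropy(self):
        """Majority-rule consensus topology matches dendropy's on a
        mixed tree sample."""
        trees = all_topologies(list("ABCDE"))
        # counts chosen so no split sits exactly at 50% (tie conventions
        # differ between implementations)
        sample = [trees[0]] * 6 + [trees[3]] * 3 + [trees[7]] * 2
        cons = majority_consensus(sample)
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList([
            dendropy.Tree.get(data=t.to_newick(), schema="newick",
                              taxon_namespace=tns) for t in sample])
        dcons = tl.consensus(min_freq=0.5)
        expected = Phylogeny.from_dendropy(dcons)
        assert cons.rf_distance(expected) == 0

    def test_taxon_mismatch_rejected(self):
        a = all_topologies(list("ABCD"))[0]
        b = all_topologies(list("ABCE"))[0]
        with pytest.raises(ValueError):
            majority_consensus([a, b])


def test_robinson_foulds_function():
    assert robinson_foulds("((A,B),(C,D));", "((A,C),(B,D));") == 2
    assert robinson_foulds("((A,B),(C,D));", "((B,A),(D,C));") == 0
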