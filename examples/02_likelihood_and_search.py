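"""Infer a phylogeny from recoded structure data by maximum likelihood.

Simulates a 6-taxon dataset with known tree, recodes it, and runs the
random-addition + NNI search under the Poisson(20) model, then compares
the result with the generating topology.
"""

from strucphy import (
    SearchConfig,
    SimSpec,
    build_model,
    recode_alignment,
    search,
    simulate_alignment,
    simulate_tree,
)

spec = SimSpec(n_tips=6, n_loop_sites=100, n_stem_pairs=150, seed=97)
true_tree = simulate_tree(spec)
taxa, rows, pt, ann = simulate_alignment(true_tree, spec)
sa = recode_alignment(taxa, rows, ann)

model = build_model("poisson", 20, "empirical", data=sa.codes)
best, lnl = search(sa, model, SearchConfig(criterion="ml", n_starts=2, seed=2))

print(f"structure sites: {sa.n_sites} "
      f"({spec.n_loop_sites} loop + {spec.n_stem_pairs} stem pairs)")
print(f"best log-likelihood: {lnl:.3f}")
print(f"best tree: {best[0].to_newick()}")
rf = best[0].rf_distance(true_tree)
print(f"Robinson-Foulds distance to the generating tree: {rf}")
print("RF = 0 means the unrooted topology was recovered exactly.")
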