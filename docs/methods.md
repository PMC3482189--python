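# Methods

## The structure alphabet and recoding

A secondary-structure model is taken for one ungapped reference sequence as
a set of base pairs (i, j), i < j, each position in at most one pair
(pseudoknot tiers are parsed but receive no special treatment downstream).
Projection through the reference's gapped alignment row classifies every
alignment column as `loop` (reference residue unpaired), `stem5`/`stem3`
(reference residues paired; the two columns are mutual partners), or
`uncovered` (reference gap — the structure model is silent there).

Recoding emits one site per loop column, one per uncovered column, and one
per stem *pair*, ordered by 5′ column. Symbols: indices 0–3 are the unpaired
bases A, C, G, U; indices 4–19 the ordered doublets (5′ base first, bases
ordered A<C<G<U). All 16 doublets are valid states — non-Watson–Crick
combinations are data, not errors. T is read as U; gaps and IUPAC ambiguity
codes map to the single missing symbol `?` (a stem site is missing if either
partner is). A fixed bijection onto the amino-acid one-letter codes
(`0:A→A … 19:UU→Y`) lets recoded matrices travel as protein FASTA/PHYLIP.

Design choices made where the convention is genuinely open:

* **One site per pair, not two doublet-coded columns.** This matches the
  4 + 16 = 20 alphabet arithmetic and avoids weighting stems twice.
* **Uncovered columns are retained** and coded as unpaired bases
  (`drop_uncovered` removes them instead); there is no principled way to
  assign them pairing partners.
* **Ambiguity codes become missing data** rather than partial state sets:
  the 20-state downstream models use a single missing convention.

## Likelihood engine

Models are reversible k-state CTMCs, `Q_ij = s_ij π_j`, rows summing to
zero, normalized to unit expected rate at equilibrium. Three families cover
the analyses: `poisson` (all exchangeabilities equal — Jukes–Cantor/Mk for
any k, the default for the 20-state structure arm), `fixed_exchangeability`
(a PAML-layout table, e.g. LG, for fidelity runs with empirical protein
models), and `gtr` (the 4-state nucleotide comparison arm). Frequencies are
equal, empirical (pooled counts over the whole matrix, missing excluded,
plus a 0.5 pseudo-count so the chain stays irreducible), or free.

Rate heterogeneity uses the mean-of-slice discrete-Γ approximation
(equal-probability categories of Γ(α, α); category mean via the Γ(α+1, α)
CDF; default 4 categories — the field standard, as the source analyses do
not state a count) and an optional invariant-site fraction.

The log-likelihood is Felsenstein pruning with per-node rescaling and site
pattern compression (bit-identical to the uncompressed value). Missing tips
contribute partial vectors of ones; no columns are deleted. Transition
matrices come from the eigendecomposition of the symmetrized rate matrix,
cached per model.

Optimization is coordinate-wise: branch lengths by Brent searches on the
per-edge 1-D likelihood (outside/inside partials are recomputed freshly per
branch, so each Brent evaluation touches a single edge — the standard trick
that makes branch optimization ~20× cheaper than naive full pruning), then
Γ shape, invariant fraction and frequencies, cycling until the gain drops
below 1e−6 lnL units (max 100 cycles). Branch lengths are bounded to
[1e−8, 20] expected substitutions. The returned lnL never decreases: every
accepted Brent move is checked against the incumbent value.

## Parsimony

Scores and ancestral sets use the unit-cost Sankoff dynamic programme,
which is exact on multifurcating trees and with missing data (a missing tip
admits every state at zero cost) and vectorizes over columns. Per-node MPR
state sets combine upward costs with downward costs, so a state is reported
iff some globally minimum-length reconstruction uses it. (The set-based
Fitch up/down passes are equivalent on binary trees; Sankoff was chosen
because support-collapsed trees are multifurcating.)

## Tree search, bootstrap, consensus

Starting trees come from seeded random stepwise addition under parsimony
(one per start; default 10 starts, mirroring classic random-addition
protocols), followed by NNI hill-climbing. NNI was chosen over TBR/SPR as
adequate at the tested problem sizes and far simpler; the multi-start
design compensates for its smaller neighbourhood. Under ML, candidates are
scored with a cheap 3-cycle branch-length fit (already-visited topologies
are cached by split set), the winner gets a full optimization; under MP the
Sankoff length is exact and cheap. All equally best topologies across
starts are retained.

The bootstrap resamples *coded* sites with replacement — a stem doublet is
one resampling unit, preserving the coding's independence assumption — and
reruns the search per replicate, all seeded from one generator. Replicate
counts default to 100 (ML) and 1,000 (MP) and are config-overridable; tests
and the `--profile test` pipeline use reduced counts. The majority-rule
consensus keeps splits in strictly more than half of the input trees
(splits at exactly 50% are dropped: two maximally conflicting trees give a
star); alternatively, split frequencies are mapped as percentages onto a
target tree's internal edges.

## Ancestral state reconstruction

Internal edges with support strictly below the threshold (default 50%) are
contracted into soft polytomies before reconstruction; an edge at exactly
the threshold is retained. Contraction redistributes nothing: children keep
their own branch lengths and the contracted edge's length vanishes with it
(collapsing operates on topology, as in Mesquite-style workflows).

ML reconstruction uses the Mk model — the symmetric one-parameter k-state
chain — with a single rate multiplier fitted per character by Brent search
(bounds 1e−4 to 1e4 on the rate) on the fixed tree, then marginal posterior
probabilities at every internal node from one up-pass and one down-pass.
Constant characters are degenerate (warned; near-zero rate, all mass on the
observed state). MP reconstruction reports the Sankoff MPR set per node,
with pie fractions 1/|set|. A very large fitted rate is a diagnostic worth
watching: it means the likelihood surface is flat in the rate and marginals
drift toward uniform, which is the honest ML answer for strongly
homoplastic characters.

The two packaged characters encode the study system's class-level
descriptions: ascus dehiscence (six states:
Schizosaccharomyces-Saccharomyces deliquescent, Taphrina-Neolecta apical
slit, Orbilia apex tearing, operculate lid, bitunicate two-walled,
inoperculate pore) and ascoma shape (absent / exposed hymenium / ostiolar
or sealed), with documented exceptions (Caespitotheca and Erysiphe are
sealed within otherwise apothecial Leotiomycetes). Dothideomycetes are
coded ostiolar/sealed at class level although part of the class is
apothecial; the apothecial subset is not enumerated taxon-by-taxon in the
source descriptions, so the fixture keeps the class-level coding and says
so in its comments rather than guessing. The three non-ascomycete outgroup
taxa have no asci (missing) and no fruitbodies (absent).

## Synthetic data

The generator produces what the recoder assumes: a seeded Yule tree
(lineages split at exponential times until the tip count is reached, tips
extended to the final time, branch lengths rescaled to a root-to-tip height
in substitutions/site), loop sites evolved iid under a 4-state model, and
each stem pair evolved as a *single* 16-state doublet site then written out
as its two nucleotide columns. Compensatory evolution therefore holds
exactly, and recoding the emitted alignment reproduces the simulated
doublet states verbatim (tested as a round-trip identity). Defaults: 8
tips, birth rate 1, height 0.5 substitutions/site root-to-tip (rRNA is
conserved; phylum-deep divergences remain well below saturation), 100 loop
sites, 200 stem pairs. Characters evolve under Mk from a uniform root. All
randomness flows from one explicit seed through a named generator.

What the generator does **not** emulate: indels and alignment error (the
simulation is ungapped), among-site rate variation unless a Γ model is
passed in, structure misannotation, and base-composition bias. Passing
recovery tests therefore show the pipeline is correct *under its own
assumptions*, not that real alignments are this clean.

Known limitation worth stating plainly: at the default recovery conditions
(8-tip Yule trees, 300 structure sites) the exact-topology recovery rate of
ML search is roughly two-thirds, and the shortfall is information-theoretic, not
algorithmic — failing replicates have a wrong tree whose optimized
likelihood exceeds the generating tree's, and re-scoring under the true
generating (partitioned) model usually agrees. Yule trees routinely contain
internal edges of 1–4% of the tree height, which carry only a handful of
expected substitutions at this alignment length; no estimator recovers
those edges reliably. Longer alignments or trees without near-zero internal
edges push recovery toward 100%.

## Problem sizes used in tests

Oracle tests enumerate all unrooted topologies with ≤ 5 tips (brute-force
sums over internal states for k ∈ {2, 4, 20}); searches and bootstraps in
the unit suite use 5–8 taxa, 60–300 coded sites, and 4–50 replicates; the
recovery experiment uses 20 seeded replicates at the generator defaults;
rate recovery uses 200 characters on 16 tips. These sizes were chosen so
the full suite exercises every stage in a few minutes while keeping the
statistical assertions well-powered.
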