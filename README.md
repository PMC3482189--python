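# strucphy

Secondary-structure-aware rRNA phylogenetics for Python.

Ribosomal RNA folds into conserved stems (base-paired helices) and loops
(unpaired stretches). In a stem, the two partner positions do not evolve
independently — a substitution on one side is frequently compensated on the
other so that pairing is preserved. Treating the two columns of a base pair
as independent 4-state characters both double-counts the evidence and hides
the compensatory signal. `strucphy` instead recodes a nucleotide alignment
over a **20-symbol structure alphabet**: 4 symbols for unpaired bases
(A, C, G, U) and 16 for ordered base-pair doublets (AA … UU), one site per
pair. Because the alphabet has exactly 20 states, the recoded matrix maps
bijectively onto the amino-acid alphabet and can be analysed with any
20-state phylogenetics machinery.

The package implements the full analysis around that idea:

* **Recoding** — parse a secondary structure (dot-bracket, CT, bpseq) for a
  reference taxon, project it through the reference's gapped alignment row,
  and emit the 20-state matrix plus a site map.
* **Inference** — k-state reversible substitution models (Poisson/Mk, fixed
  exchangeability tables such as LG in PAML format, GTR) with discrete-Γ
  rates and invariant sites; Felsenstein-pruning log-likelihood; branch
  length and parameter optimization; Fitch/Sankoff parsimony; random-addition
  + NNI tree search under ML or MP; site-resampling bootstrap and
  majority-rule consensus with support annotation. A stem doublet site is a
  single bootstrap resampling unit.
* **Ancestral state reconstruction** — collapse internal edges below a
  support threshold (strictly below; 50 stays), then reconstruct discrete
  morphological characters by marginal ML under the one-parameter Mk model
  and by most-parsimonious state sets. Two characters from the Ascomycota
  study system ship with the package (ascus dehiscence mechanism, 6 states;
  ascoma shape, 3 states) together with its 66-taxon metadata table.
* **Simulation** — seeded Yule trees, loop sites under a 4-state model and
  stem pairs as single 16-state doublet sites (compensatory change by
  construction), plus Mk-evolved tip characters, so every stage is testable
  without downloads.

For a site with unpaired base `x` the likelihood uses the standard 4-state
CTMC; a stem site carries the doublet state `(x₅′, x₃′)` and evolves under a
16-state chain. All models are normalized to one expected substitution per
site per unit branch length, with rate matrix `Q_ij = s_ij π_j` from
symmetric exchangeabilities `s` and frequencies `π`.

## Worked example

```sh
python examples/01_recode_structure_alphabet.py
```

prints, for a toy hairpin alignment:

```
site map (site, role, source columns):
  0	stem	(0, 10)
  1	stem	(1, 9)
  2	stem	(2, 8)
  3	loop	(3,)
  ...
recoded matrix (20-letter amino-acid encoding, '?' = missing):
  ref   PLPATAA?
  tax1  PLPATAAA
  tax2  PSPATAA?
  tax3  PLHATAA?
```

Each stem pair became one site: `P` is the G:C doublet, `S` the compensatory
U:A in `tax2` (one site difference, not two), and `H` the one-sided A.U in
`tax3`; `?` marks a gapped partner. The other examples walk through ML
search on simulated data (`02`, prints the best log-likelihood, the tree and
its Robinson–Foulds distance 0 to the generating topology), bootstrap
support annotation (`03`), ancestral state reconstruction of the packaged
characters on a class-level backbone (`04`), and the end-to-end pipeline
with its hash manifest (`05`).

The same stages are scriptable from the shell:

```sh
strucphy pipeline aln.fasta structure.db --reference Saccharomyces_cerevisiae \
    --characters ascus.tsv --profile test --seed 1 --out-dir run
```

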