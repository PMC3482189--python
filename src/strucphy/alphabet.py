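"""The 20-symbol structure alphabet.

Nucleotide alignments are recoded over an alphabet with 4 symbols for
unpaired bases (A, C, G, U) and 16 symbols for ordered base-pair doublets
(AA, AC, ..., UU), one symbol per structural base pair.  Because the
alphabet has exactly 20 states, recoded matrices can be written as
amino-acid alignments and analysed with any 20-state protein
phylogenetics software; the bijection onto the one-letter amino-acid
codes used for that interop is fixed here.
"""

from __future__ import annotations

BASES = "ACGU"

#: symbols 0-3: unpaired bases; 4-19: ordered doublets (5' base first)
SYMBOLS: tuple[str, ...] = tuple(BASES) + tuple(
    b5 + b3 for b5 in BASES for b3 in BASES
)

N_STATES = 20
MISSING = "?"
#: integer sentinel for missing data in coded matrices
MISSING_INDEX = -1

#: fixed bijection symbol index -> amino-acid one-letter code
AA_LETTERS = "ACGTDEFHIKLMNPQRSVWY"

SYMBOL_TO_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
AA_TO_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}

assert len(set(AA_LETTERS)) == N_STATES

#: IUPAC nucleotide codes accepted in input alignments (beyond ACGU/T and gaps)
IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
GAP_CHARS = set("-.")


def base_index(ch: str) -> int:
    """Index of an unpaired canonical base, or MISSING_INDEX for gap/ambiguity.

    Raises ValueError for characters outside the IUPAC nucleotide set.
    """
    c = ch.upper().replace("T", "U")
    if c in "ACGU":
        return "ACGU".index(c)
    if ch in GAP_CHARS or c in IUPAC_AMBIGUITY or c == "?":
        return MISSING_INDEX
    raise ValueError(f"unknown residue character {ch!r}")


def doublet_index(ch5: str, ch3: str) -> int:
    """Symbol index of an ordered base pair; MISSING_INDEX if either side
    is a gap or ambiguity code."""
    i5 = base_index(ch5)
    i3 = base_index(ch3)
    if i5 < 0 or i3 < 0:
        return MISSING_INDEX
    return 4 + 4 * i5 + i3
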