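"""Structure parsing, projection and 20-symbol recoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strucphy.alphabet import AA_LETTERS, SYMBOLS
from strucphy.structure import (
    PairTable,
    StructureParseError,
    annotation_to_pairtable,
    from_protein_letters,
    parse_structure,
    project_to_alignment,
    recode_alignment,
    to_protein_letters,
)


class TestParseStructure:
    @pytest.mark.parametrize("text,length,pairs", [
        ("((..))", 6, {(0, 5), (1, 4)}),
        ("....", 4, set()),
        (".(.).", 5, {(1, 3)}),
        ("((.[.)).]", 9, {(0, 6), (1, 5), (3, 8)}),  # pseudoknot tier
    ])
    def test_dotbracket(self, text, length, pairs):
        pt = parse_structure(text)
        assert pt.length == length
        assert set(pt.pairs) == pairs

    @pytest.mark.parametrize("bad", ["((.", ".))", "(]"])
    def test_unbalanced_brackets_rejected(self, bad):
        with pytest.raises(StructureParseError):
            parse_structure(bad)

    def test_bpseq_roundtrip(self):
        text = "1 G 4\n2 A 0\n3 C 0\n4 C 1\n"
        pt = parse_structure(text, format_hint="bpseq")
        assert pt.length == 4 and set(pt.pairs) == {(0, 3)}

    def test_nonreciprocal_ct_rejected(self):
        text = "1 G 4\n2 A 0\n3 C 0\n4 C 2\n"
        with pytest.raises(StructureParseError):
            parse_structure(text, format_hint="bpseq")

    def test_empty_rejected(self):
        with pytest.raises(StructureParseError):
            parse_structure("   ")

    def test_position_in_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            PairTable(4, frozenset({(0, 2), (1, 2)}))


class TestProjection:
    def test_gap_shift(self):
        pt = PairTable(4, frozenset({(0, 3)}))
        ann = project_to_alignment(pt, "A-CGU")
        assert ann.role == ["stem5", "uncovered", "loop", "loop", "stem3"]
        assert ann.partner == {0: 4, 4: 0}

    def test_no_pairs_all_loop(self):
        ann = project_to_alignment(PairTable(2, frozenset()), "AC")
        assert ann.role == ["loop", "loop"]

    def test_internal_gap_between_partners(self):
        ann = project_to_alignment(PairTable(2, frozenset({(0, 1)})), "A--U")
        assert ann.role == ["stem5", "uncovered", "uncovered", "stem3"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_to_alignment(PairTable(3, frozenset()), "AC")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_projection_involution(self, seed):
        """Deleting uncovered columns and un-gapping recovers the PairTable."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        positions = list(rng.permutation(n))
        pairs = set()
        while len(positions) >= 2 and rng.random() < 0.7:
            i, j = positions.pop(), positions.pop()
            pairs.add((min(i, j), max(i, j)))
        pt = PairTable(n, frozenset(pairs))
        row = []
        res = iter("ACGU"[int(rng.integers(4))] for _ in range(n))
        for _ in range(n):
            while rng.random() < 0.2:
                row.append("-")
            row.append(next(res))
        ann = project_to_alignment(pt, "".join(row))
        assert annotation_to_pairtable(ann) == pt


class TestRecoding:
    def test_symbol_assignment(self):
        pt = PairTable(4, frozenset({(0, 3)}))
        ann = project_to_alignment(pt, "ACGU")
        sa = recode_alignment(["x"], ["ACGU"], ann)
        # sites ordered by 5' column: stem pair (A,U) then loops C, G
        assert [r for r, _ in sa.site_map] == ["stem", "loop", "loop"]
        assert SYMBOLS[sa.codes[0, 0]] == "AU"
        assert sa.codes[0, 1] == 1 and sa.codes[0, 2] == 2

    def test_gc_doublet_index(self):
        pt = PairTable(2, frozenset({(0, 1)}))
        ann = project_to_alignment(pt, "GC")
        sa = recode_alignment(["x"], ["GC"], ann)
        assert sa.codes[0, 0] == 13  # 4 + 2*4 + 1

    def test_gap_in_stem_is_missing(self):
        pt = PairTable(2, frozenset({(0, 1)}))
        ann = project_to_alignment(pt, "A-U")
        sa = recode_alignment(["x", "y"], ["A-U", "AG-"], ann)
        assert sa.codes[0, 0] == 7        # AU doublet
        assert sa.codes[1, 0] == -1       # partner gapped -> missing
        assert sa.codes[1, 1] == 2        # uncovered column coded as base G

    def test_t_equals_u_and_ambiguity_missing(self):
        ann = project_to_alignment(PairTable(2, frozenset()), "AC")
        sa = recode_alignment(["x"], ["TN"], ann)
        assert sa.codes[0, 0] == 3 and sa.codes[0, 1] == -1

    def test_unknown_residue_listed(self):
        ann = project_to_alignment(PairTable(2, frozenset()), "AC")
        with pytest.raises(ValueError, match="Z"):
            recode_alignment(["x"], ["AZ"], ann)

    def test_ragged_rejected(self):
        ann = project_to_alignment(PairTable(2, frozenset()), "AC")
        with pytest.raises(ValueError):
            recode_alignment(["x", "y"], ["AC", "A"], ann)

    def test_full_alphabet_coverage(self):
        """An input exercising every canonical symbol emits exactly
        4 unpaired and 16 paired distinct symbols."""
        bases = "ACGU"
        doublets = [a + b for a in bases for b in bases]
        n_stem = len(doublets)
        row5 = "".join(d[0] for d in doublets) + bases
        row3 = "".join(d[1] for d in doublets[::-1])
        seq = row5 + row3
        struct = "(" * n_stem + "." * 4 + ")" * n_stem
        pt = parse_structure(struct)
        ann = project_to_alignment(pt, seq)
        sa = recode_alignment(["x"], [seq], ann)
        emitted = {SYMBOLS[c] for c in sa.codes[0] if c >= 0}
        assert sum(len(s) == 1 for s in emitted) == 4
        assert sum(len(s) == 2 for s in emitted) == 16

    def test_site_count_identity(self):
        pt = PairTable(6, frozenset({(0, 5), (1, 4)}))
        ann = project_to_alignment(pt, "AA-CGUU")
        sa = recode_alignment(["x"], ["AA-CGUU"], ann)
        n_loop = sum(r == "loop" for r in ann.role)
        n_unc = sum(r == "uncovered" for r in ann.role)
        assert sa.n_sites == n_loop + n_unc + len(pt.pairs)

    def test_drop_uncovered(self):
        pt = PairTable(2, frozenset())
        ann = project_to_alignment(pt, "A-C")
        sa = recode_alignment(["x"], ["AGC"], ann, drop_uncovered=True)
        assert sa.n_sites == 2


class TestProteinLetters:
    def test_fixed_mapping_endpoints(self):
        assert AA_LETTERS[0] == "A" and AA_LETTERS[3] == "T"
        assert AA_LETTERS[19] == "Y" and AA_LETTERS[13] == "P"

    def test_roundtrip(self):
        pt = PairTable(4, frozenset({(0, 3)}))
        ann = project_to_alignment(pt, "ACGU")
        sa = recode_alignment(["x", "y"], ["ACGU", "A-GU"], ann)
        rows = to_protein_letters(sa)
        back = from_protein_letters(sa.taxa, rows, sa.site_map)
        assert np.array_equal(back.codes, sa.codes)

    def test_determinism(self):
        pt = PairTable(4, frozenset({(0, 3)}))
        ann = project_to_alignment(pt, "ACGU")
        a = recode_alignment(["x"], ["ACGU"], ann)
        b = recode_alignment(["x"], ["ACGU"], ann)
        assert to_protein_letters(a) == to_protein_letters(b)
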