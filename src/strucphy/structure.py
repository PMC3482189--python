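"""Secondary-structure parsing, projection onto alignments, and recoding.

The workflow mirrors how comparative rRNA structure models are used in
practice: a curated secondary structure is available for one reference
taxon (e.g. the *S. cerevisiae* rRNA model), and the structure is carried
onto a multiple alignment through the reference's gapped row.  Alignment
columns then fall into three roles:

* ``loop``      — the reference residue is unpaired;
* ``stem5``/``stem3`` — the reference residues form a base pair; the two
  partner columns are recoded together as a single 16-state doublet site;
* ``uncovered`` — the reference row has a gap, so the structure model says
  nothing about the column; such columns are retained and coded as
  unpaired bases (dropping them is the caller's choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    MISSING_INDEX,
    SYMBOLS,
    AA_LETTERS,
    AA_TO_INDEX,
    base_index,
    doublet_index,
)


class StructureParseError(ValueError):
    pass


@dataclass(frozen=True)
class PairTable:
    """Base pairs of an ungapped reference sequence (0-based, i < j)."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i}, {j}) out of range for length {self.length}")
            for x in (i, j):
                if x in seen:
                    raise ValueError(f"position {x} occurs in more than one pair")
                seen.add(x)

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


# bracket tiers accepted in dot-bracket strings (pseudoknot tiers are
# parsed like any other tier; downstream treatment is identical)
_OPEN = "([{<"
_CLOSE = ")]}>"


def _parse_dotbracket(text: str) -> PairTable:
    s = "".join(text.split())
    stacks: dict[int, list[int]] = {t: [] for t in range(len(_OPEN))}
    pairs = []
    for pos, ch in enumerate(s):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(pos)
        elif ch in _CLOSE:
            tier = _CLOSE.index(ch)
            if not stacks[tier]:
                raise StructureParseError(
                    f"unmatched closing bracket {ch!r} at position {pos}"
                )
            pairs.append((stacks[tier].pop(), pos))
        else:
            raise StructureParseError(
                f"invalid dot-bracket character {ch!r} at position {pos}"
            )
    for tier, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unclosed bracket {_OPEN[tier]!r} opened at position {stack[-1]}"
            )
    return PairTable(length=len(s), pairs=frozenset(pairs))


def _parse_ct_like(text: str) -> PairTable:
    """Parse CT or bpseq records (1-based position / partner columns).

    bpseq rows are ``pos base partner``; CT rows carry six columns with the
    partner in column 5.  A header line (CT) or comment lines (#) are
    skipped.  Pairing must be reciprocal.
    """
    partner_of: dict[int, int] = {}
    length = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not fields[0].isdigit():
            continue  # header / free-form comment line
        if len(fields) == 3:
            pos, pair = int(fields[0]), int(fields[2])
        elif len(fields) >= 6:
            # CT: pos base prev next pair index — but the first data row can
            # be preceded by a "<length> <title>" header already skipped above
            pos, pair = int(fields[0]), int(fields[4])
        else:
            raise StructureParseError(f"unrecognised structure row: {line!r}")
        partner_of[pos] = pair
        length = max(length, pos)
    if length == 0:
        raise StructureParseError("no structure rows found")
    pairs = set()
    for pos, pair in partner_of.items():
        if pair == 0:
            continue
        if partner_of.get(pair) != pos:
            raise StructureParseError(
                f"position {pos} pairs with {pair} but {pair} does not reciprocate"
            )
        pairs.add((min(pos, pair) - 1, max(pos, pair) - 1))
    return PairTable(length=length, pairs=frozenset(pairs))


def parse_structure(text: str, format_hint: str | None = None) -> PairTable:
    """Parse a secondary-structure document into a :class:`PairTable`.

    ``format_hint`` may be ``"dotbracket"``, ``"ct"`` or ``"bpseq"``; when
    omitted the format is sniffed (numeric first field ⇒ CT/bpseq).
    """
    if not text or not text.strip():
        raise StructureParseError("empty structure document")
    if format_hint in ("ct", "bpseq"):
        return _parse_ct_like(text)
    if format_hint in ("dotbracket", "db"):
        return _parse_dotbracket(text)
    if format_hint is not None:
        raise ValueError(f"unknown structure format {format_hint!r}")
    stripped = text.strip()
    first = stripped.split(None, 1)[0]
    if first[0].isdigit():
        return _parse_ct_like(text)
    return _parse_dotbracket(text)


LOOP, STEM5, STEM3, UNCOVERED = "loop", "stem5", "stem3", "uncovered"


@dataclass
class ColumnAnnotation:
    """Per-alignment-column structural role, with partner columns for stems."""

    n_columns: int
    role: list[str]
    partner: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.role) != self.n_columns:
            raise ValueError("role vector length != n_columns")
        for c, p in self.partner.items():
            if self.partner.get(p) != c:
                raise ValueError(f"partner map is not an involution at column {c}")
            if self.role[c] == STEM5 and not (self.role[p] == STEM3 and p > c):
                raise ValueError(f"stem5 column {c} has inconsistent partner {p}")

    @property
    def stem_pairs(self) -> list[tuple[int, int]]:
        return sorted((c, self.partner[c]) for c in range(self.n_columns)
                      if self.role[c] == STEM5)


def project_to_alignment(pt: PairTable, aligned_ref_row: str) -> ColumnAnnotation:
    """Map a reference structure through the reference's gapped alignment row.

    Columns holding paired reference residues become stem5/stem3 with mutual
    partners; unpaired residues give loop columns; reference-gap columns are
    uncovered.
    """
    if not aligned_ref_row:
        raise ValueError("empty reference row")
    col_of_residue: dict[int, int] = {}
    res = 0
    roles = []
    for col, ch in enumerate(aligned_ref_row):
        if ch in "-.":
            roles.append(UNCOVERED)
        else:
            col_of_residue[res] = col
            roles.append(LOOP)  # provisional; stems assigned below
            res += 1
    if res != pt.length:
        raise ValueError(
            f"ungapped reference length {res} != structure length {pt.length}"
        )
    partner: dict[int, int] = {}
    for i, j in pt.pairs:
        ci, cj = col_of_residue[i], col_of_residue[j]
        roles[ci], roles[cj] = STEM5, STEM3
        partner[ci] = cj
        partner[cj] = ci
    return ColumnAnnotation(n_columns=len(aligned_ref_row), role=roles, partner=partner)


@dataclass
class StructureAlignment:
    """Taxa × structure-sites matrix over the 20-symbol alphabet.

    ``codes`` holds symbol indices 0–19 with −1 for missing.  ``site_map``
    records each site's role and source column(s) in the nucleotide
    alignment: one column for loop/uncovered sites, an ordered (5', 3')
    column pair for stem sites.
    """

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_sites), int8
    site_map: list[tuple[str, tuple[int, ...]]]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.taxa), len(self.site_map)):
            raise ValueError("codes shape inconsistent with taxa/site_map")
        if self.codes.max(initial=-1) > 19 or self.codes.min(initial=0) < -1:
            raise ValueError("symbol indices must be in [-1, 19]")

    @property
    def n_sites(self) -> int:
        return len(self.site_map)

    def site_map_table(self) -> str:
        """Site map as TSV text (site, role, source columns)."""
        lines = ["site\trole\tcolumns"]
        for s, (role, cols) in enumerate(self.site_map):
            lines.append(f"{s}\t{role}\t{','.join(map(str, cols))}")
        return "\n".join(lines) + "\n"


def recode_alignment(
    taxa: list[str],
    rows: list[str],
    ann: ColumnAnnotation,
    drop_uncovered: bool = False,
) -> StructureAlignment:
    """Recode a nucleotide alignment into the 20-symbol structure alphabet.

    One site is emitted per loop column, per uncovered column (unless
    ``drop_uncovered``), and per stem pair; stem sites take the ordered
    doublet symbol of the two partner bases (all 16 ordered combinations
    are valid states, non-Watson–Crick included), with any gap or IUPAC
    ambiguity on either side coded as missing.  T is read as U.  Sites are
    ordered by their 5' source column.
    """
    if len(set(map(len, rows))) > 1:
        raise ValueError("ragged alignment: rows have unequal lengths")
    if rows and len(rows[0]) != ann.n_columns:
        raise ValueError(
            f"alignment has {len(rows[0])} columns, annotation {ann.n_columns}"
        )
    bad = sorted({ch for row in rows for ch in row.upper()
                  if ch not in set("ACGTU-.?") | set("RYSWKMBDHVN")})
    if bad:
        raise ValueError(f"unknown residue characters: {bad}")

    site_map: list[tuple[str, tuple[int, ...]]] = []
    for c in range(ann.n_columns):
        if ann.role[c] in (LOOP, UNCOVERED):
            if ann.role[c] == UNCOVERED and drop_uncovered:
                continue
            site_map.append((ann.role[c], (c,)))
        elif ann.role[c] == STEM5:
            site_map.append(("stem", (c, ann.partner[c])))
    codes = np.full((len(taxa), len(site_map)), MISSING_INDEX, dtype=np.int8)
    for t, row in enumerate(rows):
        for s, (role, cols) in enumerate(site_map):
            if role == "stem":
                codes[t, s] = doublet_index(row[cols[0]], row[cols[1]])
            else:
                codes[t, s] = base_index(row[cols[0]])
    return StructureAlignment(taxa=list(taxa), codes=codes, site_map=site_map)


def to_protein_letters(sa: StructureAlignment, missing_char: str = "?") -> list[str]:
    """Emit each taxon's coded row as a string over amino-acid letters.

    The fixed 20-symbol → amino-acid bijection makes recoded matrices
    readable by standard protein phylogenetics software; missing sites are
    written as ``missing_char`` ('?' by default, '-' also accepted there).
    """
    out = []
    for t in range(len(sa.taxa)):
        out.append("".join(
            missing_char if c < 0 else AA_LETTERS[c] for c in sa.codes[t]
        ))
    return out


def from_protein_letters(
    taxa: list[str],
    rows: list[str],
    site_map: list[tuple[str, tuple[int, ...]]],
) -> StructureAlignment:
    """Inverse of :func:`to_protein_letters` (for round-tripping files)."""
    codes = np.full((len(taxa), len(site_map)), MISSING_INDEX, dtype=np.int8)
    for t, row in enumerate(rows):
        for s, ch in enumerate(row):
            if ch in AA_TO_INDEX:
                codes[t, s] = AA_TO_INDEX[ch]
            elif ch in "?-.":
                codes[t, s] = MISSING_INDEX
            else:
                raise ValueError(f"invalid coded letter {ch!r}")
    return StructureAlignment(taxa=list(taxa), codes=codes, site_map=list(site_map))


def annotation_to_pairtable(ann: ColumnAnnotation) -> PairTable:
    """Recover the reference pair table by deleting uncovered columns."""
    keep = [c for c in range(ann.n_columns) if ann.role[c] != UNCOVERED]
    new_index = {c: i for i, c in enumerate(keep)}
    pairs = frozenset(
        (new_index[c], new_index[p]) for c, p in ann.stem_pairs
    )
    return PairTable(length=len(keep), pairs=pairs)
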