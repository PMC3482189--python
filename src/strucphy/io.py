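"""Alignment and character-matrix file handling (FASTA, relaxed PHYLIP, NEXUS/TSV)."""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _sniff_format(text: str) -> str:
    head = text.lstrip()
    if head.startswith(">"):
        return "fasta"
    first = head.splitlines()[0].split()
    if len(first) == 2 and all(tok.isdigit() for tok in first):
        return "phylip-relaxed"
    raise ValueError("cannot determine alignment format (expected FASTA or PHYLIP)")


def read_alignment(path: str | Path, fmt: str | None = None) -> tuple[list[str], list[str]]:
    """Read a multiple alignment; returns (taxon names, aligned rows)."""
    text = Path(path).read_text()
    fmt = fmt or _sniff_format(text)
    aln = AlignIO.read(_io.StringIO(text), fmt)
    return [r.id for r in aln], [str(r.seq) for r in aln]


def write_alignment(path: str | Path, taxa: list[str], rows: list[str],
                    fmt: str = "fasta") -> None:
    aln = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=name, description="") for name, row in zip(taxa, rows)
    )
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, fmt)


def read_character_tsv(text: str) -> dict[str, str]:
    """Read a (taxon, state-label) two-column TSV; '?' marks missing."""
    out: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"expected two tab-separated columns: {line!r}")
        if fields[0].lower() == "taxon":
            continue
        out[fields[0]] = fields[1]
    return out


def read_characters_nexus(text: str) -> tuple[list[str], dict[str, str]]:
    """Read the first character from a NEXUS CHARACTERS/DATA matrix.

    Returns (taxon order, taxon -> single-character state symbol).  Only the
    simple standard-datatype matrices written for morphological characters
    are supported; symbols are taken verbatim.
    """
    lines = text.splitlines()
    in_matrix = False
    order: list[str] = []
    states: dict[str, str] = {}
    for raw in lines:
        line = raw.strip()
        low = line.lower()
        if low.startswith("matrix"):
            in_matrix = True
            continue
        if in_matrix:
            if line.startswith(";") or low == "end;":
                break
            if not line:
                continue
            parts = line.rstrip(";").split()
            if len(parts) >= 2:
                order.append(parts[0])
                states[parts[0]] = parts[1][0]
    if not states:
        raise ValueError("no NEXUS matrix block found")
    return order, states
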