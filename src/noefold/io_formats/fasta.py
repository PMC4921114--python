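"""FASTA sequence reading (single-record convenience wrappers over Bio.SeqIO)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from ..chem import STANDARD_AA


def read_sequence(path: str | Path) -> str:
    """Read the first record of a FASTA file as an upper-case 1-letter string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seq = str(records[0].seq).upper()
    bad = sorted(set(seq) - STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residue codes in {path}: {', '.join(bad)}")
    return seq


def write_sequence(sequence: str, path: str | Path, name: str = "target") -> None:
    Path(path).write_text(f">{name}\n{sequence}\n")
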