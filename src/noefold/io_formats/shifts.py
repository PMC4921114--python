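"""Chemical-shift table readers (SPARKY resonance-list dialect and plain TSV)."""

from __future__ import annotations

import re
from pathlib import Path

from .types import ShiftEntry, ShiftTable

_GROUP_RE = re.compile(r"^([A-Za-z])(\d+)$")

DIALECTS = ("sparky-resonance", "tsv")


class ShiftParseError(ValueError):
    pass


def _parse_tsv_row(fields: list[str]) -> ShiftEntry:
    if len(fields) != 4:
        raise ShiftParseError(f"expected 4 fields, got {len(fields)}")
    return ShiftEntry(
        residue_index=int(fields[0]),
        residue_type=fields[1].upper(),
        atom_name=fields[2].upper(),
        shift=float(fields[3]),
    )


def _parse_sparky_row(fields: list[str]) -> ShiftEntry:
    # "  A5   HA   1H   4.320  0.002   3"  (SDev / assignment-count optional)
    if len(fields) < 4:
        raise ShiftParseError(f"expected >= 4 fields, got {len(fields)}")
    m = _GROUP_RE.match(fields[0])
    if m is None:
        raise ShiftParseError(f"cannot parse group {fields[0]!r}")
    return ShiftEntry(
        residue_index=int(m.group(2)),
        residue_type=m.group(1).upper(),
        atom_name=fields[1].upper(),
        shift=float(fields[3]),
    )


def read_shift_table(path: str | Path, dialect: str = "tsv") -> ShiftTable:
    """Read a chemical-shift assignment table.

    Malformed rows raise with their line number; duplicate
    (residue, atom) pairs are a hard error listing the duplicates
    (enforced by :class:`ShiftTable`).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown shift-table dialect {dialect!r}; choose from {DIALECTS}")
    parse = _parse_tsv_row if dialect == "tsv" else _parse_sparky_row
    entries: list[ShiftEntry] = []
    bad: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if dialect == "sparky-resonance" and fields[0].lower() == "group":
            continue  # header line
        try:
            entries.append(parse(fields))
        except (ShiftParseError, ValueError) as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ShiftParseError("malformed shift-table rows:\n" + "\n".join(bad))
    if not entries:
        raise ShiftParseError(f"no entries in shift table {path}")
    return ShiftTable(entries=entries)


def write_shift_table(table: ShiftTable, path: str | Path, dialect: str = "tsv") -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown shift-table dialect {dialect!r}")
    lines = []
    if dialect == "tsv":
        for e in table.entries:
            lines.append(f"{e.residue_index}\t{e.residue_type}\t{e.atom_name}\t{e.shift:.3f}")
    else:
        lines.append(" Group   Atom  Nuc    Shift   SDev  Assignments")
        for e in table.entries:
            nuc = "15N" if e.atom_name.startswith("N") else (
                "1H" if e.atom_name.startswith(("H", "Q")) else "13C")
            lines.append(f" {e.residue_type}{e.residue_index:<5} {e.atom_name:<5} {nuc:<4} "
                         f"{e.shift:8.3f}  0.000      1")
    Path(path).write_text("\n".join(lines) + "\n")
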