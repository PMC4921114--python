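"""Constraint-table writers and readers.

Supported dialects:

* ``cyana-upl``     — one "resi resn atom  resi resn atom  upper" row per pair;
                      ambiguous restraints are expanded to one row per member
                      and flagged with a trailing comment.
* ``xplor-noe``     — ``assign (sele) (sele) d dminus dplus`` with ``or``
                      continuation lines for ambiguous members; bounds are
                      [d - dminus, d + dplus] so the upper limit is d + dplus
                      and here d is written as the upper limit (dplus = 0).
* ``xplor-hbda``    — donor N / donor H / acceptor O selection triples.
* ``cyana-aco``     — "resi resn ANGLE lower upper" torsion rows.
* ``xplor-dihedral`` — CDIH ``assign`` statements (4 selections, force,
                      center, range, exponent).

Round-trip write -> read reproduces numeric limits to 0.01 Å / 0.01°.
"""

from __future__ import annotations

import re
from pathlib import Path

from ..chem import AA1_TO_3, AA3_TO_1
from ..restraints import (AngleConstraint, CandidateAssignment,
                          DistanceConstraint, HBondConstraint)

FORMATS = ("cyana-upl", "xplor-noe", "xplor-hbda", "cyana-aco", "xplor-dihedral")

_SELE = r"\(\s*resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)"


def write_constraints(constraints, fmt: str, path: str | Path,
                      header_comments: list[str] | None = None) -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unknown constraint format {fmt!r}; choose from {FORMATS}")
    constraints = list(constraints)
    if not constraints:
        raise ValueError("refusing to write an empty constraint table")
    writer = {
        "cyana-upl": _write_upl,
        "xplor-noe": _write_noe,
        "xplor-hbda": _write_hbda,
        "cyana-aco": _write_aco,
        "xplor-dihedral": _write_dihedral,
    }[fmt]
    lines: list[str] = []
    comment_char = "#" if fmt.startswith("cyana") else "!"
    for c in header_comments or []:
        lines.append(f"{comment_char} {c}")
    writer(constraints, lines)
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraints(path: str | Path, fmt: str):
    if fmt not in FORMATS:
        raise ValueError(f"unknown constraint format {fmt!r}")
    text = Path(path).read_text()
    reader = {
        "cyana-upl": _read_upl,
        "xplor-noe": _read_noe,
        "xplor-hbda": _read_hbda,
        "cyana-aco": _read_aco,
        "xplor-dihedral": _read_dihedral,
    }[fmt]
    return reader(text)


# ---------------------------------------------------------------- distances

def _resn3(code: str) -> str:
    return AA1_TO_3.get(code, "UNK")


def _write_upl(constraints: list[DistanceConstraint], lines: list[str]) -> None:
    for c in constraints:
        tag = ""
        if c.ambiguous:
            tag = f"  # ambiguous {len(c.members)}-member constraint {c.id}: one line per member"
        for m in c.members:
            (ra, aa), (rb, ab) = m.proton_a, m.proton_b
            lines.append(
                f"{ra:4d} {_resn3(m.res_type_a):<4} {aa:<5} "
                f"{rb:4d} {_resn3(m.res_type_b):<4} {ab:<5} {c.upper_limit:8.2f}{tag}")
            tag = ""


def _read_upl(text: str) -> list[DistanceConstraint]:
    out = []
    for i, line in enumerate(text.splitlines()):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        f = body.split()
        member = CandidateAssignment(
            proton_a=(int(f[0]), f[2]), proton_b=(int(f[3]), f[5]),
            heavy_atom=(int(f[0]), "X"), shift_errors=(0.0, 0.0, 0.0),
            res_type_a=AA3_TO_1.get(f[1], "X"), res_type_b=AA3_TO_1.get(f[4], "X"))
        out.append(DistanceConstraint(members=[member], upper_limit=float(f[6]), id=i))
    return out


def _sele(ref) -> str:
    return f"(resid {ref[0]} and name {ref[1]})"


def _write_noe(constraints: list[DistanceConstraint], lines: list[str]) -> None:
    for c in constraints:
        m0 = c.members[0]
        d = c.upper_limit
        dminus = max(0.0, d - c.lower_limit)
        lines.append(f"assign {_sele(m0.proton_a)} {_sele(m0.proton_b)} "
                     f"{d:.2f} {dminus:.2f} 0.00")
        for m in c.members[1:]:
            lines.append(f"    or {_sele(m.proton_a)} {_sele(m.proton_b)}")


_NOE_ASSIGN = re.compile(
    rf"^assign\s+{_SELE}\s+{_SELE}\s+([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)", re.I)
_NOE_OR = re.compile(rf"^or\s+{_SELE}\s+{_SELE}", re.I)


def _read_noe(text: str) -> list[DistanceConstraint]:
    out: list[DistanceConstraint] = []
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        m = _NOE_ASSIGN.match(line)
        if m:
            ra, aa, rb, ab, d, dminus, dplus = m.groups()
            member = CandidateAssignment(
                proton_a=(int(ra), aa), proton_b=(int(rb), ab),
                heavy_atom=(int(ra), "X"), shift_errors=(0.0, 0.0, 0.0))
            upper = float(d) + float(dplus)
            out.append(DistanceConstraint(
                members=[member], upper_limit=upper, id=len(out),
                lower_limit=float(d) - float(dminus)))
            continue
        m = _NOE_OR.match(line)
        if m:
            if not out:
                raise ValueError("'or' continuation before any assign statement")
            ra, aa, rb, ab = m.groups()
            out[-1].members.append(CandidateAssignment(
                proton_a=(int(ra), aa), proton_b=(int(rb), ab),
                heavy_atom=(int(ra), "X"), shift_errors=(0.0, 0.0, 0.0)))
    return out


# ------------------------------------------------------------------ H-bonds

def _write_hbda(constraints: list[HBondConstraint], lines: list[str]) -> None:
    for c in constraints:
        lines.append(f"assign (resid {c.donor_residue} and name N) "
                     f"(resid {c.donor_residue} and name H) "
                     f"(resid {c.acceptor_residue} and name O)")


_HBDA = re.compile(rf"^assign\s+{_SELE}\s+{_SELE}\s+{_SELE}", re.I)


def _read_hbda(text: str) -> list[HBondConstraint]:
    out = []
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        m = _HBDA.match(line)
        if m:
            rn, _, _, _, ro, _ = m.groups()
            out.append(HBondConstraint(donor_residue=int(rn),
                                       acceptor_residue=int(ro), id=len(out)))
    return out


# ------------------------------------------------------------------- angles

def _write_aco(constraints: list[AngleConstraint], lines: list[str]) -> None:
    for c in constraints:
        lines.append(f"{c.residue_index:4d} UNK  {c.angle_name.upper():<4} "
                     f"{c.center - c.half_width:9.2f} {c.center + c.half_width:9.2f}")


def _read_aco(text: str) -> list[AngleConstraint]:
    out = []
    for raw in text.splitlines():
        body = raw.split("#", 1)[0].strip()
        if not body:
            continue
        f = body.split()
        lo, hi = float(f[3]), float(f[4])
        out.append(AngleConstraint(
            residue_index=int(f[0]), angle_name=f[2].lower(),
            center=(lo + hi) / 2.0, half_width=(hi - lo) / 2.0, id=len(out)))
    return out


def _dihedral_atoms(c: AngleConstraint) -> list[tuple[int, str]]:
    i = c.residue_index
    if c.angle_name == "phi":
        return [(i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")]
    return [(i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")]


def _write_dihedral(constraints: list[AngleConstraint], lines: list[str]) -> None:
    for c in constraints:
        seles = " ".join(_sele(a) for a in _dihedral_atoms(c))
        lines.append(f"assign {seles} 1.0 {c.center:.2f} {c.half_width:.2f} 2")


_DIH = re.compile(
    rf"^assign\s+{_SELE}\s+{_SELE}\s+{_SELE}\s+{_SELE}\s+"
    r"([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)\s+(\d+)", re.I)


def _read_dihedral(text: str) -> list[AngleConstraint]:
    out = []
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        m = _DIH.match(line)
        if not m:
            continue
        g = m.groups()
        # second selection is (resid i, N) for phi; third atom name tells psi apart
        r2, a2 = int(g[2]), g[3].upper()
        names = (g[1].upper(), g[3].upper(), g[5].upper(), g[7].upper())
        angle = "phi" if names == ("C", "N", "CA", "C") else "psi"
        resi = r2 if angle == "phi" else int(g[0])
        out.append(AngleConstraint(residue_index=resi, angle_name=angle,
                                   center=float(g[9]), half_width=float(g[10]),
                                   id=len(out)))
    return out
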