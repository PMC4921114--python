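"""TALOS-style backbone angle prediction table (pred.tab dialect).

Rows: RESID RESNAME PHI PSI DPHI DPSI CLASS.  Only the columns the
torsion-constraint builder consumes are modelled; header/VARS/FORMAT lines
are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class TalosPrediction:
    residue_index: int
    residue_type: str
    phi: float
    psi: float
    dphi: float
    dpsi: float
    classification: str  # "strong" | "generous" | anything else (unused rows)


def read_talos_table(path: str | Path) -> list[TalosPrediction]:
    out: list[TalosPrediction] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "VARS", "FORMAT", "REMARK", "DATA")):
            continue
        f = line.split()
        if len(f) < 7:
            raise ValueError(f"malformed TALOS row: {raw!r}")
        out.append(TalosPrediction(
            residue_index=int(f[0]), residue_type=f[1].upper(),
            phi=float(f[2]), psi=float(f[3]),
            dphi=float(f[4]), dpsi=float(f[5]),
            classification=f[6].lower()))
    if not out:
        raise ValueError(f"no predictions in {path}")
    return out


def write_talos_table(predictions: list[TalosPrediction], path: str | Path) -> None:
    lines = ["VARS   RESID RESNAME PHI PSI DPHI DPSI CLASS",
             "FORMAT %4d %s %8.3f %8.3f %8.3f %8.3f %s"]
    for p in predictions:
        lines.append(f"{p.residue_index:4d} {p.residue_type} {p.phi:8.3f} "
                     f"{p.psi:8.3f} {p.dphi:8.3f} {p.dpsi:8.3f} {p.classification}")
    Path(path).write_text("\n".join(lines) + "\n")
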