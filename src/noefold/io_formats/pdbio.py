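"""PDB coordinate reading/writing.

Reading goes through Bio.PDB; each MODEL block becomes one
:class:`CoordinateSet`.  Writing emits standard ATOM/MODEL/ENDMDL records
(multi-model ensembles supported).
"""

from __future__ import annotations

import warnings as _warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from ..chem import AA1_TO_3, AA3_TO_1
from .types import CoordinateSet


def read_pdb(path: str | Path, chain_id: str | None = None,
             residue_offset: int = 0) -> list[CoordinateSet]:
    """Read a PDB file into one CoordinateSet per MODEL.

    Only standard amino-acid ATOM records are kept; alternate locations
    other than blank/'A' are dropped with a warning; HETATM-only files are
    an error.  ``residue_offset`` is added to every resSeq (maps file
    numbering onto target numbering).
    """
    parser = PDBParser(QUIET=True)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", str(path))
    sets: list[CoordinateSet] = []
    for model in structure:
        resi: list[int] = []
        rest: list[str] = []
        names: list[str] = []
        xyz: list[np.ndarray] = []
        use_chain = None
        for chain in model:
            if chain_id is not None and chain.id != chain_id:
                continue
            if use_chain is None:
                use_chain = chain.id
            elif chain.id != use_chain:
                continue  # first (or requested) chain only
            for residue in chain:
                resname = residue.get_resname().strip()
                if resname not in AA3_TO_1:
                    continue
                for atom in residue:
                    if atom.get_altloc() not in (" ", "A"):
                        _warnings.warn(
                            f"dropping altloc {atom.get_altloc()!r} for "
                            f"{resname}{residue.id[1]} {atom.get_name()}")
                        continue
                    resi.append(residue.id[1] + residue_offset)
                    rest.append(AA3_TO_1[resname])
                    names.append(atom.get_name().strip())
                    xyz.append(atom.get_coord())
        if resi:
            sets.append(CoordinateSet(
                residue_indices=np.array(resi),
                residue_types=rest,
                atom_names=names,
                coords=np.array(xyz, dtype=float),
                chain_id=use_chain or "A",
                model_number=model.id + 1,
            ))
    if not sets:
        raise ValueError(f"no protein atoms in {path}")
    return sets


def write_pdb(models: CoordinateSet | list[CoordinateSet], path: str | Path) -> None:
    """Write one or more models as a (multi-MODEL) PDB file."""
    if isinstance(models, CoordinateSet):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for k, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        serial = 1
        for i in range(len(m)):
            name = m.atom_names[i]
            resn = AA1_TO_3.get(m.residue_types[i], "UNK")
            x, y, z = m.coords[i]
            element = name[0] if name[0] in ("H", "N", "C", "O", "S") else "C"
            if name.startswith("Q"):
                element = "H"  # pseudoatom standing in for protons
            # column-exact ATOM record
            atom_field = f" {name:<3}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {atom_field:<4}{resn:>4} {m.chain_id}"
                f"{m.residue_indices[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00          {element:>2}")
            serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
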