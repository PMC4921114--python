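"""Residue chemistry tables shared across the package.

Everything here is static knowledge about the 20 standard amino acids:
name conversions, which heavy atom carries a given proton, which side-chain
carbons bear protons (and therefore get a pseudoatom), and the pseudoatom
distance corrections used when an upper limit involves degenerate protons.
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = set(AA1_TO_3)

# Side-chain carbons that carry at least one proton, per residue type, with
# the number of attached protons.  Used for pseudoatom placement during
# hydrogen addition and for methyl/methylene classification.
SIDECHAIN_H_CARBONS: dict[str, dict[str, int]] = {
    "A": {"CB": 3},
    "R": {"CB": 2, "CG": 2, "CD": 2},
    "N": {"CB": 2},
    "D": {"CB": 2},
    "C": {"CB": 2},
    "Q": {"CB": 2, "CG": 2},
    "E": {"CB": 2, "CG": 2},
    "G": {},
    "H": {"CB": 2, "CD2": 1, "CE1": 1},
    "I": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "L": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "K": {"CB": 2, "CG": 2, "CD": 2, "CE": 2},
    "M": {"CB": 2, "CG": 2, "CE": 3},
    "F": {"CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "P": {"CB": 2, "CG": 2, "CD": 2},
    "S": {"CB": 2},
    "T": {"CB": 1, "CG2": 3},
    "W": {"CB": 2, "CD1": 1, "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "Y": {"CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1},
    "V": {"CB": 1, "CG1": 3, "CG2": 3},
}

# CYANA-style pseudoatom distance corrections (Å), added to the upper limit
# of a restraint for each degenerate-proton member: +1.0 for a methyl group,
# +0.7 for a methylene.
METHYL_CORRECTION = 1.0
METHYLENE_CORRECTION = 0.7


def pseudoatom_name(carbon_name: str) -> str:
    """Pseudoatom name for the protons on a side-chain carbon: CB -> QB."""
    return "Q" + carbon_name[1:]


def is_pseudoatom(atom_name: str) -> bool:
    return atom_name.startswith("Q")


def pseudoatom_correction(residue_type: str, atom_name: str) -> float:
    """Distance correction (Å) for one restraint member atom.

    Methyl pseudoatoms get +1.0 Å, methylene (or other multi-proton group)
    pseudoatoms +0.7 Å, real single protons 0.
    """
    if not is_pseudoatom(atom_name):
        return 0.0
    carbon = "C" + atom_name[1:]
    n_h = SIDECHAIN_H_CARBONS.get(residue_type, {}).get(carbon, 2)
    return METHYL_CORRECTION if n_h == 3 else METHYLENE_CORRECTION


def attached_heavy_atom(residue_type: str, proton_name: str) -> str | None:
    """Heavy atom covalently bonded to a proton (or pseudoatom).

    Returns None for names that are not recognized protons.
    """
    if proton_name in ("H", "HN"):
        return "N"
    if proton_name in ("HA", "HA2", "HA3"):
        return "CA"
    if is_pseudoatom(proton_name):
        return "C" + proton_name[1:]
    if proton_name.startswith("H") and len(proton_name) > 1:
        # HB2 -> CB, HG12 -> CG1, HD21 -> CD2 ...
        stem = proton_name[1:]
        carbons = SIDECHAIN_H_CARBONS.get(residue_type, {})
        for cut in (len(stem), len(stem) - 1):
            if cut > 0 and "C" + stem[:cut] in carbons:
                return "C" + stem[:cut]
        return "C" + stem
    return None


def group_atom(residue_type: str, atom_name: str) -> str:
    """Canonical atom-group name used when comparing atom pairs.

    Side-chain protons collapse onto their pseudoatom (HB2 -> QB); the two
    glycine alpha protons collapse onto HA; amide H and HN unify.
    """
    if atom_name in ("H", "HN"):
        return "H"
    if atom_name in ("HA", "HA2", "HA3"):
        return "HA"
    if is_pseudoatom(atom_name):
        return atom_name
    heavy = attached_heavy_atom(residue_type, atom_name)
    if heavy is not None and heavy not in ("N", "CA") and atom_name.startswith("H"):
        return pseudoatom_name(heavy)
    return atom_name


def is_proton(atom_name: str) -> bool:
    """True for real protons and for pseudoatoms standing in for protons."""
    return atom_name.startswith("H") or is_pseudoatom(atom_name)
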