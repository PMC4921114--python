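"""Dynamic hydrogen-bond detection from NOE cross-peak patterns.

Secondary structure leaves characteristic proton-proton contact patterns:
an alpha-helix shows sequential HN(i)-HN(i+1) peaks plus medium-range
HA(i)-HN(i+3) peaks, a beta-sheet shows cross-strand HN(i)-HN(j) plus
HA(i)-HN(j) pairs.  Where such a pattern is corroborated, an idealized
backbone H-bond constraint is proposed; after every calculation cycle the
bonds are re-measured on the current lowest-energy model and violated ones
are eliminated from subsequent cycles.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import HBondParams
from .io_formats.types import CoordinateSet
from .restraints import DistanceConstraint, HBondConstraint


def _unambiguous_pairs(constraints: list[DistanceConstraint]) -> set[frozenset]:
    """Proton-pair set from unambiguously assigned constraints."""
    pairs: set[frozenset] = set()
    for c in constraints:
        if len(c.members) != 1:
            continue
        m = c.members[0]
        pairs.add(frozenset([m.proton_a, m.proton_b]))
    return pairs


def detect_hbonds(assigned_constraints: list[DistanceConstraint],
                  params: HBondParams | None = None) -> list[HBondConstraint]:
    """Propose idealized backbone H-bonds from assignment patterns.

    Helix rule: a window i..i+4 with all sequential HN-HN peaks and an
    HA(i)-HN(i+3) peak proposes N-H(i+4) -> O(i).  Sheet rule: cross-strand
    HN(i)-HN(j) with |i-j| >= 3 plus HA(i)-HN(j) proposes N-H(j) -> O(i).
    Duplicates are merged.
    """
    params = params or HBondParams()
    pairs = _unambiguous_pairs(assigned_constraints)

    def hn_hn(i: int, j: int) -> bool:
        return frozenset([(i, "H"), (j, "H")]) in pairs

    def ha_hn(i: int, j: int) -> bool:
        return frozenset([(i, "HA"), (j, "H")]) in pairs

    residues = sorted({r for p in pairs for r, _ in p})
    proposed: dict[tuple[int, int], HBondConstraint] = {}

    def propose(donor: int, acceptor: int) -> None:
        key = (donor, acceptor)
        if key not in proposed:
            proposed[key] = HBondConstraint(
                donor_residue=donor, acceptor_residue=acceptor,
                ho_upper=params.ho_ideal, no_upper=params.no_ideal,
                id=len(proposed))

    for i in residues:
        if all(hn_hn(j, j + 1) for j in range(i, i + 4)) and ha_hn(i, i + 3):
            propose(i + 4, i)

    for i in residues:
        for j in residues:
            if abs(i - j) < params.min_strand_separation or i == j:
                continue
            # skip pairs already explained by the helix pattern
            if j - i == 4 and (i + 4, i) in proposed:
                continue
            if hn_hn(i, j) and ha_hn(i, j):
                propose(j, i)

    return sorted(proposed.values(), key=lambda h: (h.donor_residue, h.acceptor_residue))


def reevaluate(hbonds: list[HBondConstraint], model: CoordinateSet,
               params: HBondParams | None = None) -> list[HBondConstraint]:
    """Keep H-bonds the current model satisfies within tolerance.

    A bond survives iff H..O <= ho_keep and N..O <= no_keep in the model
    (the idealized targets plus 0.4 Å slack); eliminated bonds are dropped
    permanently for the rest of the run.  Missing atoms eliminate the bond
    with a warning.
    """
    params = params or HBondParams()
    kept: list[HBondConstraint] = []
    for hb in hbonds:
        if not hb.active:
            continue
        d, a = hb.donor_residue, hb.acceptor_residue
        if not (model.has_atom(d, "H") and model.has_atom(d, "N")
                and model.has_atom(a, "O")):
            warnings.warn(f"H-bond {d}->{a}: atoms missing in model, eliminated")
            continue
        ho = float(np.linalg.norm(model.position(d, "H") - model.position(a, "O")))
        no = float(np.linalg.norm(model.position(d, "N") - model.position(a, "O")))
        if ho <= params.ho_keep and no <= params.no_keep:
            kept.append(hb)
    return kept


def emit_constraints(hbonds: list[HBondConstraint],
                     params: HBondParams | None = None
                     ) -> tuple[list[DistanceConstraint], list[HBondConstraint]]:
    """Turn active H-bonds into NOE-style distance rows plus an HBDA listing.

    Each bond contributes two distance restraints (H..O and N..O upper
    limits) carrying the static NOE potential weight of 30; the HBDA table
    lists the donor/acceptor triples.  An empty active set yields two
    empty tables.
    """
    from .restraints import CandidateAssignment

    params = params or HBondParams()
    active = [h for h in hbonds if h.active]
    noe_rows: list[DistanceConstraint] = []
    for hb in active:
        for atoms, upper in ((("H", "O"), hb.ho_upper), (("N", "O"), hb.no_upper)):
            member = CandidateAssignment(
                proton_a=(hb.donor_residue, atoms[0]),
                proton_b=(hb.acceptor_residue, atoms[1]),
                heavy_atom=(hb.donor_residue, "N"),
                shift_errors=(0.0, 0.0, 0.0))
            noe_rows.append(DistanceConstraint(
                members=[member], upper_limit=upper, lower_limit=1.5,
                weight=params.noe_weight, id=len(noe_rows),
                comment=f"hbond {hb.donor_residue}->{hb.acceptor_residue}"))
    return noe_rows, active


def write_hbond_files(hbonds: list[HBondConstraint], noe_path, hbda_path,
                      params: HBondParams | None = None) -> bool:
    """Write the NOE and HBDA tables; returns False (no files) if no bond is active."""
    from .io_formats.constraints import write_constraints

    params = params or HBondParams()
    noe_rows, active = emit_constraints(hbonds, params)
    if not active:
        return False
    write_constraints(noe_rows, "xplor-noe", noe_path,
                      header_comments=[f"NOE potential weight = {params.noe_weight:g}"])
    write_constraints(active, "xplor-hbda", hbda_path)
    return True
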