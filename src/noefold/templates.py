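"""Database assistance: template selection and contact prediction.

Homologous template structures are aligned to the target sequence
(global Needleman-Wunsch, BLOSUM62), hydrogens are added to their
coordinates, interproton distances below 5.5 Å are tabulated and mapped
onto target numbering, and the predicted contacts are filtered against the
experimental peak lists.  Surviving contacts later feed the supportive
score of matching distance constraints.

Selection rules: the three highest-identity templates are used; if the
best identity is below 20 % no contacts are predicted at all, and above
80 % only that single template is used (with a reduced supportive-score
cap, so a single close homolog cannot lock in a wrong constraint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .chem import (SIDECHAIN_H_CARBONS, STANDARD_AA, attached_heavy_atom,
                   group_atom, is_proton, pseudoatom_name)
from .config import TemplateParams, Tolerances
from .io_formats.pdbio import read_pdb, write_pdb
from .io_formats.types import CoordinateSet, PeakList, ShiftTable


@dataclass
class TemplateEntry:
    id: str
    sequence: str
    coords: CoordinateSet

    def __post_init__(self) -> None:
        n_res = len(self.coords.residue_numbers())
        if len(self.sequence) != n_res:
            raise ValueError(
                f"template {self.id}: sequence length {len(self.sequence)} "
                f"does not match {n_res} residues in coordinates")


@dataclass
class AlignmentResult:
    template_id: str
    identity_pct: float
    aligned_pairs: list[tuple[int, int]]   # (target_residue, template_residue), 1-based
    target_sequence: str = ""
    template_sequence: str = ""

    def target_to_template(self) -> dict[int, int]:
        return dict(self.aligned_pairs)

    def template_to_target(self) -> dict[int, int]:
        return {t: s for s, t in self.aligned_pairs}


@dataclass
class PredictedContact:
    """A template-derived interproton contact mapped onto target numbering."""

    res_a: int
    atom_a: str
    res_b: int
    atom_b: str
    template_distance: float
    supporting_template_ids: list[str] = field(default_factory=list)
    tripeptide_factors: dict[str, float] = field(default_factory=dict)
    supporting_peaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.res_a, self.atom_a) == (self.res_b, self.atom_b):
            raise ValueError("contact atoms must be distinct")

    @property
    def pair_key(self) -> frozenset:
        return frozenset([(self.res_a, self.atom_a), (self.res_b, self.atom_b)])


# ---------------------------------------------------------------- alignment

def _make_aligner(params: TemplateParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    return aligner


def align(target_sequence: str, template_sequence: str,
          template_id: str = "", params: TemplateParams | None = None) -> AlignmentResult:
    """Global alignment; identity is counted over aligned (non-gap) columns."""
    params = params or TemplateParams()
    for name, seq in (("target", target_sequence), ("template", template_sequence)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = sorted(set(seq.upper()) - STANDARD_AA)
        if bad:
            raise ValueError(f"non-amino-acid symbol(s) in {name} sequence: {', '.join(bad)}")
    target = target_sequence.upper()
    template = template_sequence.upper()
    alignment = _make_aligner(params).align(target, template)[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    for (ts, te), (ss, se) in zip(*alignment.aligned):
        for k in range(te - ts):
            ti, si = ts + k, ss + k
            pairs.append((ti + 1, si + 1))
            if target[ti] == template[si]:
                identical += 1
    identity = 100.0 * identical / len(pairs) if pairs else 0.0
    return AlignmentResult(template_id=template_id, identity_pct=identity,
                           aligned_pairs=pairs, target_sequence=target,
                           template_sequence=template)


def select_templates(alignments: list[AlignmentResult],
                     params: TemplateParams | None = None
                     ) -> tuple[list[AlignmentResult], bool]:
    """Apply the homolog-selection rules.

    Returns (selected alignments, single_template_mode).  Best identity
    below ``min_identity`` -> nothing selected; above ``single_identity``
    -> only that template, flagged single-template; otherwise the top
    ``max_templates`` by identity.
    """
    params = params or TemplateParams()
    if not alignments:
        return [], False
    ranked = sorted(alignments, key=lambda a: a.identity_pct, reverse=True)
    best = ranked[0].identity_pct
    if best < params.min_identity:
        return [], False
    if best > params.single_identity:
        return [ranked[0]], True
    return ranked[:params.max_templates], False


# ------------------------------------------------------------- hydrogenation

_TET_ANGLE_COS = -1.0 / 3.0  # cos(109.47 deg)


def add_hydrogens(coords: CoordinateSet) -> CoordinateSet:
    """Add amide H, HA and side-chain pseudoatoms to a heavy-atom model.

    Amide H sits in the peptide plane at 1.01 Å from N (bisecting the
    C(prev)-N-CA directions, i.e. trans to the carbonyl O); HA is placed
    tetrahedrally at 1.09 Å; protons beyond the alpha position are
    represented by pseudoatoms at their carbon positions.  Existing
    hydrogens are preserved; residues with an incomplete backbone are
    skipped with a warning.
    """
    resi = list(coords.residue_indices)
    rest = list(coords.residue_types)
    names = list(coords.atom_names)
    xyz = [c for c in coords.coords]

    def add(idx: int, rtype: str, name: str, pos: np.ndarray) -> None:
        resi.append(idx)
        rest.append(rtype)
        names.append(name)
        xyz.append(np.asarray(pos, dtype=float))

    for idx in coords.residue_numbers():
        rtype = coords.residue_type_of(idx)
        if not all(coords.has_atom(idx, a) for a in ("N", "CA", "C")):
            warnings.warn(f"residue {idx}: incomplete backbone, no hydrogens added")
            continue
        n = coords.position(idx, "N")
        ca = coords.position(idx, "CA")
        c = coords.position(idx, "C")
        if (rtype != "P" and not coords.has_atom(idx, "H")
                and not coords.has_atom(idx, "HN")
                and coords.has_atom(idx - 1, "C")):
            c_prev = coords.position(idx - 1, "C")
            u1 = _unit(n - c_prev)
            u2 = _unit(n - ca)
            add(idx, rtype, "H", n + 1.01 * _unit(u1 + u2))
        if not coords.has_atom(idx, "HA") and not coords.has_atom(idx, "HA2"):
            if coords.has_atom(idx, "CB"):
                cb = coords.position(idx, "CB")
                direction = -_unit(_unit(n - ca) + _unit(c - ca) + _unit(cb - ca))
            else:
                d1 = _unit(n - ca)
                d2 = _unit(c - ca)
                bis = _unit(d1 + d2)
                perp = _unit(np.cross(d1, d2))
                alpha = _TET_ANGLE_COS / float(np.dot(bis, d1))
                beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
                direction = alpha * bis - beta * perp
            add(idx, rtype, "HA", ca + 1.09 * direction)
        for carbon in SIDECHAIN_H_CARBONS.get(rtype, {}):
            pseudo = pseudoatom_name(carbon)
            if coords.has_atom(idx, carbon) and not coords.has_atom(idx, pseudo):
                add(idx, rtype, pseudo, coords.position(idx, carbon))

    return CoordinateSet(residue_indices=np.array(resi), residue_types=rest,
                         atom_names=names, coords=np.array(xyz),
                         chain_id=coords.chain_id, model_number=coords.model_number)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------- contact tabulation

def tabulate_contacts(template: TemplateEntry, alignment: AlignmentResult,
                      params: TemplateParams | None = None) -> list[PredictedContact]:
    """All interproton pairs below the 5.5 Å cutoff, mapped to target numbering.

    Both residues must be aligned; intra-residue pairs (zero sequence
    separation in target numbering) carry no structural information and are
    dropped.  Side-chain protons are reported by their pseudoatom group.
    """
    params = params or TemplateParams()
    coords = template.coords
    mapping = alignment.template_to_target()
    proton_idx = [k for k in range(len(coords)) if is_proton(coords.atom_names[k])]
    out: list[PredictedContact] = []
    seen: set[frozenset] = set()
    for ii, a in enumerate(proton_idx):
        ra = int(coords.residue_indices[a])
        if ra not in mapping:
            continue
        ga = group_atom(coords.residue_types[a], coords.atom_names[a])
        for b in proton_idx[ii + 1:]:
            rb = int(coords.residue_indices[b])
            if rb not in mapping:
                continue
            ta, tb = mapping[ra], mapping[rb]
            if abs(ta - tb) < params.min_sequence_separation:
                continue
            d = float(np.linalg.norm(coords.coords[a] - coords.coords[b]))
            if d >= params.contact_cutoff:
                continue
            gb = group_atom(coords.residue_types[b], coords.atom_names[b])
            key = frozenset([(ta, ga), (tb, gb)])
            if len(key) < 2 or key in seen:
                continue
            seen.add(key)
            out.append(PredictedContact(res_a=ta, atom_a=ga, res_b=tb, atom_b=gb,
                                        template_distance=d,
                                        supporting_template_ids=[template.id]))
    return out


def tripeptide_factor(alignment: AlignmentResult, target_residue_index: int) -> float:
    """Local-match weight around one aligned residue.

    1.0 when the aligned tripeptide (i-1, i, i+1) is identical between
    target and template, 0.5 when only the central residue matches, 0.0
    otherwise.  Chain termini apply the same rule to the available
    dipeptide.
    """
    mapping = alignment.target_to_template()
    i = target_residue_index
    if i not in mapping:
        raise ValueError(f"target residue {i} is not aligned")
    target = alignment.target_sequence
    template = alignment.template_sequence

    def matches(k: int) -> bool | None:
        """True/False for a comparable position, None when out of range."""
        if k < 1 or k > len(target):
            return None
        j = mapping.get(k)
        if j is None or j < 1 or j > len(template):
            return False
        return target[k - 1] == template[j - 1]

    center = matches(i)
    if not center:
        return 0.0
    flanks = [m for m in (matches(i - 1), matches(i + 1)) if m is not None]
    return 1.0 if all(flanks) else 0.5


def merge_contacts(per_template: list[list[PredictedContact]],
                   alignments: list[AlignmentResult]) -> list[PredictedContact]:
    """Combine contacts predicted by several templates.

    Template distance keeps the minimum; each supporting template
    contributes a tripeptide factor equal to the weaker of its local-match
    weights at the two contact residues.
    """
    by_alignment = {a.template_id: a for a in alignments}
    merged: dict[frozenset, PredictedContact] = {}
    for contacts in per_template:
        for c in contacts:
            tid = c.supporting_template_ids[0]
            aln = by_alignment[tid]
            factor = min(tripeptide_factor(aln, c.res_a), tripeptide_factor(aln, c.res_b))
            key = c.pair_key
            if key not in merged:
                merged[key] = PredictedContact(
                    res_a=c.res_a, atom_a=c.atom_a, res_b=c.res_b, atom_b=c.atom_b,
                    template_distance=c.template_distance)
            m = merged[key]
            m.template_distance = min(m.template_distance, c.template_distance)
            if tid not in m.supporting_template_ids:
                m.supporting_template_ids.append(tid)
                m.tripeptide_factors[tid] = factor
    return sorted(merged.values(), key=lambda c: (c.res_a, c.atom_a, c.res_b, c.atom_b))


# ------------------------------------------------------------- peak filtering

@dataclass
class FilterResult:
    """Retained contacts plus bookkeeping of why the rest were dropped."""

    retained: list[PredictedContact]
    no_shift: int = 0   # contacts whose atoms have no assigned shifts
    no_match: int = 0   # contacts with shifts but no matching peak

    def __iter__(self):
        return iter(self.retained)

    def __len__(self) -> int:
        return len(self.retained)


def filter_against_peaks(contacts: list[PredictedContact],
                         peak_lists: list[PeakList],
                         shift_table: ShiftTable,
                         tolerances: Tolerances | None = None) -> FilterResult:
    """Keep predicted contacts whose expected shift triple matches a peak.

    A contact is probed in both orientations (either proton may sit on the
    heavy-atom axis); the expected heavy shift is that of the heavy atom
    bonded to the first proton.  Retained contacts record the supporting
    peak ids.
    """
    tolerances = tolerances or Tolerances()
    shifts = shift_table.as_dict()
    types = {e.residue_index: e.residue_type for e in shift_table.entries}
    retained: list[PredictedContact] = []
    no_shift = no_match = 0
    for c in contacts:
        expected = []
        missing = False
        for (ri, ai), (rj, aj) in (((c.res_a, c.atom_a), (c.res_b, c.atom_b)),
                                   ((c.res_b, c.atom_b), (c.res_a, c.atom_a))):
            heavy = attached_heavy_atom(types.get(ri, "X"), ai)
            if heavy is None:
                continue
            if (ri, ai) not in shifts or (ri, heavy) not in shifts or (rj, aj) not in shifts:
                missing = True
                continue
            kind = "N15-NOESY" if heavy.startswith("N") else "C13-NOESY"
            expected.append((kind, shifts[(ri, ai)], shifts[(ri, heavy)], shifts[(rj, aj)]))
        if not expected:
            no_shift += 1
            continue
        support: list[int] = []
        for pl in peak_lists:
            for peak in pl.peaks:
                for kind, h1, hv, h2 in expected:
                    if (pl.spectrum_kind == kind
                            and abs(peak.shifts[0] - h1) <= tolerances.h
                            and abs(peak.shifts[1] - hv) <= tolerances.heavy
                            and abs(peak.shifts[2] - h2) <= tolerances.h):
                        support.append(peak.id)
                        break
        if support:
            c.supporting_peaks = sorted(set(support))
            retained.append(c)
        else:
            no_match += 1
    return FilterResult(retained=retained, no_shift=no_shift, no_match=no_match)


# ------------------------------------------------------------- template store

def predict_contacts(target_sequence: str, templates: list[TemplateEntry],
                     peak_lists: list[PeakList], shift_table: ShiftTable,
                     tolerances: Tolerances | None = None,
                     params: TemplateParams | None = None
                     ) -> tuple[list[PredictedContact], bool]:
    """Full database-assistance pass: align, select, hydrogenate, tabulate,
    merge and filter.  Returns (filtered contacts, single_template_mode)."""
    params = params or TemplateParams()
    alignments = [align(target_sequence, t.sequence, template_id=t.id, params=params)
                  for t in templates]
    selected, single = select_templates(alignments, params)
    if not selected:
        return [], False
    by_id = {t.id: t for t in templates}
    per_template = []
    for aln in selected:
        template = by_id[aln.template_id]
        hydrogenated = TemplateEntry(
            id=template.id, sequence=template.sequence,
            coords=add_hydrogens(template.coords))
        per_template.append(tabulate_contacts(hydrogenated, aln, params))
    merged = merge_contacts(per_template, selected)
    return list(filter_against_peaks(merged, peak_lists, shift_table, tolerances)), single


def load_template_store(directory: str | Path) -> list[TemplateEntry]:
    """Load a template store: a manifest.tsv (id, pdb_path, sequence) plus PDBs."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    out = []
    for line in manifest.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        tid, pdb_path, sequence = line.split("\t")
        coords = read_pdb(directory / pdb_path)[0]
        out.append(TemplateEntry(id=tid, sequence=sequence, coords=coords))
    return out


def write_template_store(templates: list[TemplateEntry], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    fasta = []
    for t in templates:
        pdb_name = f"{t.id}.pdb"
        write_pdb(t.coords, directory / pdb_name)
        rows.append(f"{t.id}\t{pdb_name}\t{t.sequence}")
        fasta.append(f">{t.id}\n{t.sequence}")
    (directory / "manifest.tsv").write_text("\n".join(rows) + "\n")
    (directory / "templates.fasta").write_text("\n".join(fasta) + "\n")
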