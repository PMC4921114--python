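"""Candidate assignment enumeration and the endurance scoring system.

Each NOESY cross peak is explained by every atom triple (proton, bonded
heavy atom, proton) whose assigned shifts fall within tolerance of the
peak position.  A peak with several explanations becomes one ambiguous
constraint whose effective distance is the r^-6 sum over members, so the
closest candidate pair dominates.

Scores: the endurance score starts high for unambiguous peaks and low for
ambiguous ones, and is decremented every cycle in proportion to how often
and how badly the constraint is violated across the ensemble; template
evidence adds a supportive score.  When the combined score drops below
zero the constraint moves to the recycle bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import attached_heavy_atom, group_atom, pseudoatom_correction
from .config import CalibrationParams, ScoringParams, Tolerances
from .io_formats.types import CrossPeak, PeakList, ShiftTable
from .restraints import CandidateAssignment, DistanceConstraint
from .templates import PredictedContact


# ------------------------------------------------------- candidate enumeration

def enumerate_candidates(peak: CrossPeak, shift_table: ShiftTable,
                         tolerances: Tolerances | None = None) -> list[CandidateAssignment]:
    """All atom triples that can explain a peak within tolerance.

    The heavy atom must be covalently bonded to the first proton and of the
    element selecting the spectrum (N for 15N-edited, C for 13C-edited).
    Candidates come back sorted by total absolute shift error, best first.
    """
    tolerances = tolerances or Tolerances()
    shifts = shift_table.as_dict()
    types = {e.residue_index: e.residue_type for e in shift_table.entries}
    want_element = "N" if peak.spectrum_kind == "N15-NOESY" else "C"
    w1, w2, w3 = peak.shifts

    first: list[tuple[int, str, str, float, float]] = []
    second: list[tuple[int, str, float]] = []
    for e in shift_table.entries:
        if not (e.atom_name.startswith("H") or e.atom_name.startswith("Q")):
            continue
        err3 = e.shift - w3
        if abs(err3) <= tolerances.h:
            second.append((e.residue_index, e.atom_name, err3))
        err1 = e.shift - w1
        if abs(err1) > tolerances.h:
            continue
        heavy = attached_heavy_atom(types[e.residue_index], e.atom_name)
        if heavy is None or heavy[0] != want_element:
            continue
        heavy_shift = shifts.get((e.residue_index, heavy))
        if heavy_shift is None:
            continue
        err2 = heavy_shift - w2
        if abs(err2) <= tolerances.heavy:
            first.append((e.residue_index, e.atom_name, heavy, err1, err2))

    out: list[CandidateAssignment] = []
    for ri, ai, heavy, err1, err2 in first:
        for rj, aj, err3 in second:
            if (ri, ai) == (rj, aj):
                continue
            out.append(CandidateAssignment(
                proton_a=(ri, ai), proton_b=(rj, aj), heavy_atom=(ri, heavy),
                shift_errors=(err1, err2, err3),
                res_type_a=types[ri], res_type_b=types[rj]))
    out.sort(key=lambda c: sum(abs(e) for e in c.shift_errors))
    return out


# ------------------------------------------------------------------ distances

def calibrate_upper_limit(intensity: float, reference_median_intensity: float,
                          params: CalibrationParams | None = None) -> float:
    """Intensity -> upper limit via the d^-6 law, anchored at the median.

    u = anchor * (I / I_med)^(-1/6), clipped to [floor, ceiling]; monotone
    non-increasing in intensity.
    """
    params = params or CalibrationParams()
    if intensity <= 0 or reference_median_intensity <= 0:
        raise ValueError("intensities must be positive")
    u = params.anchor * (intensity / reference_median_intensity) ** (-1.0 / 6.0)
    return float(np.clip(u, params.floor, params.ceiling))


def effective_distance(member_distances) -> float:
    """r^-6-summed effective distance: (sum d_i^-6)^(-1/6) <= min(d_i)."""
    d = np.asarray(list(member_distances), dtype=float)
    if d.size == 0:
        raise ValueError("effective distance of an empty member set is undefined")
    if np.any(d <= 0):
        raise ValueError("member distances must be positive")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


# -------------------------------------------------------------------- scores

def initial_endurance_score(candidates_count: int, shift_errors,
                            tolerances: Tolerances | None = None,
                            params: ScoringParams | None = None) -> float:
    """Initial assignment confidence.

    E0 = endurance_max / n_candidates * q with q the mean over dimensions of
    (1 - |error| / tolerance); unambiguous exact matches score the maximum,
    and the score strictly decreases with the number of candidates.
    """
    tolerances = tolerances or Tolerances()
    params = params or ScoringParams()
    if candidates_count < 1:
        raise ValueError("candidates_count must be >= 1")
    tol = (tolerances.h, tolerances.heavy, tolerances.h)
    q = float(np.mean([max(0.0, 1.0 - abs(e) / t) for e, t in zip(shift_errors, tol)]))
    return params.endurance_max / candidates_count * q


def supportive_score(constraint: DistanceConstraint,
                     predicted_contacts: list[PredictedContact],
                     single_template_mode: bool = False,
                     params: ScoringParams | None = None) -> float:
    """Template evidence for a constraint.

    S = support_unit * sum over supporting templates of the tripeptide
    factor, capped at support_cap (support_cap_single when a single close
    homolog is in use); zero when no predicted contact matches any member.
    """
    params = params or ScoringParams()
    by_key = {c.pair_key: c for c in predicted_contacts}
    best = 0.0
    for m in constraint.members:
        key = frozenset([
            (m.proton_a[0], group_atom(m.res_type_a, m.proton_a[1])),
            (m.proton_b[0], group_atom(m.res_type_b, m.proton_b[1]))])
        contact = by_key.get(key)
        if contact is None:
            continue
        s = params.support_unit * sum(contact.tripeptide_factors.values())
        best = max(best, s)
    cap = params.support_cap_single if single_template_mode else params.support_cap
    return float(min(best, cap))


def categorize(constraint: DistanceConstraint,
               params: ScoringParams | None = None) -> str:
    """robust / intermediate / uncertain from the combined score."""
    params = params or ScoringParams()
    overall = constraint.overall_score
    if overall >= params.robust_threshold:
        return "robust"
    if overall >= params.intermediate_threshold:
        return "intermediate"
    return "uncertain"


def update_scores(constraints: list[DistanceConstraint],
                  violation_reports: list[dict[int, float]],
                  params: ScoringParams | None = None
                  ) -> tuple[list[DistanceConstraint], list[DistanceConstraint]]:
    """Decrement endurance scores from ensemble violations; bin sub-zero ones.

    ``violation_reports`` holds one {constraint id: violation Å} mapping per
    model.  The penalty is 2 * f_viol * clamp(mean_violation / 1 Å, 0, 2)
    with f_viol the fraction of models violating by more than 0.2 Å; a
    constraint whose combined score goes below zero moves to the recycle
    bin.  Endurance scores never increase here.
    """
    params = params or ScoringParams()
    if not violation_reports:
        raise ValueError("need at least one violation report")
    for rep in violation_reports:
        missing = [c.id for c in constraints if c.id not in rep]
        if missing:
            raise ValueError(f"violation report missing constraint ids {missing}")
    kept: list[DistanceConstraint] = []
    recycled: list[DistanceConstraint] = []
    n_models = len(violation_reports)
    for c in constraints:
        viols = np.array([rep[c.id] for rep in violation_reports])
        violating = viols > params.distance_violation_cutoff
        f_viol = float(np.count_nonzero(violating)) / n_models
        if f_viol > 0:
            mean_v = float(viols[violating].mean())
            penalty = (params.violation_penalty * f_viol *
                       min(params.mean_violation_clamp, mean_v / params.mean_violation_scale))
            c.endurance_score -= penalty
        if c.overall_score < 0:
            c.in_recycle_bin = True
            recycled.append(c)
        else:
            kept.append(c)
    return kept, recycled


# -------------------------------------------------------- constraint building

def build_constraints(peak_lists: list[PeakList], shift_table: ShiftTable,
                      predicted_contacts: list[PredictedContact] | None = None,
                      single_template_mode: bool = False,
                      tolerances: Tolerances | None = None,
                      scoring_params: ScoringParams | None = None,
                      calibration: CalibrationParams | None = None
                      ) -> tuple[list[DistanceConstraint], int]:
    """Turn peak lists into scored, categorized distance constraints.

    Upper limits are calibrated against the median intensity of each peak
    list, with pseudoatom corrections (the largest correction over members
    is applied).  Returns (constraints, peaks with no candidate).
    """
    tolerances = tolerances or Tolerances()
    scoring_params = scoring_params or ScoringParams()
    calibration = calibration or CalibrationParams()
    contacts = predicted_contacts or []
    constraints: list[DistanceConstraint] = []
    unassigned = 0
    next_id = 0
    for pl in peak_lists:
        if not pl.peaks:
            continue
        median = float(np.median([p.intensity for p in pl.peaks]))
        for peak in pl.peaks:
            members = enumerate_candidates(peak, shift_table, tolerances)
            if not members:
                unassigned += 1
                continue
            upper = calibrate_upper_limit(peak.intensity, median, calibration)
            correction = max(
                pseudoatom_correction(m.res_type_a, m.proton_a[1]) +
                pseudoatom_correction(m.res_type_b, m.proton_b[1])
                for m in members)
            upper = float(np.clip(upper + correction,
                                  calibration.hard_lower, calibration.hard_upper))
            best = members[0]
            c = DistanceConstraint(
                members=members, upper_limit=upper,
                source_peak_id=peak.id, id=next_id,
                comment=f"{pl.spectrum_kind} peak {peak.id}")
            c.endurance_score = initial_endurance_score(
                len(members), best.shift_errors, tolerances, scoring_params)
            c.supportive_score = supportive_score(
                c, contacts, single_template_mode, scoring_params)
            c.category = categorize(c, scoring_params)
            constraints.append(c)
            next_id += 1
    return constraints, unassigned


# --------------------------------------------------------------------- ledger

LEDGER_HEADER = ("id\tsource_peak\tn_members\tmembers\tupper\tendurance\t"
                 "supportive\tcategory\tin_bin")


def dump_ledger(constraints: list[DistanceConstraint], path: str | Path) -> None:
    """Audit dump of the full scoring state as TSV (stable, fixed precision)."""
    lines = [LEDGER_HEADER]
    for c in sorted(constraints, key=lambda c: c.id):
        members = ";".join(
            f"{m.proton_a[0]}{m.proton_a[1]}-{m.proton_b[0]}{m.proton_b[1]}"
            for m in c.members)
        lines.append(f"{c.id}\t{c.source_peak_id}\t{len(c.members)}\t{members}\t"
                     f"{c.upper_limit:.3f}\t{c.endurance_score:.4f}\t"
                     f"{c.supportive_score:.4f}\t{c.category}\t{int(c.in_recycle_bin)}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class LedgerRow:
    id: int
    source_peak: int
    n_members: int
    members: str
    upper: float
    endurance: float
    supportive: float
    category: str
    in_bin: bool


def load_ledger(path: str | Path) -> list[LedgerRow]:
    rows = []
    for line in Path(path).read_text().splitlines()[1:]:
        f = line.split("\t")
        rows.append(LedgerRow(int(f[0]), int(f[1]), int(f[2]), f[3], float(f[4]),
                              float(f[5]), float(f[6]), f[7], bool(int(f[8]))))
    return rows
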