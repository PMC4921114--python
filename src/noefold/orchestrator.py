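"""Four-phase iterative structure calculation.

Phase I anneals against robust distance constraints only (plus angle and
H-bond constraints); phase II admits the intermediate category, phase III
the uncertain category, each after filtering the newly recruited
constraints against the lowest-energy model of the previous cycle (2.0 Å
allowance for phase II, a stricter 1.0 Å for phase III).  After every
cycle the endurance scores are updated from ensemble violations, sub-zero
constraints move to the recycle bin, bin members consistent with the
current model re-enter with a zero endurance score, angle limits expand
elastically where >= 30 % of models violate them, and hydrogen bonds are
re-detected and re-evaluated.  Phase IV refines the best models of phase
III under the frozen final constraint set and keeps the lowest-energy
subset (20 of 40 by default, 20 of 100 in final-step mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .engine import (StructureModel, anneal, evaluate_violations, refine,
                     select_best)
from .hbond import detect_hbonds, reevaluate
from .io_formats.constraints import write_constraints
from .io_formats.pdbio import write_pdb
from .io_formats.talos import TalosPrediction
from .io_formats.types import PeakList, ShiftTable
from .restraints import AngleConstraint, DistanceConstraint, HBondConstraint, RestraintSet
from .scoring import build_constraints, dump_ledger, update_scores
from .templates import TemplateEntry, predict_contacts
from .torsion import AngleViolationStats, build_constraints_from_talos, elastic_expand


@dataclass
class PhaseState:
    """Bookkeeping carried between phases/cycles."""

    phase: str
    cycle: int
    active: list[DistanceConstraint]
    recycle_bin: list[DistanceConstraint]
    discarded: list[DistanceConstraint]
    angle_constraints: list[AngleConstraint]
    hbonds: list[HBondConstraint]
    eliminated_hbonds: set[tuple[int, int]]
    best_model: StructureModel | None
    ensemble: list[StructureModel]
    log: list[dict] = field(default_factory=list)

    def check_partition(self, total: int) -> None:
        ids = ([c.id for c in self.active] + [c.id for c in self.recycle_bin]
               + [c.id for c in self.discarded])
        if sorted(ids) != list(range(total)):
            raise AssertionError("constraint ledger lost or duplicated entries")


@dataclass
class PipelineInputs:
    sequence: str
    shift_table: ShiftTable
    peak_lists: list[PeakList]
    talos: list[TalosPrediction] = field(default_factory=list)
    templates: list[TemplateEntry] = field(default_factory=list)


@dataclass
class PipelineResult:
    ensemble: list[StructureModel]
    final_constraints: list[DistanceConstraint]
    angle_constraints: list[AngleConstraint]
    hbonds: list[HBondConstraint]
    state: PhaseState
    n_unassigned_peaks: int
    endurance_map: dict[int, float]


# ------------------------------------------------------------------ one cycle

def _restraint_set(state: PhaseState) -> RestraintSet:
    return RestraintSet(distances=list(state.active),
                        angles=list(state.angle_constraints),
                        hbonds=[h for h in state.hbonds if h.active])


def _run_cycle(sequence: str, state: PhaseState, seed: int,
               config: PipelineConfig, all_constraints_total: int) -> None:
    """Anneal an ensemble, update scores, recycle, expand angles, re-detect H-bonds."""
    orc = config.orchestrator
    ensemble = anneal(sequence, _restraint_set(state), orc.models_per_cycle,
                      seed, config.engine)
    state.ensemble = ensemble
    state.best_model = ensemble[0]

    reports = [m.violations for m in ensemble]
    kept, recycled = update_scores(state.active,
                                   [r.distance for r in reports], config.scoring)
    state.active = kept

    # members binned in *earlier* cycles are checked against this ensemble,
    # which was annealed without them; constraints binned just now must wait
    # for the next cycle's model
    _recycle_check(state, config)
    state.recycle_bin.extend(recycled)

    # elastic angle expansion where >= 30 % of models violate
    expanded = []
    for c in state.angle_constraints:
        viols = np.array([r.angle.get(c.id, 0.0) for r in reports])
        violating = viols > 0
        n_viol = int(np.count_nonzero(violating))
        v_diff = float(viols[violating].mean()) if n_viol else 0.0
        stats = AngleViolationStats(v_diff=v_diff, n_viol=n_viol,
                                    ensemble_size=len(ensemble))
        expanded.append(elastic_expand(c, stats, config.torsion))
    state.angle_constraints = expanded

    # dynamic H-bonds: re-detect from current unambiguous assignments, then
    # re-evaluate against the best model; eliminated bonds stay eliminated
    detected = detect_hbonds(state.active, config.hbond)
    fresh = [h for h in detected if h.key not in state.eliminated_hbonds]
    merged = {h.key: h for h in state.hbonds if h.active}
    for h in fresh:
        merged.setdefault(h.key, h)
    surviving = reevaluate(list(merged.values()), state.best_model.coords, config.hbond)
    surviving_keys = {h.key for h in surviving}
    for key in set(merged) - surviving_keys:
        state.eliminated_hbonds.add(key)
    state.hbonds = surviving

    state.check_partition(all_constraints_total)
    state.log.append({
        "phase": state.phase, "cycle": state.cycle,
        "n_active": len(state.active), "n_bin": len(state.recycle_bin),
        "n_discarded": len(state.discarded),
        "n_hbonds": len(state.hbonds),
        "best_energy": round(state.best_model.total_energy, 4),
    })
    state.cycle += 1


def _recycle_check(state: PhaseState, config: PipelineConfig) -> None:
    """Bin members satisfied by the current model re-enter with score zero."""
    if state.best_model is None or not state.recycle_bin:
        return
    rs = RestraintSet(distances=state.recycle_bin)
    report = evaluate_violations(state.best_model, rs, config.engine)
    still_binned: list[DistanceConstraint] = []
    for c in state.recycle_bin:
        if report.distance.get(c.id, 0.0) <= config.orchestrator.recycle_tolerance:
            c.in_recycle_bin = False
            c.endurance_score = 0.0
            state.active.append(c)
        else:
            still_binned.append(c)
    state.recycle_bin = still_binned


def recycle_check(state: PhaseState, config: PipelineConfig | None = None) -> PhaseState:
    """Public wrapper: re-admit bin members the current model satisfies."""
    _recycle_check(state, config or PipelineConfig())
    return state


# -------------------------------------------------------------------- phases

def run_phase_I(sequence: str, constraints: list[DistanceConstraint],
                angle_constraints: list[AngleConstraint], seed: int,
                config: PipelineConfig,
                total_constraints: int | None = None) -> PhaseState:
    """Anneal with robust constraints only; others wait in `discarded` staging."""
    robust = [c for c in constraints if c.category == "robust"]
    if not robust:
        raise ValueError(
            "no robust constraints: review shift-matching tolerances and peak quality")
    later = [c for c in constraints if c.category != "robust"]
    state = PhaseState(phase="I", cycle=0, active=robust, recycle_bin=[],
                       discarded=later, angle_constraints=list(angle_constraints),
                       hbonds=[], eliminated_hbonds=set(), best_model=None,
                       ensemble=[])
    total = total_constraints if total_constraints is not None else len(constraints)
    for cyc in range(config.orchestrator.cycles_per_phase):
        _run_cycle(sequence, state, seed + 1000 * cyc, config, total)
    return state


def _admit_category(state: PhaseState, category: str, filter_threshold: float,
                    config: PipelineConfig) -> None:
    """Move staged constraints of one category into the active set, dropping
    those the previous phase's best model violates beyond the threshold."""
    staged = [c for c in state.discarded if c.category == category
              and not c.in_recycle_bin]
    staged_ids = {id(c) for c in staged}
    remaining = [c for c in state.discarded if id(c) not in staged_ids]
    if staged and state.best_model is not None:
        report = evaluate_violations(state.best_model,
                                     RestraintSet(distances=staged), config.engine)
        admitted = [c for c in staged
                    if report.distance.get(c.id, 0.0) <= filter_threshold]
        rejected = [c for c in staged
                    if report.distance.get(c.id, 0.0) > filter_threshold]
    else:
        admitted, rejected = staged, []
    state.active.extend(admitted)
    state.discarded = remaining + rejected


def run_phase_II(sequence: str, state: PhaseState, seed: int,
                 config: PipelineConfig, total_constraints: int) -> PhaseState:
    state.phase = "II"
    _admit_category(state, "intermediate", config.orchestrator.phase2_filter, config)
    for cyc in range(config.orchestrator.cycles_per_phase):
        _run_cycle(sequence, state, seed + 1000 * cyc, config, total_constraints)
    return state


def run_phase_III(sequence: str, state: PhaseState, seed: int,
                  config: PipelineConfig, total_constraints: int) -> PhaseState:
    state.phase = "III"
    _admit_category(state, "uncertain", config.orchestrator.phase3_filter, config)
    for cyc in range(config.orchestrator.cycles_per_phase):
        _run_cycle(sequence, state, seed + 1000 * cyc, config, total_constraints)
    return state


def run_phase_IV(sequence: str, state: PhaseState, seed: int,
                 config: PipelineConfig, n_models: int | None = None,
                 keep: int | None = None) -> list[StructureModel]:
    """Refine the transferred models under the frozen final constraint set."""
    orc = config.orchestrator
    n_models = n_models if n_models is not None else orc.phase4_models
    keep = keep if keep is not None else orc.phase4_keep
    state.phase = "IV"
    final_set = _restraint_set(state)
    transferred = state.ensemble
    models: list[StructureModel] = []
    for k in range(n_models):
        base = transferred[k % len(transferred)]
        perturb = 0.0 if k < len(transferred) else 0.3
        models.append(refine(base, final_set, config.engine,
                             perturbation=perturb, seed=seed + k))
    ensemble = select_best(models, keep)
    state.ensemble = ensemble
    state.best_model = ensemble[0]
    state.log.append({
        "phase": "IV", "cycle": state.cycle, "n_active": len(state.active),
        "n_bin": len(state.recycle_bin), "n_discarded": len(state.discarded),
        "n_hbonds": len(state.hbonds),
        "best_energy": round(state.best_model.total_energy, 4),
    })
    return ensemble


# ------------------------------------------------------------------ pipeline

def run_pipeline(inputs: PipelineInputs, config: PipelineConfig | None = None,
                 seed: int = 0, out_dir: str | Path | None = None,
                 final_step_only: bool = False,
                 n_models: int | None = None,
                 keep: int | None = None) -> PipelineResult:
    """Full run: contact prediction, constraint building, phases I-IV.

    Deterministic given (inputs, config, seed).  When ``out_dir`` is given,
    the final ensemble PDB, constraint tables, score ledger and per-cycle
    log are written there.
    """
    config = config or PipelineConfig()
    orc = config.orchestrator

    contacts, single_mode = ([], False)
    if orc.use_database and inputs.templates:
        contacts, single_mode = predict_contacts(
            inputs.sequence, inputs.templates, inputs.peak_lists,
            inputs.shift_table, config.tolerances, config.templates)

    constraints, n_unassigned = build_constraints(
        inputs.peak_lists, inputs.shift_table, contacts, single_mode,
        config.tolerances, config.scoring, config.calibration)
    if not constraints:
        raise ValueError("stage constraint-building, cycle 0: no assignable peaks")

    angle_constraints = build_constraints_from_talos(inputs.talos, config.torsion)

    if final_step_only and n_models is None:
        n_models = orc.final_step_models

    total = len(constraints)
    state: PhaseState | None = None

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            cycle = state.cycle if state is not None else 0
            raise RuntimeError(f"stage phase-{name}, cycle {cycle}: {exc}") from exc

    state = _stage("I", lambda: run_phase_I(
        inputs.sequence, constraints, angle_constraints, seed, config, total))
    state = _stage("II", lambda: run_phase_II(
        inputs.sequence, state, seed + 10_000, config, total))
    state = _stage("III", lambda: run_phase_III(
        inputs.sequence, state, seed + 20_000, config, total))
    ensemble = _stage("IV", lambda: run_phase_IV(
        inputs.sequence, state, seed + 30_000, config, n_models=n_models, keep=keep))

    result = PipelineResult(
        ensemble=ensemble,
        final_constraints=list(state.active),
        angle_constraints=state.angle_constraints,
        hbonds=state.hbonds,
        state=state,
        n_unassigned_peaks=n_unassigned,
        endurance_map={c.id: c.endurance_score for c in state.active},
    )
    if out_dir is not None:
        _write_results(result, Path(out_dir), config)
    return result


def _write_results(result: PipelineResult, out_dir: Path,
                   config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb([m.coords for m in result.ensemble], out_dir / "ensemble.pdb")
    all_constraints = (result.final_constraints + result.state.recycle_bin
                       + result.state.discarded)
    dump_ledger(all_constraints, out_dir / "score_ledger.tsv")
    if result.final_constraints:
        write_constraints(result.final_constraints, "cyana-upl", out_dir / "final.upl")
        write_constraints(result.final_constraints, "xplor-noe", out_dir / "final_noe.tbl")
    if result.angle_constraints:
        write_constraints(result.angle_constraints, "cyana-aco", out_dir / "final.aco")
        write_constraints(result.angle_constraints, "xplor-dihedral",
                          out_dir / "final_dihedral.tbl")
    if result.hbonds:
        from .hbond import write_hbond_files
        write_hbond_files(result.hbonds, out_dir / "hbond_noe.tbl",
                          out_dir / "hbond_hbda.tbl", config.hbond)
    log_lines = ["phase\tcycle\tn_active\tn_bin\tn_discarded\tn_hbonds\tbest_energy"]
    for row in result.state.log:
        log_lines.append("\t".join(str(row[k]) for k in
                                   ("phase", "cycle", "n_active", "n_bin",
                                    "n_discarded", "n_hbonds", "best_energy")))
    (out_dir / "cycles.log").write_text("\n".join(log_lines) + "\n")
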