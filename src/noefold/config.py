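"""Pipeline configuration.

Every tunable constant of the method lives here, grouped by the stage it
controls, so a run is fully described by (inputs, PipelineConfig, seed).
Values can be overridden from a YAML file whose top-level keys mirror the
section names (``tolerances:``, ``scoring:``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class Tolerances:
    """Chemical-shift matching tolerances (ppm)."""

    h: float = 0.03        # 1H dimensions
    heavy: float = 0.4     # 13C / 15N dimension


@dataclass
class ScoringParams:
    """Endurance / supportive scoring constants.

    The scoring system is defined by: an initial endurance score of
    ``endurance_max / n_candidates`` scaled by shift-match quality, a
    supportive score of ``support_unit`` per matching template (tripeptide
    weighted) capped at ``support_cap`` (``support_cap_single`` when a
    single >80 %-identity template is used), category thresholds on the
    combined score, and a violation penalty that sends sub-zero constraints
    to the recycle bin.
    """

    endurance_max: float = 10.0
    support_unit: float = 3.0
    support_cap: float = 9.0
    support_cap_single: float = 3.0
    robust_threshold: float = 8.0
    intermediate_threshold: float = 4.0
    violation_penalty: float = 2.0
    distance_violation_cutoff: float = 0.2   # Å above upper limit counts as violated
    mean_violation_scale: float = 1.0        # Å normalization of the mean violation
    mean_violation_clamp: float = 2.0


@dataclass
class CalibrationParams:
    """Intensity -> upper-limit calibration: u = anchor * (I/I_med)^(-1/6)."""

    anchor: float = 3.6
    floor: float = 2.4
    ceiling: float = 5.5
    hard_lower: float = 1.8   # absolute bounds on a written upper limit
    hard_upper: float = 7.0


@dataclass
class TemplateParams:
    """Database-assistance rules."""

    contact_cutoff: float = 5.5        # Å; template contacts below this are tabulated
    min_identity: float = 20.0         # % ; below -> no prediction
    single_identity: float = 80.0      # % ; above -> single-template mode
    max_templates: int = 3
    min_sequence_separation: int = 1   # |i-j| >= 1: intra-residue contacts dropped
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class TorsionParams:
    """TALOS-derived backbone angle constraint rules."""

    clamp_low: float = 10.0
    clamp_high: float = 35.0
    strong_multiplier: float = 2.0
    generous_multiplier: float = 3.0
    elastic_trigger: float = 0.30      # fraction of models violating
    elastic_coefficient: float = 1.2
    ensemble_size: int = 20
    max_half_width: float = 180.0


@dataclass
class HBondParams:
    """Dynamic H-bond detection and re-evaluation."""

    ho_ideal: float = 2.3     # Å upper limit written for H..O
    no_ideal: float = 3.3     # Å upper limit written for N..O
    ho_keep: float = 2.7      # Å; re-evaluation tolerance (ideal + 0.4)
    no_keep: float = 3.7
    noe_weight: float = 30.0  # NOE potential term weight for H-bond restraints
    min_strand_separation: int = 3


@dataclass
class EngineParams:
    """Restrained-annealing engine schedule and force constants.

    Temperatures are in reduced units of the Langevin noise term, not
    Kelvin; the schedule decays geometrically from t_hi to t_lo.
    """

    t_hi: float = 50.0
    t_lo: float = 0.01
    n_steps: int = 2000
    step_size: float = 5e-4
    # covalent geometry is much stiffer than the restraint terms, so that a
    # restraint inconsistent with the rest of the data stays measurably
    # violated instead of bending the model to accommodate it
    k_bond: float = 100.0
    k_angle: float = 60.0
    k_improper: float = 30.0
    k_distance: float = 1.0
    k_dihedral: float = 80.0
    k_repulsion: float = 10.0
    distance_lower: float = 1.8
    polish: bool = True         # final gradient minimization after annealing


@dataclass
class OrchestratorParams:
    """Four-phase iteration bookkeeping."""

    cycles_per_phase: int = 3
    models_per_cycle: int = 20
    phase2_filter: float = 2.0     # Å; entry filter for intermediate constraints
    phase3_filter: float = 1.0     # Å; stricter filter for uncertain constraints
    phase4_models: int = 40
    phase4_keep: int = 20
    final_step_models: int = 100   # "constraints only for the final step" mode
    recycle_tolerance: float = 0.2  # Å; bin members within this re-enter
    use_database: bool = True


@dataclass
class PipelineConfig:
    tolerances: Tolerances = field(default_factory=Tolerances)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    templates: TemplateParams = field(default_factory=TemplateParams)
    torsion: TorsionParams = field(default_factory=TorsionParams)
    hbond: HBondParams = field(default_factory=HBondParams)
    engine: EngineParams = field(default_factory=EngineParams)
    orchestrator: OrchestratorParams = field(default_factory=OrchestratorParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, values in raw.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section!r}")
            target = getattr(cfg, section)
            for key, value in (values or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key: {section}.{key}")
                setattr(target, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
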