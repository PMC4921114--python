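"""Backbone dihedral constraints from TALOS-style predictions.

Only strong and generous predictions are used.  Predicted deviations are
clamped to [10°, 35°]; initial half-widths are ±2x the clamped deviation
for strong predictions and ±3x for generous ones.  When a constraint is
violated in at least 30 % of the ensemble, its limits are expanded
elastically by 1.2 * V_diff * N_viol / ensemble_size on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import TorsionParams
from .io_formats.talos import TalosPrediction
from .restraints import AngleConstraint


@dataclass
class AngleViolationStats:
    """Ensemble violation summary for one angle constraint."""

    v_diff: float          # average violation over violating models (degrees)
    n_viol: int            # number of violating models
    ensemble_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_viol <= self.ensemble_size:
            raise ValueError("n_viol must lie in [0, ensemble_size]")
        if self.v_diff < 0:
            raise ValueError("average violation must be non-negative")


def clamp_deviation(predicted_deviation: float,
                    params: TorsionParams | None = None) -> float:
    """Clamp a predicted deviation into [10°, 35°] (<=10 -> 10, >35 -> 35)."""
    params = params or TorsionParams()
    if predicted_deviation < 0:
        raise ValueError("predicted deviation must be non-negative")
    return float(max(params.clamp_low, min(params.clamp_high, predicted_deviation)))


def build_constraint(residue_index: int, angle_name: str, center: float,
                     clamped_deviation: float, prediction_class: str,
                     params: TorsionParams | None = None) -> AngleConstraint:
    """Half-width = 2x (strong) or 3x (generous) the clamped deviation."""
    params = params or TorsionParams()
    if prediction_class == "strong":
        mult = params.strong_multiplier
    elif prediction_class == "generous":
        mult = params.generous_multiplier
    else:
        raise ValueError(
            f"only strong/generous predictions are used, got {prediction_class!r}")
    return AngleConstraint(residue_index=residue_index, angle_name=angle_name,
                           center=center, half_width=mult * clamped_deviation,
                           prediction_class=prediction_class,
                           predicted_deviation=clamped_deviation)


def build_constraints_from_talos(predictions: list[TalosPrediction],
                                 params: TorsionParams | None = None
                                 ) -> list[AngleConstraint]:
    """One phi and one psi constraint per usable prediction row."""
    params = params or TorsionParams()
    out: list[AngleConstraint] = []
    for p in predictions:
        if p.classification not in ("strong", "generous"):
            continue
        for angle, center, dev in (("phi", p.phi, p.dphi), ("psi", p.psi, p.dpsi)):
            c = build_constraint(p.residue_index, angle, center,
                                 clamp_deviation(dev, params),
                                 p.classification, params)
            c.id = len(out)
            out.append(c)
    return out


def elastic_expand(constraint: AngleConstraint, stats: AngleViolationStats,
                   params: TorsionParams | None = None) -> AngleConstraint:
    """Expand limits when >= 30 % of the ensemble violates the constraint.

    Both limits move outward by 1.2 * V_diff * N_viol / ensemble_size
    (degrees); below the trigger the constraint is returned unchanged.
    Expansion compounds over cycles but is capped at a half-width of 180°.
    """
    params = params or TorsionParams()
    frac = stats.n_viol / stats.ensemble_size
    if frac < params.elastic_trigger:
        return constraint
    growth = params.elastic_coefficient * stats.v_diff * stats.n_viol / stats.ensemble_size
    new_width = min(params.max_half_width, constraint.half_width + growth)
    return replace(constraint, half_width=new_width)
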