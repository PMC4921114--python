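"""Restraint domain types shared by the scoring, torsion, H-bond and engine layers.

A distance restraint is an upper limit on one proton pair, or — when the
originating cross peak could be explained by several pairs — an ambiguous
restraint over all of them, evaluated with the r^-6-summed effective
distance.  Each restraint carries the bookkeeping of the endurance scoring
system: an endurance score (initial assignment confidence, decremented by
structural violations), a supportive score (template evidence), a category,
and a recycle-bin flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AtomRef = tuple[int, str]  # (1-based residue index, atom name)

CATEGORIES = ("robust", "intermediate", "uncertain")


@dataclass(frozen=True)
class CandidateAssignment:
    """One way of explaining a cross peak with an atom triple."""

    proton_a: AtomRef
    proton_b: AtomRef
    heavy_atom: AtomRef
    shift_errors: tuple[float, float, float]  # ppm, (H_a, heavy, H_b)
    res_type_a: str = "X"
    res_type_b: str = "X"

    def __post_init__(self) -> None:
        if self.proton_a == self.proton_b:
            raise ValueError("candidate assignment requires two distinct protons")


@dataclass
class DistanceConstraint:
    """(Possibly ambiguous) upper-limit distance restraint with its scores."""

    members: list[CandidateAssignment]
    upper_limit: float                    # Å, after pseudoatom correction
    endurance_score: float = 0.0
    supportive_score: float = 0.0
    category: str = "uncertain"
    in_recycle_bin: bool = False
    source_peak_id: int | None = None
    id: int = 0
    lower_limit: float = 1.8
    weight: float = 1.0
    comment: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("distance constraint needs at least one member")
        if self.supportive_score < 0:
            raise ValueError("supportive score must be non-negative")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def overall_score(self) -> float:
        return self.endurance_score + self.supportive_score

    @property
    def ambiguous(self) -> bool:
        return len(self.members) > 1


@dataclass
class AngleConstraint:
    """Backbone dihedral restraint: center ± half_width (degrees)."""

    residue_index: int
    angle_name: str                       # "phi" | "psi"
    center: float
    half_width: float
    prediction_class: str = "strong"      # "strong" | "generous"
    predicted_deviation: float = 0.0
    id: int = 0

    def __post_init__(self) -> None:
        if self.angle_name not in ("phi", "psi"):
            raise ValueError(f"unknown angle {self.angle_name!r}")
        if self.half_width <= 0:
            raise ValueError("half width must be positive")
        if self.prediction_class not in ("strong", "generous"):
            raise ValueError(
                f"only strong/generous predictions are used, got {self.prediction_class!r}")


@dataclass
class HBondConstraint:
    """Idealized backbone hydrogen bond N-H(donor) ... O(acceptor)."""

    donor_residue: int
    acceptor_residue: int
    ho_upper: float = 2.3   # Å
    no_upper: float = 3.3   # Å
    active: bool = True
    id: int = 0

    def __post_init__(self) -> None:
        if self.donor_residue == self.acceptor_residue:
            raise ValueError("H-bond donor and acceptor must be different residues")
        if self.ho_upper <= 0 or self.no_upper <= 0:
            raise ValueError("H-bond target distances must be positive")

    @property
    def key(self) -> tuple[int, int]:
        return (self.donor_residue, self.acceptor_residue)


@dataclass
class RestraintSet:
    """Everything the annealing engine folds against (bonded terms are implicit)."""

    distances: list[DistanceConstraint] = field(default_factory=list)
    angles: list[AngleConstraint] = field(default_factory=list)
    hbonds: list[HBondConstraint] = field(default_factory=list)
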