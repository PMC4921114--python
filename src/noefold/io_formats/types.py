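"""Core in-memory containers for the external formats the pipeline touches."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ShiftEntry:
    residue_index: int       # 1-based
    residue_type: str        # 1-letter code
    atom_name: str
    shift: float             # ppm


@dataclass
class ShiftTable:
    """Chemical-shift assignment table.

    Invariants: residue indices are 1-based, no duplicate
    (residue_index, atom_name) pairs, all shifts finite.
    """

    entries: list[ShiftEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        dups = []
        for e in self.entries:
            if e.residue_index < 1:
                raise ValueError(f"residue index must be >= 1, got {e.residue_index}")
            if not np.isfinite(e.shift):
                raise ValueError(f"non-finite shift for residue {e.residue_index} {e.atom_name}")
            key = (e.residue_index, e.atom_name)
            if key in seen:
                dups.append(key)
            seen.add(key)
        if dups:
            names = ", ".join(f"residue {r} atom {a}" for r, a in dups)
            raise ValueError(f"duplicate shift entries: {names}")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, residue_index: int, atom_name: str) -> float | None:
        for e in self.entries:
            if e.residue_index == residue_index and e.atom_name == atom_name:
                return e.shift
        return None

    def as_dict(self) -> dict[tuple[int, str], float]:
        return {(e.residue_index, e.atom_name): e.shift for e in self.entries}


@dataclass
class CrossPeak:
    """One 3D NOESY cross peak: two proton shifts, one heavy-atom shift."""

    shifts: tuple[float, float, float]   # (H attached to heavy, heavy, other H) ppm
    intensity: float
    spectrum_kind: str = "N15-NOESY"
    id: int = 0
    assignment_hint: str | None = None

    def __post_init__(self) -> None:
        if len(self.shifts) != 3:
            raise ValueError("a cross peak carries exactly 3 shift values")
        if not (np.isfinite(self.intensity) and self.intensity > 0):
            raise ValueError(f"peak intensity must be finite and positive, got {self.intensity}")


SPECTRUM_KINDS = ("C13-NOESY", "N15-NOESY")


@dataclass
class PeakList:
    """An ordered 3D NOESY peak list with parse bookkeeping counters."""

    peaks: list[CrossPeak]
    spectrum_kind: str
    dimension_labels: tuple[str, str, str] = ("H", "X", "H")
    rows_read: int = 0
    rows_kept: int = 0
    rows_skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectrum_kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.spectrum_kind!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class CoordinateSet:
    """A Cartesian model: parallel arrays of atom metadata plus an (N, 3) array.

    residue_type uses 1-letter codes.  No two atoms may share
    (residue_index, atom_name) within one chain.
    """

    residue_indices: np.ndarray          # (N,) int
    residue_types: list[str]             # 1-letter codes, len N
    atom_names: list[str]                # len N
    coords: np.ndarray                   # (N, 3) float, Å
    chain_id: str = "A"
    model_number: int = 1

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_indices), 3):
            raise ValueError("coords shape does not match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.residue_indices.tolist(), self.atom_names))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue_index, atom_name) in coordinate set")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.atom_names)

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._index

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        return self._index[(residue_index, atom_name)]

    def position(self, residue_index: int, atom_name: str) -> np.ndarray:
        return self.coords[self._index[(residue_index, atom_name)]]

    def residue_numbers(self) -> list[int]:
        return sorted(set(self.residue_indices.tolist()))

    def residue_type_of(self, residue_index: int) -> str:
        pos = np.nonzero(self.residue_indices == residue_index)[0]
        if len(pos) == 0:
            raise KeyError(f"no residue {residue_index}")
        return self.residue_types[pos[0]]

    def sequence(self) -> str:
        return "".join(self.residue_type_of(i) for i in self.residue_numbers())

    def with_offset(self, offset: int) -> "CoordinateSet":
        """Shift residue numbering by ``offset`` (maps file numbering to target)."""
        return CoordinateSet(
            residue_indices=self.residue_indices + offset,
            residue_types=list(self.residue_types),
            atom_names=list(self.atom_names),
            coords=self.coords.copy(),
            chain_id=self.chain_id,
            model_number=self.model_number,
        )
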