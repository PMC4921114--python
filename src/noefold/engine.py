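"""Restrained simulated-annealing engine.

Folds a reduced Cartesian polymer model (backbone N, H, CA, HA, C, O plus
one side-chain pseudoatom QB per non-glycine residue) under a sum of
non-negative penalty terms:

* harmonic bonded geometry (bonds, angles, peptide/improper torsions),
* flat-bottom quadratic distance restraints, ambiguous ones evaluated with
  the r^-6-summed effective distance,
* wrap-aware flat-bottom backbone dihedral restraints,
* hydrogen-bond distance restraints at weight 30,
* a soft-sphere repulsion between non-bonded atoms.

Each model starts from a random-coil build (ideal local geometry, random
phi/psi), runs noisy gradient (Langevin) annealing with a geometric
temperature decay, and is polished by L-BFGS minimization.  The total
energy is zero exactly when every term sits inside its flat bottom.
Ideal bonded targets are measured from the internal-coordinate builder, so
the engine and the fixture generator agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._energy_core import energy_grad as _energy_grad_kernel
from ._energy_core import langevin as _langevin_kernel
from .config import EngineParams
from .geometry import wrap_degrees
from .io_formats.types import CoordinateSet
from .restraints import AngleConstraint, RestraintSet
from .synth import FixtureSpec, make_structure


@dataclass
class ViolationReport:
    """Per-restraint violation magnitudes for one model (exact, no tolerance)."""

    distance: dict[int, float] = field(default_factory=dict)   # Å above upper
    angle: dict[int, float] = field(default_factory=dict)      # degrees outside limits
    hbond: dict[int, float] = field(default_factory=dict)      # Å above target


@dataclass
class StructureModel:
    coords: CoordinateSet
    total_energy: float
    violations: ViolationReport = field(default_factory=ViolationReport)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.total_energy):
            raise ValueError("model energy must be finite")


# ------------------------------------------------------------------ topology

class Topology:
    """Reduced-representation atom list and bonded terms for a sequence."""

    def __init__(self, sequence: str):
        self.sequence = sequence.upper()
        n = len(self.sequence)
        if n < 2:
            raise ValueError("need at least two residues")
        self.atoms: list[tuple[int, str]] = []
        for i, aa in enumerate(self.sequence, start=1):
            self.atoms.append((i, "N"))
            if aa != "P":
                self.atoms.append((i, "H"))
            self.atoms.append((i, "CA"))
            self.atoms.append((i, "HA"))
            if aa != "G":
                self.atoms.append((i, "QB"))
            self.atoms.append((i, "C"))
            self.atoms.append((i, "O"))
        self.index = {a: k for k, a in enumerate(self.atoms)}
        self.n_atoms = len(self.atoms)
        self._build_terms()

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        key = (residue_index, atom_name)
        if key not in self.index:
            raise KeyError(f"atom {atom_name} of residue {residue_index} "
                           "is not part of the model representation")
        return self.index[key]

    def _build_terms(self) -> None:
        from .synth import (BOND_CA_C, BOND_CA_CB, BOND_CA_HA, BOND_C_N,
                            BOND_C_O, BOND_N_CA, BOND_N_H)

        ideal = {("N", "CA"): BOND_N_CA, ("CA", "C"): BOND_CA_C,
                 ("C", "O"): BOND_C_O, ("N", "H"): BOND_N_H,
                 ("CA", "HA"): BOND_CA_HA, ("CA", "QB"): BOND_CA_CB}
        bonds: list[tuple[int, int, float]] = []

        def bond(i: int, a: str, j: int, b: str, d0: float) -> None:
            if (i, a) in self.index and (j, b) in self.index:
                bonds.append((self.index[(i, a)], self.index[(j, b)], d0))

        n_res = len(self.sequence)
        for i in range(1, n_res + 1):
            bond(i, "N", i, "H", ideal[("N", "H")])
            bond(i, "N", i, "CA", ideal[("N", "CA")])
            bond(i, "CA", i, "HA", ideal[("CA", "HA")])
            bond(i, "CA", i, "QB", ideal[("CA", "QB")])
            bond(i, "CA", i, "C", ideal[("CA", "C")])
            bond(i, "C", i, "O", ideal[("C", "O")])
            if i < n_res:
                bond(i, "C", i + 1, "N", BOND_C_N)

        self.bond_i = np.array([b[0] for b in bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in bonds], dtype=int)
        self.bond_d0 = np.array([b[2] for b in bonds], dtype=float)

        # reference build: ideal targets for every angle/improper term are
        # measured on a helix built by the same internal-coordinate code
        ref = make_structure(FixtureSpec(sequence=self.sequence, topology="helix"))
        ref_x = np.array([ref.position(i, a) for i, a in self.atoms])

        neighbors: dict[int, list[int]] = {k: [] for k in range(self.n_atoms)}
        for i, j in zip(self.bond_i, self.bond_j):
            neighbors[int(i)].append(int(j))
            neighbors[int(j)].append(int(i))
        self.neighbors = neighbors

        ang: list[tuple[int, int, int]] = []
        for j, nb in neighbors.items():
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    ang.append((nb[a], j, nb[b]))
        self.ang_i = np.array([t[0] for t in ang], dtype=int)
        self.ang_j = np.array([t[1] for t in ang], dtype=int)
        self.ang_k = np.array([t[2] for t in ang], dtype=int)
        self.ang_t0 = _angles(ref_x, self.ang_i, self.ang_j, self.ang_k)

        # torsion-independent impropers + trans peptide omega
        imp: list[tuple[int, int, int, int]] = []

        def improper(*atoms: tuple[int, str]) -> None:
            if all(a in self.index for a in atoms):
                imp.append(tuple(self.index[a] for a in atoms))  # type: ignore

        for i in range(1, n_res + 1):
            improper((i, "N"), (i, "C"), (i, "CA"), (i, "HA"))
            improper((i, "N"), (i, "C"), (i, "CA"), (i, "QB"))
            if i > 1:
                improper((i - 1, "C"), (i, "CA"), (i, "N"), (i, "H"))
            if i < n_res:
                improper((i, "CA"), (i + 1, "N"), (i, "C"), (i, "O"))
                imp.append((self.index[(i, "CA")], self.index[(i, "C")],
                            self.index[(i + 1, "N")], self.index[(i + 1, "CA")]))
        self.imp_a = np.array([t[0] for t in imp], dtype=int)
        self.imp_b = np.array([t[1] for t in imp], dtype=int)
        self.imp_c = np.array([t[2] for t in imp], dtype=int)
        self.imp_d = np.array([t[3] for t in imp], dtype=int)
        self.imp_t0 = _dihedrals(ref_x, self.imp_a, self.imp_b, self.imp_c, self.imp_d)

        # soft-sphere repulsion: all pairs at bond-graph distance > 3
        dist = _graph_distances(neighbors, self.n_atoms, cutoff=3)
        rep_i, rep_j, rep_rmin = [], [], []
        names = [a[1] for a in self.atoms]
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                if dist.get((i, j), 99) <= 3:
                    continue
                hi = names[i].startswith(("H", "Q"))
                hj = names[j].startswith(("H", "Q"))
                rmin = 1.7 if (hi and hj) else (2.0 if (hi or hj) else 2.7)
                rep_i.append(i)
                rep_j.append(j)
                rep_rmin.append(rmin)
        self.rep_i = np.array(rep_i, dtype=int)
        self.rep_j = np.array(rep_j, dtype=int)
        self.rep_rmin = np.array(rep_rmin, dtype=float)

    def random_start(self, seed: int) -> np.ndarray:
        """Random-coil coordinates with ideal local geometry."""
        rng = np.random.default_rng(seed)
        n = len(self.sequence)
        phi_psi = [(float(rng.uniform(-180, 0)), float(rng.uniform(-180, 180)))
                   for _ in range(n)]
        coil = make_structure(FixtureSpec(sequence=self.sequence, topology="helix"),
                              phi_psi=phi_psi)
        return np.array([coil.position(i, a) for i, a in self.atoms])

    def to_coordinate_set(self, x: np.ndarray, model_number: int = 1) -> CoordinateSet:
        return CoordinateSet(
            residue_indices=np.array([a[0] for a in self.atoms]),
            residue_types=[self.sequence[a[0] - 1] for a in self.atoms],
            atom_names=[a[1] for a in self.atoms],
            coords=np.asarray(x, dtype=float),
            model_number=model_number)


def _graph_distances(neighbors: dict[int, list[int]], n: int,
                     cutoff: int) -> dict[tuple[int, int], int]:
    """Bond-graph distances up to ``cutoff`` (BFS from every atom)."""
    out: dict[tuple[int, int], int] = {}
    for start in range(n):
        frontier = [start]
        seen = {start: 0}
        for depth in range(1, cutoff + 1):
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v, d in seen.items():
            if v > start:
                out[(start, v)] = d
    return out


# ------------------------------------------------------- vectorized geometry

def _angles(x: np.ndarray, ai, aj, ak) -> np.ndarray:
    u = x[ai] - x[aj]
    v = x[ak] - x[aj]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.arccos(cosang)


def _dihedrals(x: np.ndarray, a, b, c, d) -> np.ndarray:
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2n)
    xcomp = np.einsum("ij,ij->i", n1, n2)
    ycomp = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(ycomp, xcomp)


def _dihedral_gradients(x: np.ndarray, a, b, c, d):
    """d(phi)/d(atom) for each dihedral; returns (phi, ga, gb, gc, gd)."""
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    b2n = b2 / nb2[:, None]
    m1 = np.cross(n1, b2n)
    phi = np.arctan2(np.einsum("ij,ij->i", m1, n2), np.einsum("ij,ij->i", n1, n2))
    sq1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
    sq2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
    ga = (nb2 / sq1)[:, None] * n1
    gd = -(nb2 / sq2)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
    gb = -(1.0 + s12) * ga + s32 * gd
    gc = s12 * ga - (1.0 + s32) * gd
    return phi, ga, gb, gc, gd


# --------------------------------------------------------------- energy model

class EnergyModel:
    """Total restraint energy and analytic gradient for one topology."""

    def __init__(self, topology: Topology, restraints: RestraintSet,
                 params: EngineParams | None = None):
        self.top = topology
        self.params = params or EngineParams()
        self._resolve(restraints)

    def _resolve(self, restraints: RestraintSet) -> None:
        top = self.top
        p = self.params
        mem_a, mem_b, mem_cid = [], [], []
        upper, lower, weight = [], [], []
        self.distance_ids: list[int] = []
        for n, c in enumerate(restraints.distances):
            for m in c.members:
                mem_a.append(top.atom_index(*m.proton_a))
                mem_b.append(top.atom_index(*m.proton_b))
                mem_cid.append(n)
            upper.append(c.upper_limit)
            lower.append(min(c.lower_limit, c.upper_limit))
            weight.append(c.weight)
            self.distance_ids.append(c.id)
        self.mem_a = np.array(mem_a, dtype=int)
        self.mem_b = np.array(mem_b, dtype=int)
        self.mem_cid = np.array(mem_cid, dtype=int)
        self.dist_upper = np.array(upper, dtype=float)
        self.dist_lower = np.array(lower, dtype=float)
        self.dist_weight = np.array(weight, dtype=float)
        self.n_dist = len(restraints.distances)

        dih_atoms, centers, widths = [], [], []
        self.angle_ids: list[int] = []
        for c in restraints.angles:
            dih_atoms.append(tuple(top.atom_index(r, a)
                                   for r, a in _backbone_dihedral_atoms(c)))
            centers.append(np.radians(c.center))
            widths.append(np.radians(c.half_width))
            self.angle_ids.append(c.id)
        if dih_atoms:
            arr = np.array(dih_atoms, dtype=int)
            self.dih_a, self.dih_b, self.dih_c, self.dih_d = arr.T
        else:
            self.dih_a = self.dih_b = self.dih_c = self.dih_d = np.array([], dtype=int)
        self.dih_center = np.array(centers, dtype=float)
        self.dih_width = np.array(widths, dtype=float)

        hb_h, hb_n, hb_o, hb_ho, hb_no = [], [], [], [], []
        self.hbond_ids: list[int] = []
        for hb in restraints.hbonds:
            if not hb.active:
                continue
            hb_h.append(top.atom_index(hb.donor_residue, "H"))
            hb_n.append(top.atom_index(hb.donor_residue, "N"))
            hb_o.append(top.atom_index(hb.acceptor_residue, "O"))
            hb_ho.append(hb.ho_upper)
            hb_no.append(hb.no_upper)
            self.hbond_ids.append(hb.id)
        self.hb_h = np.array(hb_h, dtype=int)
        self.hb_n = np.array(hb_n, dtype=int)
        self.hb_o = np.array(hb_o, dtype=int)
        self.hb_ho = np.array(hb_ho, dtype=float)
        self.hb_no = np.array(hb_no, dtype=float)
        self.hb_weight = 30.0  # static NOE potential weight for H-bond terms

    # -- energy + gradient ---------------------------------------------------

    def _kernel_args(self):
        top = self.top
        p = self.params
        return (top.bond_i, top.bond_j, top.bond_d0, float(p.k_bond),
                top.ang_i, top.ang_j, top.ang_k, top.ang_t0, float(p.k_angle),
                top.imp_a, top.imp_b, top.imp_c, top.imp_d, top.imp_t0,
                float(p.k_improper),
                self.mem_a, self.mem_b, self.mem_cid, self.n_dist,
                self.dist_upper, self.dist_lower, self.dist_weight,
                float(p.k_distance),
                self.dih_a, self.dih_b, self.dih_c, self.dih_d,
                self.dih_center, self.dih_width, float(p.k_dihedral),
                self.hb_h, self.hb_n, self.hb_o, self.hb_ho, self.hb_no,
                self.hb_weight,
                top.rep_i, top.rep_j, top.rep_rmin, float(p.k_repulsion))

    def __call__(self, flat_x: np.ndarray) -> tuple[float, np.ndarray]:
        energy, grad = _energy_grad_kernel(
            np.ascontiguousarray(flat_x, dtype=float).reshape(-1, 3),
            *self._kernel_args())
        return float(energy), grad.reshape(-1)

    # -- measurements --------------------------------------------------------

    def distance_violations(self, x: np.ndarray) -> np.ndarray:
        """Per-constraint max(0, d_eff - upper) in Å."""
        if not self.n_dist:
            return np.array([])
        dvec = x[self.mem_a] - x[self.mem_b]
        d = np.maximum(np.linalg.norm(dvec, axis=1), 1e-6)
        sums = np.bincount(self.mem_cid, weights=d ** -6.0, minlength=self.n_dist)
        d_eff = sums ** (-1.0 / 6.0)
        return np.maximum(0.0, d_eff - self.dist_upper)

    def angle_violations(self, x: np.ndarray) -> np.ndarray:
        """Per-constraint shortest-arc excess outside limits, degrees."""
        if not len(self.dih_a):
            return np.array([])
        phi = _dihedrals(x, self.dih_a, self.dih_b, self.dih_c, self.dih_d)
        delta = wrap_degrees(np.degrees(phi) - np.degrees(self.dih_center))
        return np.maximum(0.0, np.abs(delta) - np.degrees(self.dih_width))

    def hbond_violations(self, x: np.ndarray) -> np.ndarray:
        if not len(self.hb_h):
            return np.array([])
        ho = np.linalg.norm(x[self.hb_h] - x[self.hb_o], axis=1)
        no = np.linalg.norm(x[self.hb_n] - x[self.hb_o], axis=1)
        return np.maximum(np.maximum(0.0, ho - self.hb_ho),
                          np.maximum(0.0, no - self.hb_no))


def _backbone_dihedral_atoms(c: AngleConstraint) -> list[tuple[int, str]]:
    i = c.residue_index
    if c.angle_name == "phi":
        return [(i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")]
    return [(i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")]


# ------------------------------------------------------------------ annealing

def anneal(sequence: str, restraints: RestraintSet, n_models: int, seed: int,
           params: EngineParams | None = None) -> list[StructureModel]:
    """Fold ``n_models`` independent models and return them sorted by energy.

    Model k is seeded with seed + k: a random-coil start, Langevin dynamics
    with geometric cooling from t_hi to t_lo over n_steps, then (optionally)
    an L-BFGS polish.  Restraints referencing atoms absent from the model
    representation raise before any dynamics.
    """
    params = params or EngineParams()
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    top = Topology(sequence)
    model = EnergyModel(top, restraints, params)
    temps = params.t_hi * (params.t_lo / params.t_hi) ** (
        np.arange(params.n_steps) / max(1, params.n_steps - 1))
    out: list[StructureModel] = []
    for k in range(n_models):
        rng = np.random.default_rng(seed + k)
        x = top.random_start(int(rng.integers(2 ** 31)))
        noise = rng.standard_normal((params.n_steps, top.n_atoms, 3))
        x = _langevin_kernel(np.ascontiguousarray(x), noise, temps,
                             params.step_size, 500.0, *model._kernel_args())
        flat = x.reshape(-1)
        if params.polish:
            res = minimize(model, flat, jac=True, method="L-BFGS-B",
                           options={"maxiter": 300})
            if res.fun <= model(flat)[0]:
                flat = res.x
        energy, _ = model(flat)
        coords = top.to_coordinate_set(flat.reshape(-1, 3), model_number=k + 1)
        sm = StructureModel(coords=coords, total_energy=float(energy), seed=seed + k)
        sm.violations = _report(model, flat.reshape(-1, 3))
        out.append(sm)
    out.sort(key=lambda m: m.total_energy)
    return out


def refine(model: StructureModel, restraints: RestraintSet,
           params: EngineParams | None = None,
           perturbation: float = 0.0, seed: int = 0) -> StructureModel:
    """Minimize a model against a (possibly new) restraint set.

    With ``perturbation`` > 0 the coordinates are first jittered by that
    Gaussian sigma (Å).  The unperturbed refinement never increases the
    restraint energy.
    """
    params = params or EngineParams()
    top = Topology(model.coords.sequence())
    em = EnergyModel(top, restraints, params)
    x = np.array([model.coords.position(i, a) for i, a in top.atoms])
    flat = x.reshape(-1)
    start_energy, _ = em(flat)
    if perturbation > 0:
        rng = np.random.default_rng(seed)
        flat = flat + rng.normal(0.0, perturbation, size=flat.shape)
    res = minimize(em, flat, jac=True, method="L-BFGS-B", options={"maxiter": 500})
    final = res.x if res.fun <= start_energy or perturbation > 0 else flat
    energy, _ = em(final)
    coords = top.to_coordinate_set(final.reshape(-1, 3), model.coords.model_number)
    out = StructureModel(coords=coords, total_energy=float(energy), seed=seed)
    out.violations = _report(em, final.reshape(-1, 3))
    return out


def _report(em: EnergyModel, x: np.ndarray) -> ViolationReport:
    return ViolationReport(
        distance=dict(zip(em.distance_ids, em.distance_violations(x))),
        angle=dict(zip(em.angle_ids, em.angle_violations(x))),
        hbond=dict(zip(em.hbond_ids, em.hbond_violations(x))))


def evaluate_violations(model: StructureModel | CoordinateSet,
                        restraints: RestraintSet,
                        params: EngineParams | None = None) -> ViolationReport:
    """Exact per-restraint violations of a model (no tolerance applied)."""
    coords = model.coords if isinstance(model, StructureModel) else model
    top = Topology(coords.sequence())
    em = EnergyModel(top, restraints, params)
    x = np.array([coords.position(i, a) for i, a in top.atoms])
    return _report(em, x)


def select_best(models: list[StructureModel], keep: int) -> list[StructureModel]:
    """The ``keep`` lowest-energy models, stable order."""
    if keep > len(models):
        raise ValueError(f"cannot keep {keep} of {len(models)} models")
    ranked = sorted(models, key=lambda m: m.total_energy)
    return ranked[:keep]
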