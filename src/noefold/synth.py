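"""Synthetic test-input generation at desk scale.

Builds ideal-geometry toy proteins (helix, hairpin, helix-loop-helix),
synthetic chemical-shift tables, simulated 3D NOESY peak lists (with
controllable noise, planted wrong peaks and missing peaks), TALOS-style
angle predictions, and homolog templates at controlled sequence identity.

The atom representation matches the annealing engine: backbone N, H, CA,
HA, C, O plus one side-chain pseudoatom QB per non-glycine residue.
Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import STANDARD_AA
from .geometry import place_atom
from .io_formats.talos import TalosPrediction
from .io_formats.types import CoordinateSet, CrossPeak, PeakList, ShiftEntry, ShiftTable

# Ideal covalent geometry (Engh-Huber-like values, Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.01
BOND_CA_HA = 1.09
BOND_CA_CB = 1.53
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

# Canonical per-atom-kind chemical-shift means (ppm).  Per-residue jitter is
# added on top to create realistic near-degeneracy.
SHIFT_MEANS = {"H": 8.30, "N": 118.0, "HA": 4.30, "CA": 56.0, "QB": 1.80, "CB": 33.0}
H_JITTER = 0.3      # ppm, uniform half-width for 1H
HEAVY_JITTER = 3.0  # ppm, uniform half-width for 13C/15N

TOPOLOGIES = ("helix", "hairpin", "helix-loop-helix")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    sequence: str
    topology: str = "helix"
    noise_h: float = 0.003        # ppm Gaussian shift noise, 1H dimensions
    noise_heavy: float = 0.05     # ppm Gaussian shift noise, heavy dimension
    intensity_noise: float = 0.2  # sigma of the lognormal intensity factor
    planted_fraction: float = 0.0
    missing_fraction: float = 0.0
    template_identities: list[float] = field(default_factory=list)
    peak_cutoff: float = 5.0      # Å; proton pairs closer than this give a peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unsupported topology {self.topology!r}")
        bad = sorted(set(self.sequence.upper()) - STANDARD_AA)
        if bad:
            raise ValueError(f"non-standard residues: {bad}")
        for frac in (self.planted_fraction, self.missing_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for ident in self.template_identities:
            if not 0.0 < ident <= 100.0:
                raise ValueError("template identities must lie in (0, 100]")


def topology_angles(topology: str, n: int) -> list[tuple[float, float]]:
    """Per-residue (phi, psi) for the supported toy topologies."""
    if topology == "helix":
        return [(HELIX_PHI, HELIX_PSI)] * n
    if topology == "hairpin":
        half = (n - 2) // 2
        strand = [(STRAND_PHI, STRAND_PSI)]
        turn = [(57.0, 38.0), (78.0, 6.0)]  # type I' turn
        return strand * half + turn + strand * (n - half - 2)
    # helix-loop-helix
    h = max(3, (n - 4) // 2)
    loop = [(-75.0, 145.0), (-65.0, -40.0), (-100.0, 120.0), (-80.0, 150.0)]
    angles = [(HELIX_PHI, HELIX_PSI)] * h + loop + [(HELIX_PHI, HELIX_PSI)] * (n - h - 4)
    return angles[:n]


def make_structure(spec: FixtureSpec,
                   phi_psi: list[tuple[float, float]] | None = None) -> CoordinateSet:
    """Build an ideal-geometry toy structure for a fixture's sequence/topology.

    The backbone is chained by internal coordinates (NeRF); amide H, HA, O
    and the QB side-chain pseudoatom are placed with ideal geometry.
    """
    seq = spec.sequence.upper()
    n = len(seq)
    if phi_psi is None:
        phi_psi = topology_angles(spec.topology, n)
    if len(phi_psi) != n:
        raise ValueError("phi/psi list length does not match sequence")

    bb_n = np.zeros((n, 3))
    bb_ca = np.zeros((n, 3))
    bb_c = np.zeros((n, 3))
    bb_n[0] = (0.0, 0.0, 0.0)
    bb_ca[0] = (BOND_N_CA, 0.0, 0.0)
    bb_c[0] = bb_ca[0] + BOND_CA_C * np.array(
        [-np.cos(np.radians(ANGLE_N_CA_C)), np.sin(np.radians(ANGLE_N_CA_C)), 0.0])
    for i in range(n - 1):
        psi = phi_psi[i][1]
        phi_next = phi_psi[i + 1][0]
        bb_n[i + 1] = place_atom(bb_n[i], bb_ca[i], bb_c[i], BOND_C_N, ANGLE_CA_C_N, psi)
        bb_ca[i + 1] = place_atom(bb_ca[i], bb_c[i], bb_n[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        bb_c[i + 1] = place_atom(bb_c[i], bb_n[i + 1], bb_ca[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)

    resi: list[int] = []
    rest: list[str] = []
    names: list[str] = []
    xyz: list[np.ndarray] = []

    def add(idx: int, name: str, pos: np.ndarray) -> None:
        resi.append(idx)
        rest.append(seq[idx - 1])
        names.append(name)
        xyz.append(np.asarray(pos, dtype=float))

    for i in range(n):
        idx = i + 1
        add(idx, "N", bb_n[i])
        add(idx, "CA", bb_ca[i])
        add(idx, "C", bb_c[i])
        # carbonyl O: anti-periplanar to the next amide N
        o_torsion = phi_psi[i][1] + 180.0
        add(idx, "O", place_atom(bb_n[i], bb_ca[i], bb_c[i], BOND_C_O, ANGLE_CA_C_O, o_torsion))
        if seq[i] != "P":
            if i == 0:
                h = place_atom(bb_c[0], bb_ca[0], bb_n[0], BOND_N_H, 118.2, 180.0)
            else:
                u1 = _unit(bb_n[i] - bb_c[i - 1])
                u2 = _unit(bb_n[i] - bb_ca[i])
                h = bb_n[i] + BOND_N_H * _unit(u1 + u2)
            add(idx, "H", h)
        ha, qb = _tetrahedral_pair(bb_n[i], bb_ca[i], bb_c[i])
        add(idx, "HA", ha)
        if seq[i] != "G":
            add(idx, "QB", qb)

    return CoordinateSet(residue_indices=np.array(resi), residue_types=rest,
                         atom_names=names, coords=np.array(xyz))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tetrahedral_pair(n_pos, ca_pos, c_pos):
    """HA (1.09 Å) and CB-pseudoatom (1.53 Å) directions off CA, completing a
    tetrahedron over the N and C substituents; QB takes the +perp side, which
    fixes a consistent (L-like) handedness across the package."""
    d1 = _unit(n_pos - ca_pos)
    d2 = _unit(c_pos - ca_pos)
    bis = _unit(d1 + d2)
    perp = _unit(np.cross(d1, d2))
    cos_half = float(np.dot(bis, d1))
    alpha = (-1.0 / 3.0) / cos_half          # dir . d1 = cos(109.47 deg)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    qb_dir = alpha * bis + beta * perp
    ha_dir = alpha * bis - beta * perp
    return ca_pos + BOND_CA_HA * ha_dir, ca_pos + BOND_CA_CB * qb_dir


# --------------------------------------------------------------- shift table

def make_shift_table(spec: FixtureSpec) -> ShiftTable:
    """Canonical atom-type shifts plus deterministic per-residue jitter."""
    rng = np.random.default_rng(spec.seed + 101)
    seq = spec.sequence.upper()
    entries: list[ShiftEntry] = []
    for i, aa in enumerate(seq, start=1):
        atoms = ["N", "CA"] + (["CB"] if aa != "G" else [])
        atoms += (["H"] if aa != "P" else []) + ["HA"] + (["QB"] if aa != "G" else [])
        for name in atoms:
            mean = SHIFT_MEANS[name]
            half = H_JITTER if name in ("H", "HA", "QB") else HEAVY_JITTER
            entries.append(ShiftEntry(i, aa, name, mean + rng.uniform(-half, half)))
    return ShiftTable(entries=entries)


# ----------------------------------------------------------------- peak list

def _proton_atoms(structure: CoordinateSet):
    from .chem import is_proton
    return [k for k in range(len(structure)) if is_proton(structure.atom_names[k])]


def simulate_peaks(structure: CoordinateSet, shift_table: ShiftTable,
                   spec: FixtureSpec, spectrum_kind: str = "N15-NOESY") -> PeakList:
    """Simulate one 3D NOESY peak list from a structure.

    One peak per ordered proton pair closer than ``spec.peak_cutoff`` whose
    first proton sits on a heavy atom of the spectrum's type; intensity is
    d^-6 with lognormal noise, shift positions get Gaussian noise.  Planted
    wrong peaks pair real but distant atoms (labelled "noise" in the
    assignment hint); a ``missing_fraction`` of true peaks is removed.
    """
    from .chem import attached_heavy_atom

    rng = np.random.default_rng(spec.seed + 202)
    shifts = shift_table.as_dict()
    want_element = "N" if spectrum_kind == "N15-NOESY" else "C"
    protons = _proton_atoms(structure)

    def proton_info(k):
        ri = int(structure.residue_indices[k])
        name = structure.atom_names[k]
        heavy = attached_heavy_atom(structure.residue_types[k], name)
        return ri, name, heavy

    true_pairs = []
    for a in protons:
        ria, na, ha = proton_info(a)
        if ha is None or ha[0] != want_element:
            continue
        if (ria, na) not in shifts or (ria, ha) not in shifts:
            continue
        for b in protons:
            if b == a:
                continue
            rib, nb, _ = proton_info(b)
            if (rib, nb) not in shifts:
                continue
            d = float(np.linalg.norm(structure.coords[a] - structure.coords[b]))
            if d < spec.peak_cutoff:
                true_pairs.append((a, b, d))

    keep = np.ones(len(true_pairs), dtype=bool)
    if spec.missing_fraction > 0:
        n_drop = int(round(spec.missing_fraction * len(true_pairs)))
        keep[rng.choice(len(true_pairs), size=n_drop, replace=False)] = False

    peaks: list[CrossPeak] = []
    for (a, b, d), kept in zip(true_pairs, keep):
        if not kept:
            continue
        ria, na, ha = proton_info(a)
        rib, nb, _ = proton_info(b)
        w1 = shifts[(ria, na)] + rng.normal(0.0, spec.noise_h)
        w2 = shifts[(ria, ha)] + rng.normal(0.0, spec.noise_heavy)
        w3 = shifts[(rib, nb)] + rng.normal(0.0, spec.noise_h)
        intensity = 1.0e8 * d ** -6
        if spec.intensity_noise > 0:
            intensity *= float(np.exp(rng.normal(0.0, spec.intensity_noise)))
        hint = f"{structure.residue_types[a]}{ria}{na}-{structure.residue_types[b]}{rib}{nb}"
        peaks.append(CrossPeak(shifts=(w1, w2, w3), intensity=intensity,
                               spectrum_kind=spectrum_kind, id=len(peaks),
                               assignment_hint=hint))

    n_planted = int(round(spec.planted_fraction * len(true_pairs)))
    planted = 0
    attempts = 0
    while planted < n_planted and attempts < 200 * max(1, n_planted):
        attempts += 1
        a = int(rng.choice(protons))
        b = int(rng.choice(protons))
        if a == b:
            continue
        ria, na, ha = proton_info(a)
        rib, nb, _ = proton_info(b)
        if ha is None or ha[0] != want_element:
            continue
        if (ria, na) not in shifts or (ria, ha) not in shifts or (rib, nb) not in shifts:
            continue
        d = float(np.linalg.norm(structure.coords[a] - structure.coords[b]))
        if d < 6.5:
            continue
        w1 = shifts[(ria, na)] + rng.normal(0.0, spec.noise_h)
        w2 = shifts[(ria, ha)] + rng.normal(0.0, spec.noise_heavy)
        w3 = shifts[(rib, nb)] + rng.normal(0.0, spec.noise_h)
        if not _triple_is_wrong(structure, shifts, proton_info, protons,
                                want_element, (w1, w2, w3)):
            continue  # some close pair also explains this triple: not a
            #           genuinely wrong peak, try again
        intensity = 1.0e8 * 3.5 ** -6 * float(np.exp(rng.normal(0.0, max(spec.intensity_noise, 0.1))))
        peaks.append(CrossPeak(shifts=(w1, w2, w3), intensity=intensity,
                               spectrum_kind=spectrum_kind, id=len(peaks),
                               assignment_hint="noise"))
        planted += 1

    return PeakList(peaks=peaks, spectrum_kind=spectrum_kind,
                    rows_read=len(peaks), rows_kept=len(peaks))


def _triple_is_wrong(structure, shifts, proton_info, protons, want_element,
                     triple, tol_h: float = 0.03, tol_heavy: float = 0.4,
                     min_effective: float = 5.5) -> bool:
    """A planted peak is only a genuine error if *no* credible assignment of
    its shift triple corresponds to a close proton pair in the truth; the
    r^-6-pooled distance over every matching pair must stay long."""
    w1, w2, w3 = triple
    inv6 = 0.0
    for a in protons:
        ria, na, ha = proton_info(a)
        if ha is None or ha[0] != want_element:
            continue
        sa = shifts.get((ria, na))
        sh = shifts.get((ria, ha))
        if sa is None or sh is None:
            continue
        if abs(sa - w1) > tol_h or abs(sh - w2) > tol_heavy:
            continue
        for b in protons:
            if b == a:
                continue
            rib, nb, _ = proton_info(b)
            sb = shifts.get((rib, nb))
            if sb is None or abs(sb - w3) > tol_h:
                continue
            d = float(np.linalg.norm(structure.coords[a] - structure.coords[b]))
            inv6 += d ** -6.0
    if inv6 == 0.0:
        return False  # assigns to nothing: would never become a constraint
    return inv6 ** (-1.0 / 6.0) > min_effective


# -------------------------------------------------------------------- TALOS

def make_talos_predictions(spec: FixtureSpec, deviation: float = 12.0,
                           classification: str = "strong") -> list[TalosPrediction]:
    """TALOS-style predictions matching the generating topology's phi/psi."""
    seq = spec.sequence.upper()
    angles = topology_angles(spec.topology, len(seq))
    out = []
    for i, ((phi, psi), aa) in enumerate(zip(angles, seq), start=1):
        if i == 1 or i == len(seq):
            continue  # chain termini have no complete phi/psi
        out.append(TalosPrediction(residue_index=i, residue_type=aa,
                                   phi=phi, psi=psi, dphi=deviation,
                                   dpsi=deviation, classification=classification))
    return out


# ---------------------------------------------------------------- templates

def make_homolog(structure: CoordinateSet, target_identity_pct: float, seed: int):
    """Mutate a structure's sequence to a requested alignment identity.

    Substitutions avoid glycine/proline (so the toy atom set is unchanged);
    coordinates are perturbed by 0.3 Å Gaussian noise so the template is not
    bit-identical to the truth.  The achieved identity is verified through
    the alignment operation and must land within ±2 % of the request.
    """
    from .templates import TemplateEntry, align

    if not 0.0 < target_identity_pct <= 100.0:
        raise ValueError("identity must lie in (0, 100]")
    rng = np.random.default_rng(seed)
    seq = structure.sequence()
    n = len(seq)
    candidates = "ACDEFHIKLMNQRSTVWY"  # no G, no P

    def mutate(k: int) -> str:
        positions = rng.choice(n, size=k, replace=False)
        chars = list(seq)
        for p in positions:
            choices = [c for c in candidates if c != seq[p]]
            chars[p] = choices[int(rng.integers(len(choices)))]
        return "".join(chars)

    base_k = int(round(n * (1.0 - target_identity_pct / 100.0)))
    trial_ks = [max(0, min(n, base_k + d))
                for d in (0, -1, 1, -2, 2, -3, 3, -4, 4)]
    # several mutation draws per k: at high mutation loads the alignment may
    # open gaps and report a higher identity than the substitution count implies
    for k in dict.fromkeys(trial_ks):
        for _ in range(25):
            mutated = seq if k == 0 else mutate(k)
            measured = align(seq, mutated).identity_pct
            if abs(measured - target_identity_pct) <= 2.0:
                break
        if abs(measured - target_identity_pct) <= 2.0:
            coords = structure.coords + rng.normal(0.0, 0.3, size=structure.coords.shape)
            template_coords = CoordinateSet(
                residue_indices=structure.residue_indices.copy(),
                residue_types=list(mutated[i - 1] for i in structure.residue_indices),
                atom_names=list(structure.atom_names),
                coords=coords)
            return TemplateEntry(id=f"synth-{target_identity_pct:.0f}pct-{seed}",
                                 sequence=mutated, coords=template_coords)
    raise ValueError(
        f"identity {target_identity_pct} % unreachable within ±2 % for length {n}")


# ------------------------------------------------------------------- bundle

@dataclass
class Fixture:
    spec: FixtureSpec
    structure: CoordinateSet
    shift_table: ShiftTable
    peak_lists: list[PeakList]
    talos: list[TalosPrediction]
    templates: list


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the full input bundle for one synthetic study."""
    structure = make_structure(spec)
    shift_table = make_shift_table(spec)
    peak_lists = [simulate_peaks(structure, shift_table, spec, kind)
                  for kind in ("N15-NOESY", "C13-NOESY")]
    talos = make_talos_predictions(spec)
    templates = [make_homolog(structure, ident, spec.seed + 900 + j)
                 for j, ident in enumerate(spec.template_identities)]
    return Fixture(spec=spec, structure=structure, shift_table=shift_table,
                   peak_lists=peak_lists, talos=talos, templates=templates)
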