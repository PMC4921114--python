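"""Annealing engine: energy model, violations, determinism, recovery."""

from __future__ import annotations

import numpy as np
import pytest

from noefold.config import EngineParams
from noefold.engine import (EnergyModel, Topology, anneal, evaluate_violations,
                            refine, select_best)
from noefold.geometry import arc_excess, dihedral, kabsch_rmsd
from noefold.restraints import (AngleConstraint, CandidateAssignment,
                                DistanceConstraint, HBondConstraint, RestraintSet)
from noefold.scoring import build_constraints, effective_distance
from noefold.torsion import build_constraints_from_talos

from conftest import backbone_coords


def _distance(members, upper, cid=0):
    ms = [CandidateAssignment(proton_a=a, proton_b=b, heavy_atom=(a[0], "N"),
                              shift_errors=(0, 0, 0)) for a, b in members]
    return DistanceConstraint(members=ms, upper_limit=upper, id=cid)


@pytest.fixture(scope="module")
def helix_restraints(helix_peaks, helix_shifts, helix_talos):
    constraints, _ = build_constraints(helix_peaks, helix_shifts)
    angles = build_constraints_from_talos(helix_talos)
    return RestraintSet(distances=constraints, angles=angles)


class TestEnergyModel:
    def test_gradient_matches_finite_differences(self, helix_structure,
                                                 helix_restraints):
        top = Topology(helix_structure.sequence())
        em = EnergyModel(top, helix_restraints)
        rng = np.random.default_rng(0)
        x0 = np.array([helix_structure.position(i, a) for i, a in top.atoms])
        x0 = (x0 + rng.normal(0, 0.25, x0.shape)).reshape(-1)
        _, grad = em(x0)
        for k in rng.integers(0, len(x0), 25):
            h = 1e-6
            xp, xm = x0.copy(), x0.copy()
            xp[k] += h
            xm[k] -= h
            fd = (em(xp)[0] - em(xm)[0]) / (2 * h)
            assert grad[k] == pytest.approx(fd, abs=1e-4, rel=1e-4)

    def test_energy_zero_on_satisfied_model(self, helix_structure):
        # restraints the ideal helix satisfies comfortably -> zero energy
        rs = RestraintSet(distances=[_distance([((2, "H"), (3, "H"))], 4.0)],
                          angles=[AngleConstraint(residue_index=5, angle_name="phi",
                                                  center=-57.0, half_width=20.0)],
                          hbonds=[HBondConstraint(donor_residue=6,
                                                  acceptor_residue=2)])
        top = Topology(helix_structure.sequence())
        em = EnergyModel(top, rs)
        x = np.array([helix_structure.position(i, a) for i, a in top.atoms])
        assert em(x.reshape(-1))[0] == pytest.approx(0.0, abs=1e-9)

    def test_energy_positive_once_a_restraint_is_violated(self, helix_structure):
        rs = RestraintSet(distances=[_distance([((2, "H"), (11, "H"))], 3.0)])
        top = Topology(helix_structure.sequence())
        em = EnergyModel(top, rs)
        x = np.array([helix_structure.position(i, a) for i, a in top.atoms])
        assert em(x.reshape(-1))[0] > 0.0

    def test_unresolvable_restraint_atom_raises_before_dynamics(self):
        rs = RestraintSet(distances=[_distance([((1, "H"), (99, "H"))], 3.0)])
        with pytest.raises(KeyError, match="residue 99"):
            anneal("AEKLLA", rs, n_models=1, seed=0)


class TestEvaluateViolations:
    def test_distance_violation_is_excess_over_upper(self, helix_structure):
        d_true = float(np.linalg.norm(helix_structure.position(2, "H")
                                      - helix_structure.position(5, "H")))
        rs = RestraintSet(distances=[_distance([((2, "H"), (5, "H"))],
                                               d_true - 0.5)])
        report = evaluate_violations(helix_structure, rs)
        assert report.distance[0] == pytest.approx(0.5, abs=1e-9)

    def test_ambiguous_pair_uses_effective_distance(self, helix_structure):
        # one close member dominates the r^-6 sum: no violation
        close = ((2, "H"), (3, "H"))
        far = ((2, "H"), (11, "H"))
        d_close = float(np.linalg.norm(helix_structure.position(*close[0])
                                       - helix_structure.position(*close[1])))
        rs = RestraintSet(distances=[_distance([close, far], d_close + 0.2)])
        report = evaluate_violations(helix_structure, rs)
        assert report.distance[0] == pytest.approx(0.0)

    def test_dihedral_violation_is_wrap_aware_arc_excess(self, helix_structure):
        rng = np.random.default_rng(4)
        for _ in range(50):
            center = float(rng.uniform(-180, 180))
            width = float(rng.uniform(5, 40))
            c = AngleConstraint(residue_index=6, angle_name="psi",
                                center=center, half_width=width, id=0)
            report = evaluate_violations(helix_structure,
                                         RestraintSet(angles=[c]))
            psi = dihedral(helix_structure.position(6, "N"),
                           helix_structure.position(6, "CA"),
                           helix_structure.position(6, "C"),
                           helix_structure.position(7, "N"))
            assert report.angle[0] == pytest.approx(
                arc_excess(psi, center, width), abs=1e-6)

    def test_agrees_with_brute_force_on_random_models(self, helix_structure,
                                                      helix_restraints):
        top = Topology(helix_structure.sequence())
        rng = np.random.default_rng(11)
        base = np.array([helix_structure.position(i, a) for i, a in top.atoms])
        for _ in range(100):
            coords = top.to_coordinate_set(base + rng.normal(0, 0.7, base.shape))
            report = evaluate_violations(coords, helix_restraints)
            # brute force: recompute three random distance restraints
            for c in [helix_restraints.distances[int(k)]
                      for k in rng.integers(0, len(helix_restraints.distances), 3)]:
                ds = [float(np.linalg.norm(coords.position(*m.proton_a)
                                           - coords.position(*m.proton_b)))
                      for m in c.members]
                expected = max(0.0, effective_distance(ds) - c.upper_limit)
                assert report.distance[c.id] == pytest.approx(expected, abs=1e-9)


class TestAnneal:
    def test_single_restraint_is_satisfied_from_an_extended_start(self):
        # the only long-range information pulls residues 1 and 6 together
        rs = RestraintSet(distances=[_distance([((1, "HA"), (6, "HA"))], 3.0)])
        models = anneal("AAKLSA", rs, n_models=2, seed=3)
        best = models[0].coords
        d = float(np.linalg.norm(best.position(1, "HA") - best.position(6, "HA")))
        assert d <= 3.2

    def test_bonded_geometry_alone_keeps_ideal_bond_lengths(self):
        models = anneal("AEKLLA", RestraintSet(), n_models=2, seed=1)
        top = Topology("AEKLLA")
        x = np.array([models[0].coords.position(i, a) for i, a in top.atoms])
        d = np.linalg.norm(x[top.bond_i] - x[top.bond_j], axis=1)
        np.testing.assert_allclose(d, top.bond_d0, rtol=0.02)

    def test_same_seed_reproduces_identical_energies(self, helix_restraints):
        a = anneal("AEKLLAKSIEQA", helix_restraints, n_models=2, seed=42)
        b = anneal("AEKLLAKSIEQA", helix_restraints, n_models=2, seed=42)
        assert [m.total_energy for m in a] == [m.total_energy for m in b]

    def test_models_sorted_by_energy(self, helix_restraints):
        models = anneal("AEKLLAKSIEQA", helix_restraints, n_models=4, seed=0)
        energies = [m.total_energy for m in models]
        assert energies == sorted(energies)

    def test_helix_recovered_from_complete_noise_free_restraints(
            self, helix_structure, helix_restraints):
        models = anneal(helix_structure.sequence(), helix_restraints,
                        n_models=20, seed=8)
        ref = backbone_coords(helix_structure, 12)
        best_rmsd = min(kabsch_rmsd(ref, backbone_coords(m.coords, 12))
                        for m in models[:5])
        assert best_rmsd < 1.5


class TestRefineAndSelect:
    def test_refinement_never_increases_restraint_energy(self, helix_restraints):
        models = anneal("AEKLLAKSIEQA", helix_restraints, n_models=2, seed=5)
        for m in models:
            refined = refine(m, helix_restraints)
            assert refined.total_energy <= m.total_energy + 1e-9

    def test_select_best_keeps_lowest_energy_stable(self, helix_restraints):
        models = anneal("AEKLLAKSIEQA", helix_restraints, n_models=5, seed=2)
        top2 = select_best(models, 2)
        assert [m.total_energy for m in top2] == sorted(
            m.total_energy for m in models)[:2]
        assert select_best(models, len(models)) == models

    def test_select_more_than_available_rejected(self, helix_restraints):
        models = anneal("AEKLLAKSIEQA", helix_restraints, n_models=2, seed=2)
        with pytest.raises(ValueError):
            select_best(models, 3)
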