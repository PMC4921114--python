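"""Template selection, hydrogenation, contact tabulation and peak filtering."""

from __future__ import annotations

import numpy as np
import pytest

from noefold.config import TemplateParams, Tolerances
from noefold.io_formats.types import CoordinateSet, CrossPeak, PeakList, ShiftEntry, ShiftTable
from noefold.synth import FixtureSpec, make_homolog, make_structure
from noefold.templates import (AlignmentResult, TemplateEntry, add_hydrogens,
                               align, filter_against_peaks, load_template_store,
                               merge_contacts, select_templates,
                               tabulate_contacts, tripeptide_factor,
                               write_template_store)


class TestAlign:
    def test_identity_sequence_scores_100(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert align(seq, seq).identity_pct == pytest.approx(100.0)

    def test_half_substituted_sequence_scores_50(self):
        target = "ACDEFGHIKLMNPQRSTVWY"
        # 10 substitutions at even positions, no indels
        template = "GCREYGWIRLVNSQKSAVFY"
        n_same = sum(a == b for a, b in zip(target, template))
        assert n_same == 10
        assert align(target, template).identity_pct == pytest.approx(50.0)

    def test_identity_alignment_pairs_are_diagonal(self):
        result = align("ACD", "ACD")
        assert result.aligned_pairs == [(1, 1), (2, 2), (3, 3)]

    def test_non_amino_acid_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="Z"):
            align("ACZ", "ACD")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align("", "ACD")


class TestSelectTemplates:
    @staticmethod
    def _alns(identities):
        return [AlignmentResult(template_id=f"t{k}", identity_pct=v, aligned_pairs=[])
                for k, v in enumerate(identities)]

    def test_below_20_percent_predicts_nothing(self):
        selected, single = select_templates(self._alns([19.0, 15.0]))
        assert selected == [] and not single

    def test_above_80_percent_uses_single_template(self):
        selected, single = select_templates(self._alns([85.0, 70.0, 60.0]))
        assert single and [a.identity_pct for a in selected] == [85.0]

    def test_top_three_selected_otherwise(self):
        selected, single = select_templates(self._alns([70.0, 60.0, 50.0, 40.0]))
        assert not single
        assert [a.identity_pct for a in selected] == [70.0, 60.0, 50.0]

    def test_never_more_than_three(self):
        selected, _ = select_templates(self._alns([75, 70, 65, 60, 55, 50]))
        assert len(selected) <= 3

    def test_empty_input_empty_selection(self):
        assert select_templates([]) == ([], False)

    def test_exact_boundaries_are_strict(self):
        # exactly 20 % is not "<20 %", exactly 80 % is not ">80 %"
        selected, single = select_templates(self._alns([20.0]))
        assert len(selected) == 1 and not single
        selected, single = select_templates(self._alns([80.0, 50.0]))
        assert len(selected) == 2 and not single


class TestAddHydrogens:
    @pytest.fixture()
    def heavy_dipeptide(self):
        spec = FixtureSpec(sequence="AKL", topology="helix", seed=0)
        full = make_structure(spec)
        keep = [k for k, name in enumerate(full.atom_names)
                if name in ("N", "CA", "C", "O")]
        return CoordinateSet(
            residue_indices=full.residue_indices[keep],
            residue_types=[full.residue_types[k] for k in keep],
            atom_names=[full.atom_names[k] for k in keep],
            coords=full.coords[keep])

    def test_amide_h_placed_at_bond_length(self, heavy_dipeptide):
        out = add_hydrogens(heavy_dipeptide)
        h = out.position(2, "H")
        n = out.position(2, "N")
        assert np.linalg.norm(h - n) == pytest.approx(1.01, abs=0.01)

    def test_amide_h_roughly_trans_to_carbonyl_o(self, heavy_dipeptide):
        out = add_hydrogens(heavy_dipeptide)
        # H(i) and O(i-1) sit on opposite sides of the peptide bond
        d_ho = np.linalg.norm(out.position(2, "H") - out.position(1, "O"))
        assert d_ho > 2.9

    def test_proline_gets_no_amide_h(self):
        spec = FixtureSpec(sequence="APA", topology="helix", seed=0)
        full = make_structure(spec)
        keep = [k for k, name in enumerate(full.atom_names)
                if name in ("N", "CA", "C", "O")]
        heavy = CoordinateSet(
            residue_indices=full.residue_indices[keep],
            residue_types=[full.residue_types[k] for k in keep],
            atom_names=[full.atom_names[k] for k in keep],
            coords=full.coords[keep])
        out = add_hydrogens(heavy)
        assert not out.has_atom(2, "H")

    def test_idempotent_on_hydrogen_complete_input(self, heavy_dipeptide):
        once = add_hydrogens(heavy_dipeptide)
        twice = add_hydrogens(once)
        assert len(twice) == len(once)

    def test_incomplete_backbone_skipped_with_warning(self, heavy_dipeptide):
        keep = [k for k in range(len(heavy_dipeptide))
                if not (heavy_dipeptide.residue_indices[k] == 2
                        and heavy_dipeptide.atom_names[k] == "CA")]
        broken = CoordinateSet(
            residue_indices=heavy_dipeptide.residue_indices[keep],
            residue_types=[heavy_dipeptide.residue_types[k] for k in keep],
            atom_names=[heavy_dipeptide.atom_names[k] for k in keep],
            coords=heavy_dipeptide.coords[keep])
        with pytest.warns(UserWarning, match="residue 2"):
            out = add_hydrogens(broken)
        assert not out.has_atom(2, "HA")

    def test_sidechain_protons_become_pseudoatoms(self):
        coords = CoordinateSet(
            residue_indices=np.array([1, 1, 1, 1, 1, 2, 2, 2, 2]),
            residue_types=["A"] * 5 + ["A"] * 4,
            atom_names=["N", "CA", "C", "O", "CB", "N", "CA", "C", "O"],
            coords=np.array([[0, 0, 0], [1.46, 0, 0], [2.0, 1.4, 0], [1.4, 2.4, 0],
                             [2.0, -0.7, 1.2], [3.3, 1.5, 0], [4.1, 2.7, 0],
                             [5.5, 2.4, 0.4], [6.0, 1.3, 0.6]], dtype=float))
        out = add_hydrogens(coords)
        assert out.has_atom(1, "QB")
        np.testing.assert_allclose(out.position(1, "QB"), coords.position(1, "CB"))


def _two_proton_template(separation: float) -> tuple[TemplateEntry, AlignmentResult]:
    """Two residues whose HA protons sit exactly ``separation`` apart."""
    coords = CoordinateSet(
        residue_indices=np.array([1, 1, 2, 2]),
        residue_types=["A", "A", "A", "A"],
        atom_names=["CA", "HA", "CA", "HA"],
        coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0],
                         [separation, 0.0, 0.0], [separation, 0.0, 1.0]]))
    template = TemplateEntry(id="two", sequence="AA", coords=coords)
    alignment = AlignmentResult(template_id="two", identity_pct=100.0,
                                aligned_pairs=[(1, 1), (2, 2)],
                                target_sequence="AA", template_sequence="AA")
    return template, alignment


class TestTabulateContacts:
    def test_pair_beyond_cutoff_excluded(self):
        template, alignment = _two_proton_template(5.6)
        assert tabulate_contacts(template, alignment) == []

    def test_pair_within_cutoff_tabulated_with_distance(self):
        template, alignment = _two_proton_template(3.0)
        contacts = tabulate_contacts(template, alignment)
        assert len(contacts) == 1
        assert contacts[0].template_distance == pytest.approx(3.0)

    def test_unaligned_residue_excluded(self):
        template, _ = _two_proton_template(3.0)
        partial = AlignmentResult(template_id="two", identity_pct=50.0,
                                  aligned_pairs=[(1, 1)],
                                  target_sequence="AA", template_sequence="AA")
        assert tabulate_contacts(template, partial) == []

    def test_all_distances_below_cutoff(self, helix_structure):
        template = TemplateEntry(id="h", sequence=helix_structure.sequence(),
                                 coords=helix_structure)
        n = len(template.sequence)
        alignment = AlignmentResult(
            template_id="h", identity_pct=100.0,
            aligned_pairs=[(i, i) for i in range(1, n + 1)],
            target_sequence=template.sequence, template_sequence=template.sequence)
        contacts = tabulate_contacts(template, alignment)
        assert contacts
        assert all(c.template_distance < 5.5 for c in contacts)
        assert all(c.res_a != c.res_b for c in contacts)

    def test_matches_brute_force_scan_on_five_residue_template(self):
        spec = FixtureSpec(sequence="AKLSE", topology="helix", seed=3)
        coords = make_structure(spec)
        template = TemplateEntry(id="t5", sequence="AKLSE", coords=coords)
        alignment = AlignmentResult(
            template_id="t5", identity_pct=100.0,
            aligned_pairs=[(i, i) for i in range(1, 6)],
            target_sequence="AKLSE", template_sequence="AKLSE")
        contacts = tabulate_contacts(template, alignment)
        got = {c.pair_key for c in contacts}
        # independent all-pairs scan
        expected = set()
        protons = [k for k, name in enumerate(coords.atom_names)
                   if name.startswith(("H", "Q"))]
        for a in protons:
            for b in protons:
                if b <= a:
                    continue
                ra, rb = int(coords.residue_indices[a]), int(coords.residue_indices[b])
                if ra == rb:
                    continue
                d = np.linalg.norm(coords.coords[a] - coords.coords[b])
                if d < 5.5:
                    expected.add(frozenset([(ra, coords.atom_names[a]),
                                            (rb, coords.atom_names[b])]))
        assert got == expected


class TestTripeptideFactor:
    @staticmethod
    def _aln(target, template):
        return align(target, template)

    def test_full_tripeptide_identity_scores_1(self):
        assert tripeptide_factor(self._aln("AGK", "AGK"), 2) == 1.0

    def test_center_only_match_scores_half(self):
        assert tripeptide_factor(self._aln("AGK", "SGT"), 2) == 0.5

    def test_center_mismatch_scores_zero(self):
        assert tripeptide_factor(self._aln("AGK", "SVT"), 2) == 0.0

    def test_terminal_residue_uses_dipeptide(self):
        # position 1 has no left flank; identity on (1, 2) suffices for 1.0
        assert tripeptide_factor(self._aln("AGK", "AGT"), 1) == 1.0
        assert tripeptide_factor(self._aln("AGK", "ATT"), 1) == 0.5

    def test_unaligned_residue_rejected(self):
        aln = AlignmentResult(template_id="x", identity_pct=50.0,
                              aligned_pairs=[(1, 1)], target_sequence="AGK",
                              template_sequence="AGK")
        with pytest.raises(ValueError, match="not aligned"):
            tripeptide_factor(aln, 2)


def _shift_table_for(pairs):
    entries = []
    seen = set()
    for resi, atom, shift in pairs:
        if (resi, atom) in seen:
            continue
        seen.add((resi, atom))
        entries.append(ShiftEntry(resi, "A", atom, shift))
    return ShiftTable(entries=entries)


class TestFilterAgainstPeaks:
    @staticmethod
    def _contact(res_a=1, res_b=3):
        template, _ = _two_proton_template(3.0)
        contacts = tabulate_contacts(
            template,
            AlignmentResult(template_id="two", identity_pct=100.0,
                            aligned_pairs=[(res_a, 1), (res_b, 2)],
                            target_sequence="A" * max(res_a, res_b),
                            template_sequence="AA"))
        return contacts

    def test_exact_match_retained_with_supporting_peak(self):
        contacts = self._contact()
        shifts = _shift_table_for([(1, "HA", 4.1), (1, "CA", 55.0), (3, "HA", 4.5),
                                   (3, "CA", 57.0)])
        peaks = [PeakList(peaks=[CrossPeak(shifts=(4.1, 55.0, 4.5), intensity=1e6,
                                           spectrum_kind="C13-NOESY", id=9)],
                          spectrum_kind="C13-NOESY")]
        result = filter_against_peaks(contacts, peaks, shifts)
        assert len(result) == 1
        assert result.retained[0].supporting_peaks == [9]

    def test_off_tolerance_contact_discarded(self):
        contacts = self._contact()
        shifts = _shift_table_for([(1, "HA", 4.1), (1, "CA", 55.0), (3, "HA", 4.5),
                                   (3, "CA", 57.0)])
        peaks = [PeakList(peaks=[CrossPeak(shifts=(4.3, 55.0, 4.5), intensity=1e6,
                                           spectrum_kind="C13-NOESY", id=0)],
                          spectrum_kind="C13-NOESY")]
        result = filter_against_peaks(contacts, peaks, shifts,
                                      Tolerances(h=0.03, heavy=0.4))
        assert len(result) == 0 and result.no_match == 1

    def test_contact_without_shifts_counted_separately(self):
        contacts = self._contact()
        shifts = _shift_table_for([(1, "HA", 4.1)])  # heavy + partner missing
        result = filter_against_peaks(contacts, [], shifts)
        assert len(result) == 0
        assert result.no_shift == 1 and result.no_match == 0

    def test_output_is_subset_and_monotone_in_tolerance(self, helix_structure,
                                                        helix_shifts, helix_peaks):
        template = TemplateEntry(id="h", sequence=helix_structure.sequence(),
                                 coords=helix_structure)
        n = len(template.sequence)
        alignment = AlignmentResult(
            template_id="h", identity_pct=100.0,
            aligned_pairs=[(i, i) for i in range(1, n + 1)],
            target_sequence=template.sequence, template_sequence=template.sequence)
        contacts = merge_contacts([tabulate_contacts(template, alignment)], [alignment])
        keys = {c.pair_key for c in contacts}
        tight = filter_against_peaks(contacts, helix_peaks, helix_shifts,
                                     Tolerances(h=0.005, heavy=0.05))
        loose = filter_against_peaks(contacts, helix_peaks, helix_shifts,
                                     Tolerances(h=0.05, heavy=0.8))
        assert {c.pair_key for c in tight} <= keys
        assert len(loose) >= len(tight)

    def test_retention_counts_match_brute_force(self):
        # 5 contacts at separations straddling the shift table: exactly the
        # two with both assignments present and a matching peak survive
        contacts = (self._contact(1, 3) + self._contact(2, 4)
                    + self._contact(5, 7) + self._contact(6, 8) + self._contact(1, 8))
        shifts = _shift_table_for([
            (1, "HA", 4.1), (1, "CA", 55.0), (3, "HA", 4.5), (3, "CA", 57.0),
            (2, "HA", 3.9), (2, "CA", 54.0), (4, "HA", 4.7), (4, "CA", 58.0),
            (5, "HA", 4.2), (5, "CA", 56.0), (7, "HA", 4.8), (7, "CA", 59.0),
        ])
        peaks = [PeakList(peaks=[
            CrossPeak(shifts=(4.1, 55.0, 4.5), intensity=1e6,
                      spectrum_kind="C13-NOESY", id=0),
            CrossPeak(shifts=(3.9, 54.0, 4.7), intensity=1e6,
                      spectrum_kind="C13-NOESY", id=1)],
            spectrum_kind="C13-NOESY")]
        result = filter_against_peaks(contacts, peaks, shifts)
        assert len(result) == 2


class TestTemplateStore:
    def test_store_round_trip(self, tmp_path, helix_structure):
        spec = FixtureSpec(sequence=helix_structure.sequence(), topology="helix", seed=2)
        entries = [make_homolog(make_structure(spec), ident, seed=30 + k)
                   for k, ident in enumerate([60.0, 40.0])]
        write_template_store(entries, tmp_path / "store")
        back = load_template_store(tmp_path / "store")
        assert [t.id for t in back] == [t.id for t in entries]
        assert [t.sequence for t in back] == [t.sequence for t in entries]
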