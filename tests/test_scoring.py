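"""Candidate enumeration, calibration, r^-6 sums and endurance scoring."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noefold.config import ScoringParams, Tolerances
from noefold.io_formats.types import CrossPeak, PeakList, ShiftEntry, ShiftTable
from noefold.restraints import CandidateAssignment, DistanceConstraint
from noefold.scoring import (build_constraints, calibrate_upper_limit,
                             categorize, dump_ledger, effective_distance,
                             enumerate_candidates, initial_endurance_score,
                             load_ledger, supportive_score, update_scores)
from noefold.templates import PredictedContact


@pytest.fixture()
def small_shifts():
    return ShiftTable(entries=[
        ShiftEntry(2, "A", "H", 8.20), ShiftEntry(2, "A", "N", 119.0),
        ShiftEntry(2, "A", "HA", 4.30), ShiftEntry(2, "A", "CA", 52.0),
        ShiftEntry(3, "K", "H", 7.90), ShiftEntry(3, "K", "N", 121.0),
        ShiftEntry(3, "K", "HA", 4.10), ShiftEntry(3, "K", "CA", 56.0),
        ShiftEntry(4, "L", "HA", 4.30), ShiftEntry(4, "L", "CA", 55.0),
    ])


class TestEnumerateCandidates:
    def test_unique_triple_yields_one_candidate(self, small_shifts):
        peak = CrossPeak(shifts=(8.20, 119.0, 4.10), intensity=1e6,
                         spectrum_kind="N15-NOESY")
        cands = enumerate_candidates(peak, small_shifts)
        assert len(cands) == 1
        c = cands[0]
        assert c.proton_a == (2, "H") and c.proton_b == (3, "HA")
        assert c.heavy_atom == (2, "N")

    def test_degenerate_proton_b_yields_two_candidates(self, small_shifts):
        # residues 2 and 4 share HA = 4.30
        peak = CrossPeak(shifts=(7.90, 121.0, 4.30), intensity=1e6,
                         spectrum_kind="N15-NOESY")
        cands = enumerate_candidates(peak, small_shifts)
        assert len(cands) == 2
        assert {c.proton_b for c in cands} == {(2, "HA"), (4, "HA")}

    def test_far_peak_yields_nothing(self, small_shifts):
        peak = CrossPeak(shifts=(6.0, 110.0, 2.0), intensity=1e6,
                         spectrum_kind="N15-NOESY")
        assert enumerate_candidates(peak, small_shifts) == []

    def test_heavy_atom_element_selects_spectrum(self, small_shifts):
        # same proton shifts, but a 13C spectrum must bind HA/CA, not H/N
        peak = CrossPeak(shifts=(4.30, 52.0, 7.90), intensity=1e6,
                         spectrum_kind="C13-NOESY")
        cands = enumerate_candidates(peak, small_shifts)
        assert cands and all(c.heavy_atom[1].startswith("C") for c in cands)

    def test_candidates_sorted_by_shift_error(self, small_shifts):
        peak = CrossPeak(shifts=(7.905, 121.0, 4.295), intensity=1e6,
                         spectrum_kind="N15-NOESY")
        cands = enumerate_candidates(peak, small_shifts)
        errors = [sum(abs(e) for e in c.shift_errors) for c in cands]
        assert errors == sorted(errors)


class TestCalibration:
    def test_median_intensity_maps_to_anchor(self):
        assert calibrate_upper_limit(5e5, 5e5) == pytest.approx(3.6)

    def test_strong_peak_clipped_to_floor(self):
        # 64x the median: 3.6 * 64^(-1/6) = 1.8 -> clipped to 2.4
        assert calibrate_upper_limit(64 * 2e5, 2e5) == pytest.approx(2.4)

    def test_vanishing_peak_clipped_to_ceiling(self):
        assert calibrate_upper_limit(1e-9, 1e6) == pytest.approx(5.5)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            calibrate_upper_limit(0.0, 1e6)

    def test_monotone_nonincreasing_over_six_decades(self):
        intensities = np.logspace(0, 6, 200)
        limits = [calibrate_upper_limit(i, 1e3) for i in intensities]
        assert all(a >= b - 1e-12 for a, b in zip(limits, limits[1:]))


class TestEffectiveDistance:
    def test_single_member_is_identity(self):
        assert effective_distance([4.0]) == pytest.approx(4.0)

    def test_two_equal_members_pool_by_sixth_root_of_two(self):
        assert effective_distance([4.0, 4.0]) == pytest.approx(4.0 * 2 ** (-1 / 6),
                                                               abs=1e-9)

    def test_far_member_is_negligible(self):
        assert effective_distance([3.0, 30.0]) == pytest.approx(3.0, abs=1e-3)

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            effective_distance([])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=1.0, max_value=50.0), min_size=1, max_size=8))
    def test_matches_brute_force_and_bounded_by_minimum(self, distances):
        brute = sum(d ** -6 for d in distances) ** (-1 / 6)
        d_eff = effective_distance(distances)
        assert d_eff == pytest.approx(brute, abs=1e-9)
        assert d_eff <= min(distances) + 1e-12

    def test_oracle_agreement_on_1000_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            d = rng.uniform(1.5, 12.0, size=rng.integers(1, 7))
            assert effective_distance(d) == pytest.approx(
                float(np.sum(d ** -6.0) ** (-1 / 6)), abs=1e-9)


class TestEnduranceScore:
    def test_unambiguous_exact_match_scores_maximum(self):
        assert initial_endurance_score(1, (0.0, 0.0, 0.0)) == pytest.approx(10.0)

    def test_two_candidates_halve_the_score(self):
        assert initial_endurance_score(2, (0.0, 0.0, 0.0)) == pytest.approx(5.0)

    def test_errors_at_tolerance_edge_drive_score_to_zero(self):
        tol = Tolerances()
        score = initial_endurance_score(1, (tol.h, tol.heavy, tol.h), tol)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing_in_ambiguity(self):
        scores = [initial_endurance_score(n, (0.01, 0.1, 0.005))
                  for n in range(1, 11)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_zero_candidates_rejected(self):
        with pytest.raises(ValueError):
            initial_endurance_score(0, (0, 0, 0))


def _constraint(members=None, upper=4.0, cid=0, **kw):
    members = members or [CandidateAssignment(
        proton_a=(2, "H"), proton_b=(5, "HA"), heavy_atom=(2, "N"),
        shift_errors=(0, 0, 0), res_type_a="A", res_type_b="K")]
    return DistanceConstraint(members=members, upper_limit=upper, id=cid, **kw)


class TestSupportiveScore:
    @staticmethod
    def _contact(factors):
        return PredictedContact(res_a=2, atom_a="H", res_b=5, atom_b="HA",
                                template_distance=3.0,
                                supporting_template_ids=list(factors),
                                tripeptide_factors=dict(factors))

    def test_three_full_matches_reach_cap_of_nine(self):
        contact = self._contact({"t1": 1.0, "t2": 1.0, "t3": 1.0})
        assert supportive_score(_constraint(), [contact]) == pytest.approx(9.0)

    def test_single_template_mode_caps_at_three(self):
        contact = self._contact({"t1": 1.0})
        assert supportive_score(_constraint(), [contact],
                                single_template_mode=True) == pytest.approx(3.0)

    def test_no_matching_contact_scores_zero(self):
        contact = PredictedContact(res_a=7, atom_a="H", res_b=9, atom_b="HA",
                                   template_distance=3.0)
        assert supportive_score(_constraint(), [contact]) == 0.0

    def test_partial_tripeptide_factors_sum(self):
        contact = self._contact({"t1": 1.0, "t2": 0.5})
        assert supportive_score(_constraint(), [contact]) == pytest.approx(4.5)


class TestCategorize:
    @pytest.mark.parametrize("endurance,supportive,expected", [
        (10.0, 0.0, "robust"),
        (8.0, 0.0, "robust"),       # boundary: >= 8
        (5.0, 0.0, "intermediate"),
        (4.0, 0.0, "intermediate"),  # boundary: >= 4
        (3.99, 0.0, "uncertain"),
        (1.0, 0.0, "uncertain"),
        (1.0, 9.0, "robust"),        # supportive score rescues
    ])
    def test_thresholds(self, endurance, supportive, expected):
        c = _constraint()
        c.endurance_score = endurance
        c.supportive_score = supportive
        assert categorize(c) == expected


class TestUpdateScores:
    def test_no_violations_leave_scores_unchanged(self):
        c = _constraint()
        c.endurance_score = 6.0
        kept, recycled = update_scores([c], [{0: 0.0}, {0: 0.0}])
        assert recycled == [] and kept[0].endurance_score == 6.0

    def test_fully_violated_low_score_constraint_recycled(self):
        c = _constraint()
        c.endurance_score = 1.0
        kept, recycled = update_scores([c], [{0: 1.0}] * 20)
        # penalty 2 * 1.0 * 1.0 = 2 -> score -1 < 0
        assert kept == [] and recycled == [c]
        assert c.in_recycle_bin
        assert c.endurance_score == pytest.approx(-1.0)

    def test_single_slight_violation_keeps_strong_constraint(self):
        c = _constraint()
        c.endurance_score = 10.0
        reports = [{0: 0.3}] + [{0: 0.0}] * 19
        kept, recycled = update_scores([c], reports)
        assert recycled == []
        assert 9.9 < kept[0].endurance_score < 10.0

    def test_violations_below_cutoff_do_not_count(self):
        c = _constraint()
        c.endurance_score = 5.0
        kept, _ = update_scores([c], [{0: 0.15}] * 20)
        assert kept[0].endurance_score == 5.0

    def test_never_increases_and_partitions_input(self):
        rng = np.random.default_rng(5)
        constraints = []
        for k in range(30):
            c = _constraint(cid=k)
            c.endurance_score = float(rng.uniform(-0.5, 10))
            constraints.append(c)
        before = {c.id: c.endurance_score for c in constraints}
        reports = [{c.id: float(rng.uniform(0, 2.0)) for c in constraints}
                   for _ in range(10)]
        kept, recycled = update_scores(constraints, reports)
        assert len(kept) + len(recycled) == 30
        assert {c.id for c in kept} | {c.id for c in recycled} == set(range(30))
        assert all(c.endurance_score <= before[c.id] for c in kept + recycled)

    def test_missing_report_entry_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            update_scores([_constraint(cid=3)], [{0: 0.0}])


class TestBuildConstraints:
    def test_noiseless_helix_constraints_have_valid_limits(self, helix_peaks,
                                                           helix_shifts):
        constraints, unassigned = build_constraints(helix_peaks, helix_shifts)
        assert constraints and unassigned == 0
        for c in constraints:
            assert 1.8 <= c.upper_limit <= 7.0
            assert c.category in ("robust", "intermediate", "uncertain")

    def test_pseudoatom_members_loosen_the_limit(self, helix_peaks, helix_shifts):
        constraints, _ = build_constraints(helix_peaks, helix_shifts)
        with_q = [c for c in constraints
                  if any("Q" in m.proton_a[1] or "Q" in m.proton_b[1]
                         for m in c.members)]
        assert with_q  # methyl/methylene corrections must be exercised

    def test_ledger_round_trip(self, tmp_path, helix_peaks, helix_shifts):
        constraints, _ = build_constraints(helix_peaks, helix_shifts)
        path = tmp_path / "ledger.tsv"
        dump_ledger(constraints, path)
        rows = load_ledger(path)
        assert len(rows) == len(constraints)
        by_id = {c.id: c for c in constraints}
        for row in rows:
            assert row.upper == pytest.approx(by_id[row.id].upper_limit, abs=1e-3)
            assert row.category == by_id[row.id].category
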