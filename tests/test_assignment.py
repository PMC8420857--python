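import numpy as np
import pytest

from cd2struct import (
    AssignmentTargets,
    ConsistencyError,
    FractionVector,
    InvalidParameterError,
    SSAssignment,
    constrained_assign,
    diff_assignments,
    discrepancy,
    make_planted_profile,
    region_summary,
    targets_from_vuvcd,
)
from cd2struct.assignment import run_counts
from cd2struct.segments import SegmentEstimate
from _oracles import brute_force_min_discrepancy


def random_targets(rng, n):
    nh = int(rng.integers(0, n + 1))
    ne = int(rng.integers(0, n - nh + 1))
    sh = int(rng.integers(0, nh + 1))
    se = int(rng.integers(0, ne + 1))
    return AssignmentTargets(nh, ne, sh, se, n)


def random_labels(rng, n, p=(0.3, 0.3, 0.4)):
    return "".join(rng.choice(list("HEC"), size=n, p=p))


class TestTargetsFromVuvcd:
    def test_tagged_construct_arithmetic(self):
        # helix 17.1 %, strand 27.2 % of 238 residues -> 41 and 65 residues
        f = FractionVector(0.067, 0.104, 0.159, 0.113, 0.28, 0.277)
        seg = SegmentEstimate(6, 13, 238)
        t = targets_from_vuvcd(f, seg, 238)
        assert (t.n_h_residues, t.n_e_residues) == (41, 65)
        assert (t.n_h_segments, t.n_e_segments) == (6, 13)

    def test_zero_fractions_give_zero_targets(self):
        f = FractionVector(0, 0, 0, 0, 0.5, 0.5)
        t = targets_from_vuvcd(f, SegmentEstimate(0, 0, 50), 50)
        assert (t.n_h_residues, t.n_e_residues, t.n_h_segments, t.n_e_segments) == (0, 0, 0, 0)

    def test_rounding_overflow_resolved_feasibly(self):
        # helix + strand = 1 with rounding pressure on a 10-residue chain
        f = FractionVector(0.25, 0.30, 0.25, 0.20, 0.0, 0.0)
        t = targets_from_vuvcd(f, SegmentEstimate(1, 1, 10), 10)
        assert t.n_h_residues + t.n_e_residues == 10

    def test_segment_targets_capped_at_residue_targets(self):
        f = FractionVector(0.0, 0.01, 0.0, 0.01, 0.49, 0.49)
        t = targets_from_vuvcd(f, SegmentEstimate(5, 5, 100), 100)
        assert t.n_h_segments <= t.n_h_residues
        assert t.n_e_segments <= t.n_e_residues


class TestDiscrepancy:
    def test_exact_match_scores_zero(self):
        a = SSAssignment("HHCEEC")
        t = AssignmentTargets(2, 2, 1, 1, 6)
        assert discrepancy(a, t) == 0

    def test_one_extra_helix_residue_scores_one(self):
        a = SSAssignment("HHHCEE")
        t = AssignmentTargets(2, 2, 1, 1, 6)
        assert discrepancy(a, t) == 1

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            labels = random_labels(rng, n)
            t = random_targets(rng, n)
            a = SSAssignment(labels)
            # independent recount of residues and maximal runs
            nh = labels.count("H")
            ne = labels.count("E")
            sh = sum(
                1 for i, c in enumerate(labels)
                if c == "H" and (i == 0 or labels[i - 1] != "H")
            )
            se = sum(
                1 for i, c in enumerate(labels)
                if c == "E" and (i == 0 or labels[i - 1] != "E")
            )
            expected = (
                abs(nh - t.n_h_residues) + abs(ne - t.n_e_residues)
                + 2.5 * (abs(sh - t.n_h_segments) + abs(se - t.n_e_segments))
            )
            assert discrepancy(a, t, lambda_seg=2.5) == expected


class TestConstrainedAssign:
    def test_all_zero_targets_give_all_other(self):
        p = make_planted_profile("HEC" * 5, seed=0)
        t = AssignmentTargets(0, 0, 0, 0, 15)
        a = constrained_assign(p, t)
        assert a.labels == "C" * 15

    def test_length_mismatch_rejected(self):
        p = make_planted_profile("HEC", seed=0)
        with pytest.raises(ConsistencyError):
            constrained_assign(p, AssignmentTargets(1, 1, 1, 1, 5))

    def test_matches_exhaustive_minimum_on_small_chains(self):
        rng = np.random.default_rng(17)
        for trial in range(60):
            n = int(rng.integers(3, 13))
            t = random_targets(rng, n)
            p = make_planted_profile(
                random_labels(rng, n), margin=1.0, noise_sigma=0.5, seed=trial
            )
            a = constrained_assign(p, t)
            assert a.discrepancy == brute_force_min_discrepancy(t)

    def test_planted_truth_recovered_exactly(self):
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            labels = random_labels(rng, 80)
            p = make_planted_profile(labels, margin=2.0, noise_sigma=0.1, seed=seed)
            nh, ne, sh, se = run_counts(labels)
            a = constrained_assign(p, AssignmentTargets(nh, ne, sh, se, 80))
            assert a.labels == labels
            assert a.discrepancy == 0

    def test_feasible_targets_always_met_exactly(self):
        rng = np.random.default_rng(4)
        done = 0
        while done < 100:
            n = int(rng.integers(10, 60))
            labels = random_labels(rng, n)  # counts of a real labeling: feasible
            nh, ne, sh, se = run_counts(labels)
            t = AssignmentTargets(nh, ne, sh, se, n)
            p = make_planted_profile(
                random_labels(rng, n), margin=0.5, noise_sigma=0.5, seed=done
            )
            a = constrained_assign(p, t)
            assert a.discrepancy == 0
            assert a.counts() == (nh, ne, sh, se)
            done += 1

    def test_reconciliation_never_regresses_phase_one(self):
        rng = np.random.default_rng(8)
        for trial in range(50):
            n = int(rng.integers(5, 40))
            t = random_targets(rng, n)
            p = make_planted_profile(
                random_labels(rng, n), margin=1.0, noise_sigma=1.0, seed=trial
            )
            a = constrained_assign(p, t)
            assert a.discrepancy <= a.phase1_discrepancy

    def test_deterministic_for_fixed_inputs(self):
        rng = np.random.default_rng(2)
        t = random_targets(rng, 40)
        p = make_planted_profile(random_labels(rng, 40), seed=3)
        a1 = constrained_assign(p, t)
        a2 = constrained_assign(p, t)
        assert a1.labels == a2.labels


class TestDiffAndRegions:
    def test_identical_assignments_give_empty_diff(self):
        a = SSAssignment("HHCEEC")
        assert diff_assignments(a, SSAssignment("HHCEEC")) == []

    def test_single_difference_reported(self):
        a = SSAssignment("HHCEEC")
        b = SSAssignment("HHCECC")
        assert diff_assignments(a, b) == [(5, "E", "C")]

    def test_planted_differences_found_with_tag_offset(self):
        rng = np.random.default_rng(6)
        labels = list(random_labels(rng, 238))
        other = labels.copy()
        for pos in (150, 219, 230):  # construct numbering, 1-based
            other[pos - 1] = "H" if other[pos - 1] != "H" else "C"
        diffs = diff_assignments(
            SSAssignment("".join(labels)), SSAssignment("".join(other)), offset=129
        )
        assert [d[0] for d in diffs] == [150 - 129, 219 - 129, 230 - 129]
        assert (219 - 129) == 90  # construct position 219 is protein residue 90

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            diff_assignments(SSAssignment("HC"), SSAssignment("HCC"))

    def test_region_summary_hand_case(self):
        a = SSAssignment("CCHHHHCEEC")
        s = region_summary(a, 3, 8)
        assert s["helix_segments"] == 1
        assert s["strand_segments"] == 1

    def test_whole_sequence_summary_matches_global_counts(self):
        a = SSAssignment("HHCEECHHHC")
        s = region_summary(a, 1, 10)
        nh, ne, sh, se = a.counts()
        assert s["helix_segments"] == sh and s["strand_segments"] == se
        assert s["helix_residues"] == nh and s["strand_residues"] == ne

    def test_region_without_structure_gives_zeros(self):
        a = SSAssignment("HHCCCEE")
        s = region_summary(a, 3, 5)
        assert s["helix_segments"] == 0 and s["strand_segments"] == 0

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            region_summary(SSAssignment("HEC"), 2, 5)
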