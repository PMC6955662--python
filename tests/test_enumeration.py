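"""Counting, exhaustive enumeration, and uniform sampling of admissible sets.

Closed-form counts are checked against independent brute-force oracles built
from raw itertools filtering, never from the generators under test.
"""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from sced import (
    AlternationDesignSpec,
    MultipleBaselineSpec,
    PhaseDesignSpec,
    count_mbd_assignments,
    count_phase_assignments,
    enumerate_alternation,
    enumerate_assignments,
    enumerate_ccd_assignments,
    enumerate_mbd_assignments,
    enumerate_phase_assignments,
    is_admissible,
    sample_assignment,
)
from sced.design import DesignError

# the exhaustively printed admissible set for 6 occasions, 3 A + 3 B,
# maximal run <= 2
ATD_14_SEQUENCES = [
    "AABABB", "AABBAB", "ABAABB", "ABABAB", "ABABBA", "ABBAAB", "ABBABA",
    "BAABAB", "BAABBA", "BABAAB", "BABABA", "BABBAA", "BBAABA", "BBABAA",
]


def brute_phase_sequences(n, pattern, m):
    """Oracle: filter all label sequences over the pattern's alphabet."""
    out = []
    alphabet = sorted(set(pattern))
    for seq in itertools.product(alphabet, repeat=n):
        runs = [(lab, len(list(grp))) for lab, grp in itertools.groupby(seq)]
        if tuple(lab for lab, _ in runs) == tuple(pattern) and all(l >= m for _, l in runs):
            out.append("".join(seq))
    return out


class TestPhaseCounts:
    @pytest.mark.parametrize("n,k,m,expected", [
        (24, 4, 3, 455),   # C(15, 3)
        (12, 4, 3, 1),     # the single composition 3+3+3+3
        (14, 4, 3, 10),    # C(5, 3), verified by brute force below
    ])
    def test_closed_form(self, n, k, m, expected):
        assert count_phase_assignments(n, k, m) == expected

    def test_count_matches_brute_force(self):
        for n, m in [(10, 2), (12, 3), (14, 3)]:
            pattern = ("A", "B", "A", "B")
            assert count_phase_assignments(n, 4, m) == len(brute_phase_sequences(n, pattern, m))

    def test_infeasible_raises(self):
        with pytest.raises(DesignError):
            count_phase_assignments(11, 4, 3)


class TestPhaseEnumeration:
    def test_abab24_contains_printed_assignments(self, abab24):
        seqs = ["".join(a.labels) for a in enumerate_phase_assignments(abab24)]
        assert len(seqs) == 455
        assert "AAABBBAAABBBBBBBBBBBBBBB" in seqs
        assert "AAAAAABBBBBBAAAAAABBBBBB" in seqs
        assert len(set(seqs)) == 455

    def test_single_admissible_assignment(self):
        spec = PhaseDesignSpec(("A", "B", "A", "B"), n=12, min_phase_length=3)
        seqs = ["".join(a.labels) for a in enumerate_phase_assignments(spec)]
        assert seqs == ["AAABBBAAABBB"]

    def test_ab_design_change_points(self):
        spec = PhaseDesignSpec(("A", "B"), n=10, min_phase_length=3)
        aset = enumerate_phase_assignments(spec)
        assert aset.size == 5
        assert [a.change_points for a in aset] == [(4,), (5,), (6,), (7,), (8,)]

    def test_matches_brute_force_and_lexicographic_changepoints(self):
        spec = PhaseDesignSpec(("A", "B", "A"), n=11, min_phase_length=2)
        got = [a for a in enumerate_phase_assignments(spec)]
        assert sorted("".join(a.labels) for a in got) == sorted(
            brute_phase_sequences(11, ("A", "B", "A"), 2))
        cps = [a.change_points for a in got]
        assert cps == sorted(cps)


class TestAlternationEnumeration:
    def test_atd_equals_printed_14_sequence_list(self, atd6):
        aset = enumerate_alternation(atd6)
        assert aset.size == 14
        assert ["".join(a.labels) for a in aset] == ATD_14_SEQUENCES

    def test_atd_minimal(self):
        spec = AlternationDesignSpec(scheme="alternating_treatments", n=2,
                                     condition_counts={"A": 1, "B": 1}, max_run=1)
        assert ["".join(a.labels) for a in enumerate_alternation(spec)] == ["AB", "BA"]

    def test_rbd_size_matches_brute_force_product(self):
        spec = AlternationDesignSpec(scheme="randomized_block", n_blocks=5,
                                     treatments_per_block=3)
        aset = enumerate_alternation(spec)
        assert aset.size == 6 ** 5 == 7776
        # brute-force oracle on a smaller instance, element-for-element
        small = AlternationDesignSpec(scheme="randomized_block", n_blocks=2,
                                      treatments_per_block=3)
        got = ["".join(a.labels) for a in enumerate_alternation(small)]
        oracle = sorted("".join(b1 + b2)
                        for b1 in itertools.permutations("ABC")
                        for b2 in itertools.permutations("ABC"))
        assert sorted(got) == oracle and len(got) == 36

    def test_crd_fixed_totals(self):
        spec = AlternationDesignSpec(scheme="completely_randomized", n=4,
                                     condition_counts={"A": 2, "B": 2})
        seqs = ["".join(a.labels) for a in enumerate_alternation(spec)]
        assert len(seqs) == math.comb(4, 2) == 6
        assert seqs == sorted(seqs)

    def test_crd_unrestricted_coin_flip_scheme(self):
        spec = AlternationDesignSpec(scheme="completely_randomized", n=3,
                                     condition_counts={"A": 2, "B": 1},
                                     unrestricted=True)
        seqs = ["".join(a.labels) for a in enumerate_alternation(spec)]
        assert len(seqs) == 2 ** 3 and "AAA" in seqs and "BBB" in seqs

    def test_infeasible_totals_give_empty_set(self):
        spec = AlternationDesignSpec(scheme="alternating_treatments", n=6,
                                     condition_counts={"A": 5, "B": 1}, max_run=2)
        aset = enumerate_alternation(spec)
        assert aset.size == 0 and list(aset) == []

    def test_atd_size_matches_brute_force_across_run_limits(self):
        for max_run in (1, 2, 3):
            spec = AlternationDesignSpec(scheme="alternating_treatments", n=8,
                                         condition_counts={"A": 4, "B": 4},
                                         max_run=max_run)
            oracle = [s for s in itertools.product("AB", repeat=8)
                      if Counter(s) == Counter("AAAABBBB")
                      and max(len(list(g)) for _, g in itertools.groupby(s)) <= max_run]
            assert enumerate_alternation(spec).size == len(oracle)


class TestMbdEnumeration:
    @pytest.mark.parametrize("W,u,expected", [(22, 5, 3_160_080), (2, 2, 2), (3, 2, 6)])
    def test_distinct_counts(self, W, u, expected):
        assert count_mbd_assignments(W, u, distinct=True) == expected

    def test_non_distinct_count(self):
        assert count_mbd_assignments(4, 3, distinct=False) == 64

    def test_count_matches_brute_force_with_stagger(self):
        for W, u, s in [(5, 2, 1), (6, 3, 1), (6, 2, 2), (8, 3, 2), (7, 3, 3)]:
            oracle = [v for v in itertools.product(range(W), repeat=u)
                      if all(abs(a - b) >= s for i, a in enumerate(v) for b in v[i + 1:])]
            assert count_mbd_assignments(W, u, distinct=True, min_stagger=s) == len(oracle)

    def test_window_contains_paper_shaped_start_vector(self, mbd_5x55):
        aset = enumerate_mbd_assignments(mbd_5x55)
        assert aset.size == 3_160_080
        # baseline lengths (16,18,21,26,27) <-> starts (17,19,22,27,28)
        spec_small = MultipleBaselineSpec(n_units=2, n=40, start_window=(15, 17))
        vectors = [a.start_points for a in enumerate_mbd_assignments(spec_small)]
        assert (15, 16) in vectors and len(vectors) == 6

    def test_window_width_equal_units_gives_permutations(self):
        spec = MultipleBaselineSpec(n_units=3, n=20, start_window=(5, 7))
        vectors = sorted(a.start_points for a in enumerate_mbd_assignments(spec))
        assert vectors == sorted(itertools.permutations((5, 6, 7)))

    def test_min_stagger_two(self):
        spec = MultipleBaselineSpec(n_units=2, n=20, start_window=(15, 17), min_stagger=2)
        assert sorted(a.start_points for a in enumerate_mbd_assignments(spec)) == \
            [(15, 17), (17, 15)]


class TestCcdEnumeration:
    def test_nine_binary_boundaries(self, ccd_weight):
        aset = enumerate_ccd_assignments(ccd_weight)
        assert aset.size == 512
        assert (13, 20, 27, 37, 45, 55, 65, 78, 86) in {a.change_points for a in aset}

    def test_eight_binary_boundaries(self, ccd_weight):
        from dataclasses import replace
        spec8 = replace(ccd_weight,
                        phase_labels=ccd_weight.phase_labels[:9], n=95,
                        candidate_changepoints=ccd_weight.candidate_changepoints[1:],
                        criterion_schedule=ccd_weight.criterion_schedule[:8])
        assert enumerate_ccd_assignments(spec8).size == 256

    def test_singleton_candidates_give_single_assignment(self, ccd_weight):
        from dataclasses import replace
        spec1 = replace(ccd_weight,
                        candidate_changepoints=tuple((lst[0],) for lst
                                                     in ccd_weight.candidate_changepoints))
        assert enumerate_ccd_assignments(spec1).size == 1


class TestAssignmentSetContract:
    def test_size_equals_yielded_count_across_families(self, abab24, atd6, ccd_weight):
        small_mbd = MultipleBaselineSpec(n_units=3, n=30, start_window=(10, 16))
        for spec in (abab24, atd6, ccd_weight, small_mbd):
            aset = enumerate_assignments(spec)
            items = [a.key() for a in aset]
            assert len(items) == aset.size
            assert len(set(items)) == aset.size, "duplicate assignments"


class TestUniformSampling:
    def test_atd_sampler_uniform_chi_square(self, atd6):
        rng = np.random.default_rng(2024)
        draws = Counter("".join(sample_assignment(atd6, rng).labels)
                        for _ in range(10_000))
        assert set(draws) == set(ATD_14_SEQUENCES)
        observed = [draws[s] for s in ATD_14_SEQUENCES]
        _, p = sps.chisquare(observed)
        assert p > 0.001

    def test_phase_sampler_uniform_chi_square(self):
        spec = PhaseDesignSpec(("A", "B"), n=10, min_phase_length=3)  # R = 5
        rng = np.random.default_rng(7)
        draws = Counter(sample_assignment(spec, rng).change_points for _ in range(10_000))
        assert len(draws) == 5
        _, p = sps.chisquare(list(draws.values()))
        assert p > 0.001

    def test_mbd_sampler_uniform_and_distinct(self):
        spec = MultipleBaselineSpec(n_units=2, n=30, start_window=(10, 13))  # R = 12
        rng = np.random.default_rng(11)
        draws = Counter(sample_assignment(spec, rng).start_points for _ in range(12_000))
        assert len(draws) == 12
        assert all(a != b for (a, b) in draws)
        _, p = sps.chisquare(list(draws.values()))
        assert p > 0.001

    def test_sampled_assignments_satisfy_constraints(self, abab24, mbd_5x55, ccd_weight, atd6):
        rng = np.random.default_rng(3)
        for spec in (abab24, mbd_5x55, ccd_weight, atd6):
            for _ in range(50):
                assert is_admissible(spec, sample_assignment(spec, rng))

    def test_sampler_deterministic_given_seed(self, mbd_5x55):
        a = sample_assignment(mbd_5x55, 99)
        b = sample_assignment(mbd_5x55, 99)
        assert a.start_points == b.start_points
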