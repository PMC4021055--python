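"""Reciprocal overlap, event grouping, and between-sample matching."""

import itertools

import numpy as np
import pytest

from cnvconcord import (
    CallSet,
    build_event_groups,
    match_pairwise,
    overlap_length,
    reciprocal_overlap,
)
from cnvconcord.errors import ValidationError
from cnvconcord.overlap_match import candidate_pairs

from conftest import make_call, make_callset


def brute_force_passing_pairs(calls_a, calls_b, threshold=0.5):
    """Exhaustive all-pairs oracle for the index-accelerated candidate search."""
    return {
        (i, j)
        for i, x in enumerate(calls_a)
        for j, y in enumerate(calls_b)
        if reciprocal_overlap(x, y, threshold).passes
    }


def oracle_max_matching(calls_a, calls_b, threshold=0.5):
    """Maximum-cardinality matching size via augmenting paths (Kuhn's
    algorithm), independent of the assignment-solver route under test; for
    tiny edge sets the answer is cross-checked by exhaustive enumeration."""
    edges = sorted(brute_force_passing_pairs(calls_a, calls_b, threshold))
    adj = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
    match_of_b = {}

    def try_augment(i, seen):
        for j in adj.get(i, ()):
            if j in seen:
                continue
            seen.add(j)
            if j not in match_of_b or try_augment(match_of_b[j], seen):
                match_of_b[j] = i
                return True
        return False

    size = sum(try_augment(i, set()) for i in adj)

    if len(edges) <= 12:  # exhaustive cross-check of the oracle itself
        best = 0
        for r in range(1, len(edges) + 1):
            for combo in itertools.combinations(edges, r):
                if (len({i for i, _ in combo}) == r
                        and len({j for _, j in combo}) == r):
                    best = max(best, r)
        assert best == size
    return size


class TestOverlapLength:
    def test_partial_disjoint_and_identity(self):
        assert overlap_length(make_call(100, 199), make_call(150, 249)) == 50
        assert overlap_length(make_call(100, 199), make_call(300, 400)) == 0
        assert overlap_length(make_call(100, 199), make_call(100, 199)) == 100

    def test_different_chromosomes_never_overlap(self):
        assert overlap_length(make_call(100, 199), make_call(100, 199, chrom="2")) == 0


class TestReciprocalOverlap:
    def test_boundary_half_overlap_passes(self):
        res = reciprocal_overlap(make_call(100, 199, 1), make_call(150, 249, 1))
        assert res.O_a == res.O_b == 0.5
        assert res.passes

    def test_asymmetric_nesting_fails(self):
        res = reciprocal_overlap(make_call(100, 199, 1), make_call(1, 1000, 1))
        assert res.O_a == 1.0 and res.O_b == pytest.approx(0.1)
        assert not res.passes

    def test_identity_passes(self):
        res = reciprocal_overlap(make_call(100, 199, 3), make_call(100, 199, 3))
        assert res.O_a == res.O_b == 1.0 and res.passes

    def test_status_mismatch_fails_despite_full_overlap(self):
        res = reciprocal_overlap(make_call(100, 199, 3), make_call(100, 199, 1))
        assert res.O_a == 1.0 and not res.passes

    def test_gain_states_three_and_four_match(self):
        assert reciprocal_overlap(make_call(100, 199, 3), make_call(100, 199, 4)).passes

    def test_symmetry(self, rng):
        for _ in range(200):
            x = make_call(
                int(rng.integers(1, 1000)),
                int(rng.integers(1000, 2000)),
                state=int(rng.choice([1, 3])),
            )
            y = make_call(
                int(rng.integers(1, 1000)),
                int(rng.integers(1000, 2000)),
                state=int(rng.choice([1, 3])),
            )
            fwd, rev = reciprocal_overlap(x, y), reciprocal_overlap(y, x)
            assert fwd.passes == rev.passes
            assert (fwd.O_a, fwd.O_b) == (rev.O_b, rev.O_a)


class TestEventGroups:
    def test_four_programs_agreeing_form_one_group(self):
        callsets = [
            make_callset([(1000, 5000, 1)], program=p)
            for p in ("PC", "AGC", "PGS", "GH")
        ]
        (group,) = build_event_groups(callsets)
        assert len(group.programs) == 4 and len(group) == 4

    def test_non_overlapping_calls_stay_singletons(self):
        callsets = [
            make_callset([(1000, 2000, 1)], program="PC"),
            make_callset([(9000, 10000, 1)], program="AGC"),
        ]
        groups = build_event_groups(callsets)
        assert len(groups) == 2 and all(len(g) == 1 for g in groups)

    def test_chain_forms_one_component_even_without_clique(self):
        a = make_callset([(1, 1000, 1)], program="PC")
        b = make_callset([(401, 1400, 1)], program="AGC")
        c = make_callset([(801, 1800, 1)], program="PGS")
        groups = build_event_groups([a, b, c])
        assert not reciprocal_overlap(a.calls[0], c.calls[0]).passes
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_groups_partition_the_input(self, rng):
        callsets = []
        for p in ("PC", "AGC"):
            calls = []
            for _ in range(40):
                s = int(rng.integers(1, 200_000))
                calls.append(
                    make_call(s, s + int(rng.integers(999, 20_000)),
                              state=int(rng.choice([1, 3])), program=p)
                )
            callsets.append(CallSet("S1", p, calls))
        groups = build_event_groups(callsets)
        assert sum(len(g) for g in groups) == sum(len(cs) for cs in callsets)


class TestCandidateGeneration:
    def test_index_matches_exhaustive_oracle(self, rng):
        """The interval-index search returns exactly the all-pairs result."""
        for _ in range(100):
            def rand_calls(sample):
                n = int(rng.integers(0, 50))
                out = []
                for _ in range(n):
                    chrom = str(rng.integers(1, 4))
                    s = int(rng.integers(1, 100_000))
                    out.append(
                        make_call(s, s + int(rng.integers(0, 5_000)),
                                  state=int(rng.choice([0, 1, 3, 4])),
                                  chrom=chrom, sample=sample)
                    )
                return out

            a, b = rand_calls("S1"), rand_calls("S2")
            fast = {(i, j) for i, j, _ in candidate_pairs(a, b)}
            assert fast == brute_force_passing_pairs(a, b)


class TestMatchPairwise:
    def test_single_candidate_is_matched(self):
        A = make_callset([(1000, 2000, 1)], sample="S1")
        B = make_callset([(1100, 2100, 1)], sample="S2")
        (m,) = match_pairwise(A, B)
        assert m.call_a == A.calls[0] and m.call_b == B.calls[0]

    def test_one_call_vs_two_candidates_picks_best_single_pair(self):
        A = make_callset([(1000, 2000, 1)], sample="S1")
        B = make_callset([(1000, 2000, 1), (1400, 2400, 1)], sample="S2")
        (m,) = match_pairwise(A, B)
        assert (m.call_b.start, m.call_b.end) == (1000, 2000)  # higher min RO

    def test_two_by_two_graph_yields_size_two_matching(self):
        # passes: (a1,b1), (a1,b2), (a2,b2) -> must pick (a1,b1),(a2,b2)
        A = make_callset([(1000, 2000, 1), (1800, 2800, 1)], sample="S1")
        B = make_callset([(1000, 2000, 1), (1500, 2500, 1)], sample="S2")
        matches = match_pairwise(A, B)
        assert len(matches) == 2
        matched = {(m.call_a.start, m.call_b.start) for m in matches}
        assert matched == {(1000, 1000), (1800, 1500)}

    def test_cross_program_comparison_refused(self):
        A = make_callset([(1, 2000, 1)], sample="S1", program="PC")
        B = make_callset([(1, 2000, 1)], sample="S2", program="GH")
        with pytest.raises(ValidationError):
            match_pairwise(A, B)

    def test_matching_is_maximum_cardinality(self, rng):
        """No augmenting pair exists: size equals the brute-force optimum."""
        for _ in range(40):
            def rand_cs(sample):
                n = int(rng.integers(0, 9))
                calls = []
                for _ in range(n):
                    s = int(rng.integers(1, 20_000))
                    calls.append(
                        make_call(s, s + int(rng.integers(500, 4_000)),
                                  state=int(rng.choice([1, 3])), sample=sample)
                    )
                return CallSet(sample, "PC", calls)

            A, B = rand_cs("S1"), rand_cs("S2")
            got = len(match_pairwise(A, B))
            assert got == oracle_max_matching(A.calls, B.calls)
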