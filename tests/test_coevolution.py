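"""Coevolution rule: pair statistics, Fisher oracle, planted recovery."""

import math

import numpy as np
import pytest

from famdet import (
    Alignment,
    assemble_sets,
    detect_correlated_pairs,
    event_catalog,
    pair_statistics,
)
from famdet.coevolution import (
    InvalidPairError,
    ResidueEvent,
    fisher_upper_tail,
)

from conftest import perfect_association_alignment, random_alignment
from oracles import exact_fisher_upper


class TestEventCatalog:
    def test_presence_floor(self):
        # A in 10% of rows -> absent; B in 30% -> present
        rows = ["A"] + ["B"] * 3 + ["C"] * 6
        aln = Alignment([(f"s{i}", r) for i, r in enumerate(rows)])
        events = event_catalog(aln, min_presence=0.20)
        assert [(e.residue, e.count, e.fraction) for e in events] == [
            ("B", 3, 0.3),
            ("C", 6, 0.6),
        ]

    def test_invariant_column_single_event(self):
        aln = Alignment([(f"s{i}", "W") for i in range(5)])
        events = event_catalog(aln)
        assert len(events) == 1 and events[0].fraction == 1.0

    def test_hand_counted_event(self, rng):
        rows = ["A" if i < 20 else "G" for i in range(40)]
        aln = Alignment([(f"s{i}", "MMMMM" + rows[i]) for i in range(40)])
        events = event_catalog(aln)
        by_col5 = [e for e in events if e.column == 5 and e.residue == "A"]
        assert by_col5 == [ResidueEvent(5, "A", 20, 0.5)]

    def test_gaps_never_events(self):
        aln = Alignment([("a", "-"), ("b", "-"), ("c", "A")])
        assert all(e.residue != "-" for e in event_catalog(aln, 0.1))


class TestPairStatistics:
    def test_perfect_association(self):
        aln = perfect_association_alignment(40)
        a, b = event_catalog(aln)
        pair = pair_statistics(aln, a, b)
        assert pair.f_b == 0.5
        assert pair.f_b_given_a == 1.0
        assert pair.relative_increase_ab == pytest.approx(1.0)
        assert pair.p_value == pytest.approx(1 / math.comb(40, 20), rel=1e-9)

    def test_universal_events_no_association(self):
        aln = Alignment([(f"s{i}", "AW") for i in range(10)])
        a, b = event_catalog(aln)
        pair = pair_statistics(aln, a, b)
        assert pair.relative_increase_ab == 0.0
        assert pair.p_value == pytest.approx(1.0)

    def test_independent_events_no_increase(self):
        # 2x2 balanced construction: b split evenly across a and not-a
        rows = ["AW"] * 10 + ["AY"] * 10 + ["CW"] * 10 + ["CY"] * 10
        aln = Alignment([(f"s{i}", r) for i, r in enumerate(rows)])
        events = {(e.column, e.residue): e for e in event_catalog(aln)}
        pair = pair_statistics(aln, events[(0, "A")], events[(1, "W")])
        assert pair.relative_increase_ab == pytest.approx(0.0, abs=1e-12)

    def test_same_column_rejected(self):
        aln = Alignment([("a", "AW"), ("b", "CW")])
        ev = event_catalog(aln)
        col0 = [e for e in ev if e.column == 0]
        with pytest.raises(InvalidPairError):
            pair_statistics(aln, col0[0], col0[1])


def test_fisher_matches_exact_rational_oracle():
    """Hypergeometric upper tail vs exact Fraction arithmetic, 1e-12 relative."""
    checked = 0
    for n in range(2, 26):
        for count_a in range(1, n + 1):
            for count_b in range(1, count_a + 1):
                lo = max(0, count_a + count_b - n)
                hi = min(count_a, count_b)
                for k11 in (lo, (lo + hi) // 2, hi):
                    expected = float(exact_fisher_upper(k11, count_a, count_b, n))
                    got = fisher_upper_tail(k11, count_a, count_b, n)
                    assert got == pytest.approx(expected, rel=1e-12)
                    checked += 1
    # spot grid at larger N up to 60
    for n in (40, 50, 60):
        for count_a in range(5, n, 7):
            for count_b in range(5, count_a + 1, 7):
                for k11 in range(max(0, count_a + count_b - n),
                                 min(count_a, count_b) + 1, 3):
                    expected = float(exact_fisher_upper(k11, count_a, count_b, n))
                    assert fisher_upper_tail(k11, count_a, count_b, n) == pytest.approx(
                        expected, rel=1e-12
                    )
    assert checked > 1000


class TestDetectCorrelatedPairs:
    def test_perfect_fixture_reported_once(self):
        pairs = detect_correlated_pairs(perfect_association_alignment(40))
        assert len(pairs) == 1
        p = pairs[0]
        assert {p.event_a.residue, p.event_b.residue} == {"A", "W"}
        assert p.p_value == pytest.approx(1 / math.comb(40, 20), rel=1e-9)
        assert p.direction == "both"

    def test_n30_fails_p_threshold(self):
        """p = 1/C(30,15) ~ 6.4e-9 > 1e-10: below the evidence bar."""
        pairs = detect_correlated_pairs(perfect_association_alignment(30))
        assert pairs == []

    def test_random_alignment_no_pairs(self, rng):
        aln = random_alignment(100, 50, rng, gap_rate=0.0)
        assert detect_correlated_pairs(aln) == []

    def test_unsatisfiable_increase(self):
        pairs = detect_correlated_pairs(
            perfect_association_alignment(40), min_increase=float("inf")
        )
        assert pairs == []

    def test_row_and_column_permutation_invariance(self, rng):
        aln, _ = _planted_small()
        base = {
            frozenset([(p.event_a.column, p.event_a.residue),
                       (p.event_b.column, p.event_b.residue)])
            for p in detect_correlated_pairs(aln)
        }
        rows = [aln.records[i] for i in rng.permutation(aln.n_sequences)]
        assert {
            frozenset([(p.event_a.column, p.event_a.residue),
                       (p.event_b.column, p.event_b.residue)])
            for p in detect_correlated_pairs(Alignment(rows))
        } == base
        colperm = list(rng.permutation(aln.n_columns))
        permuted = Alignment(
            [(rid, "".join(s[c] for c in colperm)) for rid, s in aln.records]
        )
        # permuted column i holds original column colperm[i]
        relabeled = {
            frozenset([(colperm[p.event_a.column], p.event_a.residue),
                       (colperm[p.event_b.column], p.event_b.residue)])
            for p in detect_correlated_pairs(permuted)
        }
        assert relabeled == base

    def test_threshold_tightening_monotone(self):
        aln, _ = _planted_small()
        loose = detect_correlated_pairs(aln, 0.20, 0.80, 1e-10)
        for kwargs in ({"min_presence": 0.3}, {"min_increase": 1.2},
                       {"max_p": 1e-30}):
            tight = detect_correlated_pairs(aln, **{
                "min_presence": 0.20, "min_increase": 0.80, "max_p": 1e-10,
                **kwargs})
            assert len(tight) <= len(loose)


def _planted_small():
    from famdet import FamilySpec, generate_family

    spec = FamilySpec(
        n_sequences=120, n_columns=20,
        subfamilies=[("sub", 0.5, [[(3, "W"), (7, "H")]]), ("bg", 0.5, [])],
        seed=9,
    )
    return generate_family(spec)


class TestAssembleSets:
    def _pair(self, a, b):
        from famdet.coevolution import CorrelatedPair

        return CorrelatedPair(a, b, 0.5, 0.5, 1.0, 1.0, 1.0, 1.0, 1e-15, "both")

    def test_transitive_component(self):
        a = ResidueEvent(0, "A", 10, 0.5)
        b = ResidueEvent(1, "W", 10, 0.5)
        c = ResidueEvent(2, "H", 10, 0.5)
        sets = assemble_sets([self._pair(a, b), self._pair(b, c)])
        assert len(sets) == 1 and set(sets[0].events) == {a, b, c}
        assert len(sets[0].supporting_pairs) == 2

    def test_no_pairs_no_sets(self):
        assert assemble_sets([]) == []

    def test_disjoint_pairs_two_sets(self):
        a, b, c, d = (ResidueEvent(i, "A", 10, 0.5) for i in range(4))
        sets = assemble_sets([self._pair(a, b), self._pair(c, d)])
        assert [len(s.events) for s in sets] == [2, 2]

    def test_clique_mode_splits_non_clique(self):
        a = ResidueEvent(0, "A", 10, 0.5)
        b = ResidueEvent(1, "W", 10, 0.5)
        c = ResidueEvent(2, "H", 10, 0.5)
        sets = assemble_sets([self._pair(a, b), self._pair(b, c)], mode="clique")
        assert sorted(len(s.events) for s in sets) == [2, 2]


def test_planted_family_recovery(planted_family):
    """Zero-noise planted subfamily set is recovered exactly, nothing else."""
    aln, truth = planted_family
    pairs = detect_correlated_pairs(aln)
    sets = assemble_sets(pairs)
    assert len(sets) == 1
    planted = {(c, r) for c, r in truth.planted_sets["reductase"][0]}
    assert {(e.column, e.residue) for e in sets[0].events} == planted
    involved = {(p.event_a.column, p.event_b.column) for p in pairs}
    planted_cols = {c for c, _ in planted}
    assert all(x in planted_cols and y in planted_cols for x, y in involved)
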