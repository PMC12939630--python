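from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epifuse import (
    BeliefContext,
    MassFunction,
    SIRConfig,
    VACUOUS,
    belief_context,
    belief_of,
    count_transitions,
    dempster_combine,
    generate_random,
    initial_belief,
    intra_node_fuse,
    normalize_counts,
    plausibility_of,
    simulate_batch,
    simulate_once,
)
from epifuse.evidence import (
    AssociationMatrix,
    CountMatrix,
    TotalConflictError,
    TotalConflictWarning,
)

from oracles import combine_powerset, initial_belief_fractions, mass_dict

CTX = BeliefContext(1.0, 0.0, 0.5)


def simplex_triples():
    return st.tuples(
        st.floats(0.001, 1.0), st.floats(0.001, 1.0), st.floats(0.001, 1.0)
    ).map(lambda t: MassFunction(*(x / sum(t) for x in t)))


# ---------------------------------------------------------------------------
# transition counting
# ---------------------------------------------------------------------------


class TestCountTransitions:
    def _path3_batch(self, path3, m=1):
        return simulate_batch(path3, "1", SIRConfig(beta=1.0, gamma=1.0, rng_seed=0), m)

    def test_path3_hand_trace(self, path3):
        mc = count_transitions(self._path3_batch(path3))
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = expected[1, 2] = 1
        assert np.array_equal(mc.values, expected)

    def test_additive_over_replicates(self, path3):
        mc = count_transitions(self._path3_batch(path3, m=5))
        assert mc.values[0, 1] == 5

    def test_single_row_matrix_counts_nothing(self, path3):
        from epifuse.sir import TimeStateMatrix

        ts = TimeStateMatrix(np.array([[1, 0, 0]]), path3.nodes, "1")
        assert count_transitions([ts]).values.sum() == 0

    def test_replicate_order_irrelevant(self, karate):
        batch = simulate_batch(karate, "1", SIRConfig(beta=0.5, rng_seed=3), 10)
        a = count_transitions(batch).values
        b = count_transitions(batch[::-1]).values
        assert np.array_equal(a, b)

    def test_inconsistent_columns_rejected(self, path3, star4):
        a = simulate_once(path3, "1", SIRConfig(beta=1.0, rng_seed=0))
        b = simulate_once(star4, "1", SIRConfig(beta=1.0, rng_seed=0))
        with pytest.raises(ValueError, match="node order|empty"):
            count_transitions([a, b])

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([])


class TestNormalization:
    def test_scales_by_global_max(self):
        mc = CountMatrix(np.array([[0, 5, 0], [0, 0, 3], [0, 0, 0]]), ("1", "2", "3"), 1)
        mr = normalize_counts(mc)
        assert mr.values[0, 1] == 1.0
        assert mr.values[1, 2] == pytest.approx(0.6)

    def test_max_entry_is_one(self, karate):
        batch = simulate_batch(karate, "2", SIRConfig(beta=0.5, rng_seed=1), 20)
        mr = normalize_counts(count_transitions(batch))
        assert mr.values.max() == 1.0

    def test_all_zero_counts_rejected(self):
        mc = CountMatrix(np.zeros((3, 3), dtype=int), ("1", "2", "3"), 1)
        with pytest.raises(ValueError, match="no propagation events"):
            normalize_counts(mc)


class TestBeliefContext:
    def test_midpoint_definition(self):
        values = np.array([[0.0, 0.6, 1.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        ctx = belief_context(values)
        assert ctx == BeliefContext(1.0, 0.0, 0.5, degenerate=False)

    def test_constant_offdiagonal_is_degenerate(self):
        values = np.full((3, 3), 0.4)
        np.fill_diagonal(values, 0.4)
        assert belief_context(values).degenerate

    def test_diagonal_excluded_from_extrema(self):
        # diagonal zeros must not drag Rmin down
        values = np.full((3, 3), 0.5)
        np.fill_diagonal(values, 0.0)
        ctx = belief_context(values)
        assert ctx.rmin == 0.5 and ctx.degenerate


# ---------------------------------------------------------------------------
# initial belief mapping
# ---------------------------------------------------------------------------


class TestInitialBelief:
    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_matches_rational_oracle(self, x):
        expected = initial_belief_fractions(Fraction(x), 1, 0, Fraction(1, 2))
        got = initial_belief(x, CTX)
        for g, e in zip(got, expected):
            assert g == pytest.approx(float(e), abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            initial_belief(1.5, CTX)

    def test_degenerate_context_vacuous(self):
        assert initial_belief(0.4, BeliefContext(0.4, 0.4, 0.4, degenerate=True)) == VACUOUS

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_produces_valid_mass(self, x):
        m = initial_belief(x, CTX)
        m.validate()

    def test_support_strictly_increasing_in_strength(self):
        # provable from the deviation formulas; checked on a fine grid
        xs = np.linspace(0.0, 1.0, 501)
        m_t = [initial_belief(x, CTX).m_t for x in xs]
        assert all(b > a for a, b in zip(m_t, m_t[1:]))


# ---------------------------------------------------------------------------
# Dempster algebra
# ---------------------------------------------------------------------------


class TestDempsterCombine:
    def test_vacuous_identity(self):
        m = MassFunction(0.3, 0.5, 0.2)
        assert dempster_combine(m, VACUOUS) == pytest.approx(m)

    def test_worked_example_two_thirds(self):
        got = dempster_combine(MassFunction(2 / 3, 0, 1 / 3), MassFunction(0, 2 / 3, 1 / 3))
        assert got == pytest.approx((0.4, 0.4, 0.2))

    def test_worked_example_with_certain_pair(self):
        got = dempster_combine(MassFunction(2 / 3, 0, 1 / 3), MassFunction(0.5, 0.5, 0.0))
        assert got == pytest.approx((0.75, 0.25, 0.0))

    def test_total_conflict_warns_and_returns_vacuous(self):
        with pytest.warns(TotalConflictWarning):
            got = dempster_combine(MassFunction(1, 0, 0), MassFunction(0, 1, 0))
        assert got == VACUOUS

    def test_total_conflict_strict_raises(self):
        with pytest.raises(TotalConflictError):
            dempster_combine(MassFunction(1, 0, 0), MassFunction(0, 1, 0), "strict")

    def test_agrees_with_powerset_oracle(self):
        rng = np.random.default_rng(2024)
        triples = rng.dirichlet(np.ones(3), size=(1000, 2))
        for (a, b) in triples:
            m1, m2 = MassFunction(*a), MassFunction(*b)
            expected, _ = combine_powerset(mass_dict(*m1), mass_dict(*m2))
            got = dempster_combine(m1, m2)
            assert abs(got.m_t - float(expected.get(frozenset({"T"}), 0))) < 1e-12
            assert abs(got.m_f - float(expected.get(frozenset({"F"}), 0))) < 1e-12
            assert abs(got.m_tf - float(expected.get(frozenset({"T", "F"}), 0))) < 1e-12

    @settings(max_examples=300, derandomize=True)
    @given(simplex_triples(), simplex_triples())
    def test_commutative_exactly(self, m1, m2):
        assert dempster_combine(m1, m2) == dempster_combine(m2, m1)

    @settings(max_examples=200, derandomize=True)
    @given(simplex_triples(), simplex_triples(), simplex_triples())
    def test_associative_within_tolerance(self, m1, m2, m3):
        left = dempster_combine(dempster_combine(m1, m2), m3)
        right = dempster_combine(m1, dempster_combine(m2, m3))
        assert left == pytest.approx(right, abs=1e-9)

    @settings(max_examples=300, derandomize=True)
    @given(simplex_triples(), simplex_triples())
    def test_result_is_valid_mass(self, m1, m2):
        dempster_combine(m1, m2).validate()


class TestBeliefPlausibility:
    def test_worked_example(self):
        m = MassFunction(0.6, 0.2, 0.2)
        assert belief_of(m, {"T"}) == pytest.approx(0.6)
        assert plausibility_of(m, {"T"}) == pytest.approx(0.8)

    def test_whole_frame_belief_is_one(self):
        m = MassFunction(0.3, 0.5, 0.2)
        assert belief_of(m, {"T", "F"}) == pytest.approx(1.0)

    @settings(max_examples=200, derandomize=True)
    @given(simplex_triples())
    def test_uncertainty_gap_equals_mass_on_frame(self, m):
        assert plausibility_of(m, {"T"}) - belief_of(m, {"T"}) == pytest.approx(m.m_tf)

    @settings(max_examples=200, derandomize=True)
    @given(simplex_triples())
    def test_belief_below_plausibility(self, m):
        for prop in ({"T"}, {"F"}, {"T", "F"}):
            assert belief_of(m, prop) <= plausibility_of(m, prop) + 1e-12

    def test_invalid_proposition_rejected(self):
        with pytest.raises(ValueError):
            belief_of(VACUOUS, {"X"})


# ---------------------------------------------------------------------------
# intra-node fusion
# ---------------------------------------------------------------------------


def _assoc(values) -> AssociationMatrix:
    values = np.asarray(values, dtype=float)
    return AssociationMatrix(values, tuple(str(i + 1) for i in range(len(values))),
                             belief_context(values))


class TestIntraNodeFuse:
    def test_one_way_evidence_balances(self):
        # x_ij=1 against x_ji=0 lands exactly between support and opposition
        mr = _assoc([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        ev = intra_node_fuse(mr)
        assert ev.mass_at(0, 1) == pytest.approx((0.4, 0.4, 0.2))

    def test_double_absence_opposes(self):
        mr = _assoc([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        ev = intra_node_fuse(mr)
        assert ev.mass_at(0, 2) == pytest.approx((0.0, 8 / 9, 1 / 9))

    def test_output_exactly_symmetric(self, karate):
        batch = simulate_batch(karate, "3", SIRConfig(beta=0.5, rng_seed=11), 30)
        ev = intra_node_fuse(normalize_counts(count_transitions(batch)))
        for m in (ev.bpa_t, ev.bpa_f, ev.bpa_tf):
            assert np.array_equal(m, m.T)

    def test_diagonal_vacuous(self):
        mr = _assoc([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        ev = intra_node_fuse(mr)
        assert np.array_equal(np.diag(ev.bpa_tf), np.ones(3))
        assert not np.diag(ev.bpa_t).any()

    def test_offdiagonal_triples_normalized(self, karate):
        batch = simulate_batch(karate, "1", SIRConfig(beta=0.5, rng_seed=4), 25)
        ev = intra_node_fuse(normalize_counts(count_transitions(batch)))
        total = ev.bpa_t + ev.bpa_f + ev.bpa_tf
        assert np.allclose(total, 1.0, atol=1e-9)
        assert (ev.bpa_t >= 0).all() and (ev.bpa_f >= 0).all() and (ev.bpa_tf >= 0).all()

    def test_degenerate_context_gives_vacuous_evidence(self):
        values = np.full((3, 3), 0.5)
        np.fill_diagonal(values, 0.0)
        mr = AssociationMatrix(values, ("1", "2", "3"), belief_context(values))
        ev = intra_node_fuse(mr)
        assert np.array_equal(ev.bpa_tf, np.ones((3, 3)))
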