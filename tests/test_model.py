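"""Pattern enumeration, expected-count equations, and design accounting."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from projcensus import (
    InjectionExperiment,
    ObservationSet,
    TypeCountVector,
    build_system,
    design_tally,
    enumerate_patterns,
    expected_label_counts,
)
from projcensus.model import combo_key, parse_combo_key

from conftest import monte_carlo_label_counts


class TestPatternEnumeration:
    def test_canonical_order_for_four_targets(self):
        index = enumerate_patterns(4)
        assert len(index) == 15
        assert index.labels() == [
            "1", "2", "1+2", "3", "1+3", "2+3", "1+2+3",
            "4", "1+4", "2+4", "1+2+4", "3+4", "1+3+4", "2+3+4", "1+2+3+4",
        ]

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 3), (4, 15), (7, 127)])
    def test_pattern_count(self, n, expected):
        assert len(enumerate_patterns(n)) == expected

    def test_single_target(self):
        assert enumerate_patterns(1).patterns == (frozenset({1}),)

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_invalid_n_targets(self, bad):
        with pytest.raises(ValueError):
            enumerate_patterns(bad)

    @given(st.integers(min_value=1, max_value=8))
    @settings(derandomize=True, max_examples=8)
    def test_every_nonempty_subset_appears_once(self, n):
        index = enumerate_patterns(n)
        assert len(set(index.patterns)) == len(index) == 2**n - 1
        for s in index.patterns:
            assert s and s <= set(range(1, n + 1))
            # position formula: subset S sits at sum(2^(i-1)) - 1
            assert index.patterns[index.position(s)] == s

    def test_combo_key_roundtrip(self):
        assert parse_combo_key(combo_key({3, 1, 4})) == frozenset({1, 3, 4})
        with pytest.raises(ValueError):
            parse_combo_key("1+1")


class TestExpectedLabelCounts:
    def test_matches_green_equation_symbolically(self):
        """The C={1} expectation of a triple injection expands term-for-term to
        G = k1(T1+T14) + k1(1-k2)(T12+T124) + k1(1-k3)(T13+T134)
          + k1(1-k2)(1-k3)(T123+T1234)."""
        index = enumerate_patterns(4)
        T = {p: sympy.Symbol("T" + "".join(map(str, sorted(p)))) for p in index.patterns}
        k1, k2, k3 = sympy.symbols("k1 k2 k3", positive=True)
        counts = TypeCountVector(
            index=index, counts=np.array([T[p] for p in index.patterns], dtype=object)
        )
        exp = InjectionExperiment(injected=frozenset({1, 2, 3}), fractions={1: k1, 2: k2, 3: k3})
        obs = expected_label_counts(counts, exp)

        def sym(label):
            return T[frozenset(label)]

        g_reference = (
            k1 * (sym({1}) + sym({1, 4}))
            + k1 * (1 - k2) * (sym({1, 2}) + sym({1, 2, 4}))
            + k1 * (1 - k3) * (sym({1, 3}) + sym({1, 3, 4}))
            + k1 * (1 - k2) * (1 - k3) * (sym({1, 2, 3}) + sym({1, 2, 3, 4}))
        )
        assert sympy.expand(obs[{1}] - g_reference) == 0

    def test_perfect_yield_routes_each_pattern_to_its_footprint(self):
        index = enumerate_patterns(4)
        counts = np.zeros(15, dtype=int)
        counts[index.position({1})] = 100
        tcv = TypeCountVector(index=index, counts=counts)
        exp = InjectionExperiment(injected=frozenset({1, 2, 3}), fractions={1: 1.0, 2: 1.0, 3: 1.0})
        obs = expected_label_counts(tcv, exp)
        assert obs[{1}] == 100
        assert sum(obs.values()) == 100

    def test_half_fractions_split_double_projector_evenly(self):
        index = enumerate_patterns(4)
        counts = np.zeros(15, dtype=int)
        counts[index.position({1, 2})] = 8
        tcv = TypeCountVector(index=index, counts=counts)
        exp = InjectionExperiment(
            injected=frozenset({1, 2, 3}), fractions={1: 0.5, 2: 0.5, 3: 0.5}
        )
        obs = expected_label_counts(tcv, exp)
        expected = {"1": 2, "2": 2, "1+2": 2}
        for key, value in obs.as_dict().items():
            assert value == pytest.approx(expected.get(key, 0.0))

    def test_agrees_with_bernoulli_monte_carlo_oracle(self, small_counts_n4, triple_experiment):
        """Per-combination expectations match per-neuron Bernoulli simulation
        within 3 standard errors."""
        rng = np.random.default_rng(2024)
        n_reps = 400
        mc = monte_carlo_label_counts(small_counts_n4, triple_experiment, rng, n_reps=n_reps)
        exact = np.array(expected_label_counts(small_counts_n4, triple_experiment).values())
        # binomial-sum variance bound: each combo count is a sum of Bernoullis
        se = np.sqrt(np.maximum(exact, 1.0) / n_reps)
        assert np.all(np.abs(mc - exact) <= 3 * se)

    def test_injected_target_out_of_range(self, small_counts_n4):
        exp = InjectionExperiment(injected=frozenset({1, 5}), fractions={1: 0.5, 5: 0.5})
        with pytest.raises(ValueError):
            expected_label_counts(small_counts_n4, exp)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=1000), min_size=7, max_size=7),
        fracs=st.lists(
            st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=2
        ),
    )
    @settings(derandomize=True, max_examples=40)
    def test_unlabeled_mass_closes_the_budget(self, counts, fracs):
        """Labeled combination expectations plus the unlabeled remainder add
        up exactly to the projecting-neuron total, for any fractions."""
        index = enumerate_patterns(3)
        tcv = TypeCountVector(index=index, counts=np.array(counts))
        S = frozenset({1, 3})
        exp = InjectionExperiment(injected=S, fractions={1: fracs[0], 3: fracs[1]})
        obs = expected_label_counts(tcv, exp)
        unlabeled = sum(
            t * np.prod([1 - exp.fractions[j] for j in (p & S)])
            for p, t in zip(index.patterns, tcv.counts)
            if p & S
        )
        visible = sum(t for p, t in zip(index.patterns, tcv.counts) if p & S)
        assert sum(obs.values()) + unlabeled == pytest.approx(visible)


class TestSystemAccounting:
    def test_four_choose_three_design(self):
        tally = design_tally(4, 3, 0)
        assert tally["injections"] == 4
        assert tally["constraints"] == 28
        assert tally["unknowns"] == 27
        assert tally["ratio"] == pytest.approx(28 / 27)

    def test_seven_choose_four_design(self):
        tally = design_tally(7, 4, 0)
        assert tally["injections"] == 35
        assert tally["constraints"] == 525
        assert tally["unknowns"] == 267

    def test_empty_design(self):
        system = build_system(4, [])
        assert system.n_constraints == 0
        assert system.n_unknown_ints == 15
        assert system.n_unknown_reals == 0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            design_tally(4, 5, 0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
    def test_tally_matches_explicit_enumeration(self, n):
        """Closed-form tallies agree with counting equations of an explicitly
        built experiment list, for every k <= n and up to 3 repetitions."""
        from itertools import combinations

        for k in range(1, n + 1):
            for reps in range(0, 4):
                experiments = [
                    InjectionExperiment(injected=frozenset(s), label=f"{s}_{r}")
                    for r in range(reps + 1)
                    for s in combinations(range(1, n + 1), k)
                ]
                system = build_system(n, experiments)
                tally = design_tally(n, k, reps)
                assert tally["injections"] == len(experiments)
                assert tally["constraints"] == system.n_constraints
                assert tally["unknown_reals"] == system.n_unknown_reals
                assert tally["unknown_ints"] == system.n_unknown_ints

    def test_observation_set_must_cover_all_combinations(self, triple_experiment):
        with pytest.raises(ValueError):
            ObservationSet(experiment=triple_experiment, counts={frozenset({1}): 5.0})

    def test_mismatched_observation_lists(self, triple_experiment):
        with pytest.raises(ValueError):
            build_system(4, [triple_experiment], [])
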