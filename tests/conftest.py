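import numpy as np
import pytest

from projcensus import (
    InjectionExperiment,
    TypeCountVector,
    enumerate_patterns,
)


def monte_carlo_label_counts(counts, experiment, rng, n_reps=1):
    """Independent Bernoulli-labeling oracle for expected combination counts.

    Simulates every neuron of every pattern individually: each injected
    target the neuron projects to labels it with probability k_i, and the
    soma is tallied under its exact label set.  Returns the mean tally per
    combination over ``n_reps`` replicates, in canonical combination order.

    Deliberately re-derives the combinatorics from scratch (per-neuron loop
    over explicit label sets) rather than reusing any package code path.
    """
    S = sorted(experiment.injected)
    k = [experiment.fractions[t] for t in S]
    combos = experiment.combinations()
    totals = np.zeros(len(combos))
    for _ in range(n_reps):
        tally = {c: 0 for c in combos}
        for pattern, m in zip(counts.index.patterns, counts.counts):
            proj = [j for j, t in enumerate(S) if t in pattern]
            if not proj:
                continue
            draws = rng.random((int(m), len(proj)))
            for row in draws:
                labeled = frozenset(S[proj[j]] for j in range(len(proj)) if row[j] < k[proj[j]])
                if labeled:
                    tally[labeled] += 1
        totals += np.array([tally[c] for c in combos], dtype=float)
    return totals / n_reps


@pytest.fixture
def small_counts_n4():
    index = enumerate_patterns(4)
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 200, size=15)
    return TypeCountVector(index=index, counts=counts)


@pytest.fixture
def triple_experiment():
    return InjectionExperiment(
        injected=frozenset({1, 2, 3}),
        fractions={1: 0.55, 2: 0.7, 3: 0.4},
        label="triple",
    )
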