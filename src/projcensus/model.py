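"""Labeling-count model for combinatorial retrograde tracing.

A source region projecting to ``n`` target regions hosts up to ``2^n - 1``
projection neuron types, one per nonempty subset of targets.  A multi-color
retrograde injection experiment covers a subset ``S`` of targets; each target
``i`` in ``S`` labels a projecting neuron independently with probability
``k_i`` (the labeling fraction, < 1 because injections cover only part of a
region).  The observable unit is the count of somata carrying an *exact*
color combination ``C`` (labeled by every tracer in ``C`` and by no other).

This module enumerates projection patterns, evaluates the expected exact-
combination counts for arbitrary type-count vectors and experiments, and
tallies the constraint/unknown accounting of full experimental designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PatternIndex",
    "TypeCountVector",
    "InjectionExperiment",
    "ObservationSet",
    "ModelSystem",
    "enumerate_patterns",
    "expected_label_counts",
    "build_system",
    "design_tally",
    "combo_key",
    "parse_combo_key",
]


def combo_key(subset: frozenset[int] | Sequence[int]) -> str:
    """Render a target subset as the canonical ``"1+3+4"`` string key."""
    return "+".join(str(i) for i in sorted(subset))


def parse_combo_key(key: str) -> frozenset[int]:
    """Inverse of :func:`combo_key`."""
    try:
        parts = [int(p) for p in key.split("+")]
    except ValueError as exc:
        raise ValueError(f"malformed combination key {key!r}") from exc
    if not parts or any(p < 1 for p in parts) or len(set(parts)) != len(parts):
        raise ValueError(f"malformed combination key {key!r}")
    return frozenset(parts)


def _subsets_in_binary_order(universe: Sequence[int]) -> list[frozenset[int]]:
    """All nonempty subsets of ``universe`` in binary-counting order.

    Element ``universe[j]`` corresponds to bit ``j``; subset with bitmask
    ``m`` sits at position ``m - 1``.  For targets ``1..n`` this yields the
    order T1, T2, T12, T3, T13, T23, T123, T4, ...
    """
    elems = list(universe)
    out = []
    for mask in range(1, 1 << len(elems)):
        out.append(frozenset(elems[j] for j in range(len(elems)) if mask >> j & 1))
    return out


@dataclass(frozen=True)
class PatternIndex:
    """Canonical ordered enumeration of the ``2^n - 1`` projection patterns."""

    n_targets: int
    patterns: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        expected = tuple(_subsets_in_binary_order(range(1, self.n_targets + 1)))
        if tuple(self.patterns) != expected:
            raise ValueError("patterns are not in canonical binary-counting order")

    def __len__(self) -> int:
        return len(self.patterns)

    def position(self, pattern: frozenset[int] | Sequence[int]) -> int:
        """0-based position of a pattern: ``sum(2**(i-1) for i in S) - 1``."""
        s = frozenset(pattern)
        if not s or max(s) > self.n_targets or min(s) < 1:
            raise ValueError(f"pattern {sorted(s)} not valid for n={self.n_targets}")
        return sum(1 << (i - 1) for i in s) - 1

    def labels(self) -> list[str]:
        """Human-readable pattern labels ("1", "2", "1+2", ...)."""
        return [combo_key(p) for p in self.patterns]


def enumerate_patterns(n_targets: int) -> PatternIndex:
    """Enumerate all nonempty target subsets in canonical order.

    Parameters
    ----------
    n_targets
        Number of target regions the source projects to (>= 1).

    Returns
    -------
    PatternIndex
        The ``2^n_targets - 1`` patterns in binary-counting order.
    """
    if not isinstance(n_targets, (int, np.integer)) or n_targets < 1:
        raise ValueError("n_targets must be a positive integer")
    return PatternIndex(
        n_targets=int(n_targets),
        patterns=tuple(_subsets_in_binary_order(range(1, n_targets + 1))),
    )


@dataclass(frozen=True)
class TypeCountVector:
    """Neuron count per projection pattern, aligned with a PatternIndex."""

    index: PatternIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.index),):
            raise ValueError(
                f"counts length {counts.shape} does not match "
                f"{len(self.index)} patterns"
            )
        if counts.dtype != object and np.any(counts < 0):
            raise ValueError("counts must be nonnegative")  # symbolic entries skip the check
        object.__setattr__(self, "counts", counts)

    @property
    def total(self):
        return self.counts.sum()

    def __getitem__(self, pattern) -> float:
        return self.counts[self.index.position(pattern)]

    def as_dict(self) -> dict[str, float]:
        return {
            label: c.item() if hasattr(c, "item") else c
            for label, c in zip(self.index.labels(), self.counts)
        }


@dataclass(frozen=True)
class InjectionExperiment:
    """One multi-color injection: the covered targets and their yields.

    ``fractions[i]`` is the probability that a neuron projecting to target
    ``i`` is labeled by the tracer injected there.  Repeated trials of the
    same target subset are distinct experiments carrying their own fractions.
    """

    injected: frozenset[int]
    fractions: Mapping[int, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        injected = frozenset(self.injected)
        object.__setattr__(self, "injected", injected)
        if not injected or min(injected) < 1:
            raise ValueError("injected must be a nonempty set of targets >= 1")
        if self.fractions:
            fractions = dict(self.fractions)
            if set(fractions) != injected:
                raise ValueError("fractions must be defined for exactly the injected targets")
            for i, k in fractions.items():
                if isinstance(k, (int, float, np.floating)) and not (0.0 < k <= 1.0):
                    # symbolic fractions (e.g. sympy symbols) pass through
                    raise ValueError(f"fraction for target {i} must be in (0, 1], got {k}")
            object.__setattr__(self, "fractions", fractions)

    @property
    def k(self) -> int:
        """Number of injected targets."""
        return len(self.injected)

    def sorted_targets(self) -> list[int]:
        return sorted(self.injected)

    def combinations(self) -> list[frozenset[int]]:
        """The ``2^k - 1`` nonempty color combinations, canonical order."""
        return _subsets_in_binary_order(self.sorted_targets())


@dataclass(frozen=True)
class ObservationSet:
    """Observed (or expected) soma count per exact color combination."""

    experiment: InjectionExperiment
    counts: Mapping[frozenset[int], float]

    def __post_init__(self) -> None:
        combos = self.experiment.combinations()
        counts = {frozenset(c): v for c, v in self.counts.items()}
        if set(counts) != set(combos):
            raise ValueError(
                f"observation set must cover exactly the {len(combos)} "
                "nonempty combinations of the injected targets"
            )
        for c, v in counts.items():
            if isinstance(v, (int, float, np.integer, np.floating)) and v < 0:
                raise ValueError(f"negative count for combination {combo_key(c)}")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, combo) -> float:
        return self.counts[frozenset(combo)]

    def values(self) -> list[float]:
        """Counts in canonical combination order."""
        return [self.counts[c] for c in self.experiment.combinations()]

    def as_dict(self) -> dict[str, float]:
        return {combo_key(c): self.counts[c] for c in self.experiment.combinations()}


def expected_label_counts(
    counts: TypeCountVector, experiment: InjectionExperiment
) -> ObservationSet:
    """Expected exact-combination counts under the independent-labeling model.

    A neuron of pattern ``P`` projects to the injected targets ``P ∩ S``;
    each target ``i`` there labels it independently with probability ``k_i``.
    Its soma shows exact combination ``C ⊆ P ∩ S`` with probability
    ``prod_{i in C} k_i * prod_{j in (P∩S)\\C} (1 - k_j)``, so

    ``E[count(C)] = sum_{P ⊇ C} T_P * prod_{i in C} k_i
    * prod_{j in (P∩S)\\C} (1 - k_j)``.

    For a triple injection S={1,2,3} and the green-only combination C={1}
    this expands to the familiar
    ``G = k1(T1+T14) + k1(1-k2)(T12+T124) + k1(1-k3)(T13+T134)
    + k1(1-k2)(1-k3)(T123+T1234)`` (n=4).

    Implemented in pure Python over exact pattern subsets, so symbolic
    fractions/counts (e.g. sympy expressions) pass through unchanged; the
    solver uses an equivalent vectorized compilation of the same equations.
    """
    index = counts.index
    S = experiment.injected
    if max(S) > index.n_targets:
        raise ValueError(
            f"injected target {max(S)} exceeds n_targets={index.n_targets}"
        )
    if not experiment.fractions:
        raise ValueError("experiment carries no labeling fractions")
    k = experiment.fractions
    out: dict[frozenset[int], object] = {c: 0 for c in experiment.combinations()}
    for pattern, t in zip(index.patterns, counts.counts):
        q = pattern & S
        if not q:
            continue  # neuron invisible to this experiment
        for c in out:
            if not (c <= q):
                continue
            w = 1
            for i in c:
                w = w * k[i]
            for j in q - c:
                w = w * (1 - k[j])
            out[c] = out[c] + t * w
    return ObservationSet(experiment=experiment, counts=out)


@dataclass(frozen=True)
class ModelSystem:
    """A full system of constraints: experiments, observations, tallies.

    ``n_constraints`` counts one equation per (experiment, combination);
    unknowns split into ``2^n - 1`` integers (type counts) and one real
    labeling fraction per (experiment, injected target).
    """

    index: PatternIndex
    experiments: tuple[InjectionExperiment, ...]
    observations: tuple[ObservationSet, ...] | None

    def __post_init__(self) -> None:
        for e in self.experiments:
            if max(e.injected) > self.index.n_targets:
                raise ValueError(
                    f"experiment {e.label!r} injects target {max(e.injected)} "
                    f"but n_targets={self.index.n_targets}"
                )
        if self.observations is not None:
            if len(self.observations) != len(self.experiments):
                raise ValueError("one ObservationSet required per experiment")
            for e, o in zip(self.experiments, self.observations):
                if o.experiment.injected != e.injected:
                    raise ValueError("observation/experiment injected sets mismatch")

    @property
    def n_targets(self) -> int:
        return self.index.n_targets

    @property
    def n_constraints(self) -> int:
        return sum((1 << e.k) - 1 for e in self.experiments)

    @property
    def n_unknown_ints(self) -> int:
        return len(self.index)

    @property
    def n_unknown_reals(self) -> int:
        return sum(e.k for e in self.experiments)

    @property
    def n_unknowns(self) -> int:
        return self.n_unknown_ints + self.n_unknown_reals

    def observed_vector(self) -> np.ndarray:
        """All observed counts flattened in canonical (experiment, combo) order."""
        if self.observations is None:
            raise ValueError("system is a design skeleton without observations")
        return np.concatenate([np.asarray(o.values(), dtype=float) for o in self.observations])


def build_system(
    n_targets: int,
    experiments: Sequence[InjectionExperiment],
    observations: Sequence[ObservationSet] | None = None,
) -> ModelSystem:
    """Assemble a ModelSystem (or a design skeleton if observations omitted)."""
    index = enumerate_patterns(n_targets)
    return ModelSystem(
        index=index,
        experiments=tuple(experiments),
        observations=tuple(observations) if observations is not None else None,
    )


def design_tally(n_targets: int, k: int, repetitions: int = 0):
    """Constraint/unknown accounting for the full (n choose k) design.

    With ``N`` extra repetition rounds of every k-subset, the design has
    ``(N+1)*C(n,k)`` injections, each contributing ``2^k - 1`` constraints
    and ``k`` unknown labeling fractions, while the ``2^n - 1`` unknown type
    counts are shared.

    Returns
    -------
    dict with keys ``injections``, ``unknown_reals``, ``unknown_ints``,
    ``constraints``, ``unknowns`` and ``ratio`` (constraints / unknowns).
    """
    if not 1 <= k <= n_targets:
        raise ValueError(f"need 1 <= k <= n_targets, got k={k}, n={n_targets}")
    if repetitions < 0:
        raise ValueError("repetitions must be >= 0")
    injections = (repetitions + 1) * comb(n_targets, k)
    unknown_reals = k * injections
    unknown_ints = (1 << n_targets) - 1
    constraints = injections * ((1 << k) - 1)
    return {
        "injections": injections,
        "unknown_reals": unknown_reals,
        "unknown_ints": unknown_ints,
        "constraints": constraints,
        "unknowns": unknown_ints + unknown_reals,
        "ratio": constraints / (unknown_ints + unknown_reals),
    }
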