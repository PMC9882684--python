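"""Surrogate ground truth and simulated multi-color injection experiments.

The simulation study works from a surrogate type-count vector (a subset of
patterns zeroed, since not every pattern is expected between a source and a
set of targets), labeling fractions drawn from a truncated normal around
0.6, and observations computed either as exact model expectations or by
Bernoulli sampling of individual neurons.  A structure-matched null design,
whose observations are pure noise, provides a convergence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as iter_combinations

import numpy as np

from .model import (
    InjectionExperiment,
    ModelSystem,
    ObservationSet,
    TypeCountVector,
    build_system,
    enumerate_patterns,
    expected_label_counts,
)

__all__ = [
    "SurrogateSpec",
    "FractionSpec",
    "generate_surrogate_counts",
    "sample_fractions",
    "simulate_experiment",
    "simulate_design",
    "null_constraints",
    "GroundTruth",
]

_EPS = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for a surrogate ground-truth count vector.

    ``n_zero_types`` patterns are absent (count forced to zero); the
    remaining counts are positive integers summing to ``total_count_target``
    (within rounding).  Default 7 of 15 types zeroed for n=4, total 20,000 —
    the magnitude of a combined cortical source population.
    """

    n_targets: int = 4
    n_zero_types: int = 7
    total_count_target: int = 20_000

    def __post_init__(self) -> None:
        n_patterns = (1 << self.n_targets) - 1
        if not 0 <= self.n_zero_types <= n_patterns:
            raise ValueError(
                f"n_zero_types must be in [0, {n_patterns}], got {self.n_zero_types}"
            )
        if self.total_count_target < 1:
            raise ValueError("total_count_target must be positive")


@dataclass(frozen=True)
class FractionSpec:
    """Truncated-normal distribution of labeling fractions.

    Defaults N(0.6, 0.2) truncated to (0, 1): injections cover part of a
    region, so a bit over half of projecting neurons pick up label, with
    sizable experiment-to-experiment variability.
    """

    mean: float = 0.6
    sd: float = 0.2
    lower: float = _EPS
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValueError("need 0 <= lower < upper <= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative reals to integers that sum exactly to ``total``."""
    floors = np.floor(values).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:deficit]] += 1
    elif deficit < 0:  # possible only if values already summed above total
        order = np.argsort(values - floors, kind="stable")
        floors[order[: -deficit]] -= 1
    return floors


def generate_surrogate_counts(
    spec: SurrogateSpec, rng: np.random.Generator
) -> TypeCountVector:
    """Draw a surrogate type-count vector.

    Zero patterns are chosen uniformly at random; nonzero counts are drawn
    uniformly and rescaled to ``total_count_target``, then integer-rounded
    with largest-remainder correction so the realized total matches the
    target exactly (nonzero entries are kept >= 1).
    """
    index = enumerate_patterns(spec.n_targets)
    n = len(index)
    counts = np.zeros(n, dtype=np.int64)
    zero_pos = rng.choice(n, size=spec.n_zero_types, replace=False)
    nonzero = np.setdiff1d(np.arange(n), zero_pos)
    if nonzero.size:
        raw = rng.uniform(0.05, 1.0, size=nonzero.size)  # floor keeps types present
        scaled = raw / raw.sum() * spec.total_count_target
        counts[nonzero] = np.maximum(
            _largest_remainder_round(scaled, spec.total_count_target), 1
        )
    return TypeCountVector(index=index, counts=counts)


def sample_fractions(
    k: int, spec: FractionSpec | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``k`` labeling fractions from the truncated normal by rejection."""
    spec = spec or FractionSpec()
    rng = rng if rng is not None else np.random.default_rng()
    if k < 1:
        raise ValueError("k must be >= 1")
    if spec.sd == 0.0:
        if not spec.lower < spec.mean <= spec.upper:
            raise ValueError("degenerate spec: mean outside truncation interval")
        return np.full(k, spec.mean)
    out = np.empty(0)
    while out.size < k:
        draw = rng.normal(spec.mean, spec.sd, size=max(k, 16))
        keep = draw[(draw > spec.lower) & (draw <= spec.upper)]
        out = np.concatenate([out, keep])
    return out[:k]


def simulate_experiment(
    counts: TypeCountVector,
    injected,
    fractions,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
    label: str = "",
) -> ObservationSet:
    """Simulate one injection experiment.

    ``mode="expectation"`` returns the exact model expectations (real
    valued); ``mode="sampling"`` labels every neuron of every pattern by
    independent Bernoulli(k_i) events per injected-and-projected target and
    tallies exact label combinations (integer counts).
    """
    injected = frozenset(injected)
    targets = sorted(injected)
    fr = (
        dict(fractions)
        if isinstance(fractions, dict)
        else dict(zip(targets, np.asarray(fractions, dtype=float)))
    )
    experiment = InjectionExperiment(injected=injected, fractions=fr, label=label)
    if mode == "expectation":
        return expected_label_counts(counts, experiment)
    if mode != "sampling":
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        raise ValueError("sampling mode requires an rng")
    tallies = {c: 0 for c in experiment.combinations()}
    for pattern, m in zip(counts.index.patterns, counts.counts):
        q = sorted(pattern & injected)
        m = int(m)
        if not q or m == 0:
            continue
        probs = np.array([fr[i] for i in q])
        labels = rng.random((m, len(q))) < probs  # Bernoulli per neuron x target
        masks = labels @ (1 << np.arange(len(q)))
        hits = np.bincount(masks, minlength=1 << len(q))
        for mask in range(1, 1 << len(q)):
            if hits[mask]:
                combo = frozenset(q[j] for j in range(len(q)) if mask >> j & 1)
                tallies[combo] += int(hits[mask])
    return ObservationSet(experiment=experiment, counts=tallies)


def simulate_design(
    counts: TypeCountVector,
    n_targets: int,
    k: int,
    repetitions: int = 0,
    fraction_spec: FractionSpec | None = None,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> tuple[ModelSystem, "GroundTruth"]:
    """Simulate the full (n choose k) design with ``repetitions`` extra rounds.

    Every k-subset of targets is injected once per round, each time with
    freshly sampled fractions, so repeated trials contribute distinct
    constraints.  Returns the assembled system plus the generating truth.
    """
    if not 1 <= k <= n_targets:
        raise ValueError(f"need 1 <= k <= n_targets, got k={k}")
    rng = rng if rng is not None else np.random.default_rng()
    fraction_spec = fraction_spec or FractionSpec()
    experiments, observations = [], []
    for rep in range(repetitions + 1):
        for subset in iter_combinations(range(1, n_targets + 1), k):
            fr = sample_fractions(k, fraction_spec, rng)
            label = f"inj_{'+'.join(map(str, subset))}_r{rep}"
            obs = simulate_experiment(counts, subset, fr, mode=mode, rng=rng, label=label)
            experiments.append(obs.experiment)
            observations.append(obs)
    system = build_system(n_targets, experiments, observations)
    return system, GroundTruth(counts=counts, experiments=tuple(experiments))


def simulate_experiments(
    counts: TypeCountVector,
    subsets,
    fraction_spec: FractionSpec | None = None,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> tuple[ModelSystem, "GroundTruth"]:
    """Simulate an explicit list of injected subsets (repeats allowed).

    Unlike :func:`simulate_design`, the subsets need not form full
    combination rounds — e.g. the seven-experiment layout of four distinct
    triple injections plus one repeat of one and two repeats of another.
    Each entry gets freshly sampled fractions.
    """
    rng = rng if rng is not None else np.random.default_rng()
    fraction_spec = fraction_spec or FractionSpec()
    experiments, observations = [], []
    for idx, subset in enumerate(subsets):
        subset = tuple(sorted(subset))
        fr = sample_fractions(len(subset), fraction_spec, rng)
        obs = simulate_experiment(
            counts, subset, fr, mode=mode, rng=rng,
            label=f"inj_{'+'.join(map(str, subset))}_{idx}",
        )
        experiments.append(obs.experiment)
        observations.append(obs)
    system = build_system(counts.index.n_targets, experiments, observations)
    return system, GroundTruth(counts=counts, experiments=tuple(experiments))


SEVEN_EXPERIMENT_SUBSETS: tuple[tuple[int, ...], ...] = (
    (1, 2, 3), (1, 2, 4), (1, 3, 4), (2, 3, 4),  # the four distinct triples
    (1, 2, 3),                                    # one repeated trial
    (1, 2, 4), (1, 2, 4),                         # two repeated trials
)
"""Seven triple injections on four targets: every distinct triple once,
one subset repeated once and another repeated twice."""


def null_constraints(
    design_system: ModelSystem,
    count_scale: float | None = None,
    rng: np.random.Generator | None = None,
) -> ModelSystem:
    """Structure-matched null system: observations are i.i.d. uniform noise.

    Keeps the experiment layout (same targets, fractions become irrelevant)
    but replaces every observed count with a Uniform(0, count_scale) draw;
    no type-count vector generates these constraints.  ``count_scale``
    defaults to the mean observed constraint of the matched system, keeping
    the noise on the scale of the real data.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if count_scale is None:
        count_scale = float(design_system.observed_vector().mean())
    if count_scale <= 0:
        raise ValueError("count_scale must be > 0")
    observations = []
    for e in design_system.experiments:
        combos = e.combinations()
        vals = rng.uniform(0.0, count_scale, size=len(combos))
        observations.append(
            ObservationSet(experiment=e, counts=dict(zip(combos, vals)))
        )
    return build_system(design_system.n_targets, design_system.experiments, observations)


@dataclass(frozen=True)
class GroundTruth:
    """The generating truth of a simulated design, for recovery scoring."""

    counts: TypeCountVector
    experiments: tuple[InjectionExperiment, ...]

    def fraction_vector(self) -> np.ndarray:
        """True fractions flattened in (experiment, sorted target) order."""
        return np.array(
            [e.fractions[i] for e in self.experiments for i in e.sorted_targets()]
        )

    def as_dict(self) -> dict:
        return {
            "counts": self.counts.as_dict(),
            "experiments": [
                {
                    "label": e.label,
                    "injected": e.sorted_targets(),
                    "fractions": {str(i): e.fractions[i] for i in e.sorted_targets()},
                }
                for e in self.experiments
            ],
        }
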