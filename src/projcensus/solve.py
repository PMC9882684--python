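"""(μ+λ) evolution strategy over mixed integer/real genomes.

The unknowns of a constraint system are the ``2^n - 1`` integer type counts
plus one real labeling fraction per (experiment, injected target).  Fitness
is the RMSE between predicted and observed exact-combination counts,
normalized by the mean observed constraint.  Each generation, λ offspring
are cloned from uniformly chosen parents and mutated (integer random-walk
steps, Gaussian steps on fractions, both at fixed per-gene rates, no
adaptation); the best μ of parents ∪ offspring survive — elitist truncation
selection, so the incumbent best never worsens.

Genome evaluation is vectorized: each experiment's equations factor into a
linear aggregation of the type counts (patterns sharing a visible footprint
``P ∩ S`` are interchangeable within that experiment) followed by
subset-product weights in the fractions, evaluated for the whole population
with a handful of numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import ModelSystem, TypeCountVector

__all__ = [
    "SolverConfig",
    "Candidate",
    "SolutionTrial",
    "AggregatedSolution",
    "fitness",
    "evolve",
    "run_trials",
    "aggregate_trials",
    "DESK_PROFILE",
    "PAPER_PROFILE",
]

_FRACTION_EPS = 1e-9


@dataclass(frozen=True)
class SolverConfig:
    """Evolution-strategy settings.

    The ``paper`` profile (μ=50,000, λ=250,000, 2,500 generations, 50
    trials) matches the full-scale study and takes hours to days on one
    CPU; the ``desk`` profile (μ=500, λ=2,500, 300 generations, 10 trials)
    is sized for interactive work and the test suite.
    """

    mu: int = 50_000
    lam: int = 250_000
    generations: int = 2_500
    trials: int = 50
    int_mutation_rate: float = 0.1
    real_mutation_rate: float = 0.1
    int_step: int | None = None  # bound scales with data (half the init cap) when None
    real_sigma: float = 0.05
    int_upper_bound: int | None = None  # derived from data scale when None
    seed: int = 0
    fit_fractions: bool = True

    def __post_init__(self) -> None:
        if self.mu < 1 or self.lam < self.mu:
            raise ValueError("need 1 <= mu <= lambda")
        if self.generations < 1 or self.trials < 1:
            raise ValueError("generations and trials must be >= 1")
        for r in (self.int_mutation_rate, self.real_mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")
        if (self.int_step is not None and self.int_step < 1) or self.real_sigma <= 0:
            raise ValueError("int_step >= 1 and real_sigma > 0 required")

    def with_profile(self, profile: str) -> "SolverConfig":
        if profile == "paper":
            return replace(self, mu=50_000, lam=250_000, generations=2_500, trials=50)
        if profile == "desk":
            return replace(self, mu=500, lam=2_500, generations=300, trials=10)
        raise ValueError(f"unknown profile {profile!r}")


DESK_PROFILE = SolverConfig().with_profile("desk")
PAPER_PROFILE = SolverConfig().with_profile("paper")


@dataclass(frozen=True)
class Candidate:
    """One genome: a type-count vector plus flat per-experiment fractions."""

    counts: TypeCountVector
    fractions: np.ndarray  # flat, (experiment, sorted target) order
    fitness: float

    def fractions_by_experiment(self, system: ModelSystem) -> list[dict[int, float]]:
        out, pos = [], 0
        for e in system.experiments:
            targets = e.sorted_targets()
            out.append({t: float(self.fractions[pos + j]) for j, t in enumerate(targets)})
            pos += len(targets)
        return out


@dataclass(frozen=True)
class SolutionTrial:
    best: Candidate
    fitness_trace: np.ndarray  # best fitness after each generation (non-increasing)
    seed: int


class CompiledSystem:
    """Per-experiment factorization of the expected-count equations.

    For experiment ``e`` injecting targets ``S`` (size k), patterns with the
    same footprint ``Q = P ∩ S`` are summed by a 0/1 aggregation matrix; an
    exact combination ``C`` then expects
    ``sum_{Q ⊇ C} M_Q * prod_{i in C} k_i * prod_{j in Q\\C} (1 - k_j)``.
    Subset products of the fractions are built incrementally over bitmasks.
    """

    def __init__(self, system: ModelSystem):
        if system.observations is None:
            raise ValueError("cannot compile a design skeleton without observations")
        self.system = system
        self.observed = system.observed_vector()
        if self.observed.size == 0:
            raise ValueError("system has no constraints")
        self.norm = float(self.observed.mean())
        if self.norm == 0.0:
            raise ValueError("degenerate normalization: all observed constraints are zero")
        self.n_patterns = len(system.index)
        self.n_reals = system.n_unknown_reals
        self._experiments = []
        pos = 0
        for e in system.experiments:
            targets = e.sorted_targets()
            k = len(targets)
            bit = {t: 1 << j for j, t in enumerate(targets)}
            agg = np.zeros(((1 << k) - 1, self.n_patterns))
            for p_idx, pattern in enumerate(system.index.patterns):
                mask = sum(bit[t] for t in pattern if t in bit)
                if mask:
                    agg[mask - 1, p_idx] = 1.0
            # superset lists: for each combo C, the footprints Q ⊇ C (within S)
            supersets = []
            full = (1 << k) - 1
            for c in range(1, full + 1):
                comp = full & ~c
                qs, r = [], comp
                while True:
                    qs.append(c | r)
                    if r == 0:
                        break
                    r = (r - 1) & comp
                supersets.append(np.array(sorted(qs)))
            self._experiments.append(
                {"k": k, "slice": slice(pos, pos + k), "agg": agg, "supersets": supersets}
            )
            pos += k
        self.fixed_fractions = None
        if all(e.fractions for e in system.experiments):
            self.fixed_fractions = np.array(
                [e.fractions[t] for e in system.experiments for t in e.sorted_targets()]
            )

    def predict(self, counts: np.ndarray, fractions: np.ndarray) -> np.ndarray:
        """Expected counts for a population: (pop, n_constraints)."""
        counts = np.atleast_2d(counts).astype(float)
        fractions = np.atleast_2d(fractions)
        pop = counts.shape[0]
        cols = []
        for ex in self._experiments:
            k = ex["k"]
            m = counts @ ex["agg"].T  # (pop, 2^k - 1)
            p = fractions[:, ex["slice"]]
            w1 = [np.ones(pop)]
            w0 = [np.ones(pop)]
            for mask in range(1, 1 << k):
                j = (mask & -mask).bit_length() - 1
                w1.append(w1[mask & (mask - 1)] * p[:, j])
                w0.append(w0[mask & (mask - 1)] * (1.0 - p[:, j]))
            for c in range(1, 1 << k):
                qs = ex["supersets"][c - 1]
                acc = np.zeros(pop)
                for q in qs:
                    acc += m[:, q - 1] * w0[q & ~c]
                cols.append(w1[c] * acc)
        return np.stack(cols, axis=1)

    def fitness_of(self, counts: np.ndarray, fractions: np.ndarray) -> np.ndarray:
        pred = self.predict(counts, fractions)
        rmse = np.sqrt(np.mean((pred - self.observed) ** 2, axis=1))
        return rmse / self.norm

    def default_int_upper_bound(self) -> int:
        # crude scale guess: twice the total observed mass spread over patterns
        return max(1, int(np.ceil(2.0 * self.observed.sum() / self.n_patterns)))


def fitness(candidate: Candidate, system: ModelSystem) -> float:
    """Normalized constraint RMSE of one candidate against a system."""
    compiled = CompiledSystem(system)
    return float(
        compiled.fitness_of(
            candidate.counts.counts[None, :], np.asarray(candidate.fractions)[None, :]
        )[0]
    )


def evolve(
    system: ModelSystem,
    config: SolverConfig,
    rng: np.random.Generator,
    compiled: CompiledSystem | None = None,
    seed_label: int = 0,
) -> SolutionTrial:
    """Run one (μ+λ) ES trial to convergence (fixed generation budget).

    Initialization: counts uniform integers in [0, int_upper_bound],
    fractions uniform in (0, 1).  Mutation: each integer gene, with
    probability ``int_mutation_rate``, takes a signed random-walk step whose
    magnitude is drawn log-uniformly from [1, int_step] (mixing coarse
    exploration with fine refinement at a fixed, non-adaptive rate), clipped
    at 0; each real gene, with probability ``real_mutation_rate``, adds
    N(0, real_sigma) noise clipped to (0, 1].  Survivor selection keeps the
    best μ of parents ∪ offspring (stable sort: ties broken by insertion
    order, parents first).
    """
    compiled = compiled or CompiledSystem(system)
    n_p, n_r = compiled.n_patterns, compiled.n_reals
    ub = config.int_upper_bound or compiled.default_int_upper_bound()
    int_step = config.int_step or max(5, ub // 2)
    mu, lam = config.mu, config.lam

    counts = rng.integers(0, ub + 1, size=(mu, n_p)).astype(np.int64)
    if config.fit_fractions:
        fracs = rng.uniform(_FRACTION_EPS, 1.0, size=(mu, n_r))
    else:
        if compiled.fixed_fractions is None:
            raise ValueError("fit_fractions=False requires fractions on every experiment")
        fracs = np.tile(compiled.fixed_fractions, (mu, 1))
    fit = compiled.fitness_of(counts, fracs)
    order = np.argsort(fit, kind="stable")
    counts, fracs, fit = counts[order], fracs[order], fit[order]

    trace = np.empty(config.generations + 1)
    trace[0] = fit[0]
    for gen in range(config.generations):
        parents = rng.integers(0, mu, size=lam)
        off_c = counts[parents].copy()
        off_f = fracs[parents].copy()
        mask = rng.random((lam, n_p)) < config.int_mutation_rate
        mag = np.rint(
            np.exp(rng.uniform(0.0, np.log(int_step), size=(lam, n_p)))
        ).astype(np.int64)
        steps = mag * (rng.integers(0, 2, size=(lam, n_p)) * 2 - 1)
        off_c[mask] += steps[mask]
        np.maximum(off_c, 0, out=off_c)
        if config.fit_fractions and n_r:
            rmask = rng.random((lam, n_r)) < config.real_mutation_rate
            noise = rng.normal(0.0, config.real_sigma, size=(lam, n_r))
            off_f[rmask] += noise[rmask]
            np.clip(off_f, _FRACTION_EPS, 1.0, out=off_f)
        off_fit = compiled.fitness_of(off_c, off_f)
        all_c = np.concatenate([counts, off_c])
        all_f = np.concatenate([fracs, off_f])
        all_fit = np.concatenate([fit, off_fit])
        keep = np.argsort(all_fit, kind="stable")[:mu]
        counts, fracs, fit = all_c[keep], all_f[keep], all_fit[keep]
        trace[gen + 1] = fit[0]

    best = Candidate(
        counts=TypeCountVector(index=system.index, counts=counts[0]),
        fractions=fracs[0].copy(),
        fitness=float(fit[0]),
    )
    return SolutionTrial(best=best, fitness_trace=trace, seed=seed_label)


def run_trials(
    system: ModelSystem, config: SolverConfig, rng: np.random.Generator | None = None
) -> list[SolutionTrial]:
    """Independent ES trials with distinct seeds derived from the master seed.

    Trial sub-seeds are spawned deterministically from ``config.seed`` (the
    optional ``rng`` argument is accepted for interface symmetry but the
    master seed governs reproducibility), so results are identical across
    reruns and independent of execution order.
    """
    del rng
    compiled = CompiledSystem(system)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.trials)
    trials = []
    for i, child in enumerate(children):
        trial_rng = np.random.default_rng(child)
        trials.append(
            evolve(system, config, trial_rng, compiled=compiled, seed_label=i)
        )
    return trials


@dataclass(frozen=True)
class AggregatedSolution:
    """Median/IQR summary over the top trials, per pattern and per fraction."""

    pattern_labels: tuple[str, ...]
    count_median: np.ndarray
    count_iqr: np.ndarray
    fraction_median: np.ndarray
    fraction_iqr: np.ndarray
    top_seeds: tuple[int, ...]
    top_fitness: tuple[float, ...]

    def counts_table(self) -> list[dict]:
        return [
            {"pattern": lbl, "median": float(m), "iqr": float(q)}
            for lbl, m, q in zip(self.pattern_labels, self.count_median, self.count_iqr)
        ]


def aggregate_trials(
    trials: Sequence[SolutionTrial], top_k: int = 10
) -> AggregatedSolution:
    """Median and IQR across the ``top_k`` trials by best fitness.

    Ties in fitness break toward the lower trial seed.  Quartiles use
    linear interpolation; medians of integer counts over an even top_k may
    therefore be half-integers and are reported as-is.
    """
    if not trials:
        raise ValueError("empty trial list")
    if not 1 <= top_k <= len(trials):
        raise ValueError(f"top_k must be in [1, {len(trials)}]")
    ranked = sorted(trials, key=lambda t: (t.best.fitness, t.seed))[:top_k]
    counts = np.stack([t.best.counts.counts for t in ranked]).astype(float)
    fracs = np.stack([t.best.fractions for t in ranked])
    q1c, medc, q3c = np.percentile(counts, [25, 50, 75], axis=0)
    if fracs.shape[1]:
        q1f, medf, q3f = np.percentile(fracs, [25, 50, 75], axis=0)
    else:
        q1f = medf = q3f = np.empty(0)
    labels = tuple(ranked[0].best.counts.index.labels())
    return AggregatedSolution(
        pattern_labels=labels,
        count_median=medc,
        count_iqr=q3c - q1c,
        fraction_median=medf,
        fraction_iqr=q3f - q1f,
        top_seeds=tuple(t.seed for t in ranked),
        top_fitness=tuple(t.best.fitness for t in ranked),
    )
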