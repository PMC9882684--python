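# Methods

## The labeling-count model

A neuron's projection pattern is the subset *P* of the *n* target regions
its axon reaches; patterns are enumerated in binary-counting order (pattern
*S* at position Σ<sub>i∈S</sub> 2<sup>i−1</sup>), giving the fixed sequence
T1, T2, T12, T3, T13, … used by every vector, file and report in the
package. An injection experiment covers a target subset *S*; each injected
target *i* labels a projecting neuron independently with probability
*k<sub>i</sub>* ∈ (0, 1]. A neuron of pattern *P* is visible to the
experiment through its footprint *Q = P ∩ S* and lands in exact color
combination *C ⊆ Q* with probability
Π<sub>i∈C</sub> k<sub>i</sub> · Π<sub>j∈Q\C</sub> (1 − k<sub>j</sub>), in
the unlabeled remainder otherwise. Expected combination counts are linear
in the type counts and polynomial in the yields; they are kept real-valued
throughout (no rounding inside the model), and observations are accepted
as nonnegative reals so expectation-mode simulations are representable.

Independence of labeling across tracers within a neuron is a model
assumption, not an established fact of tracer biology: possible tracer
competition would make co-labeling anti-correlated and is not modeled.

The reference implementation of the expectation
(`model.expected_label_counts`) is a direct pure-Python sum over patterns,
which also evaluates symbolically; the solver uses an equivalent compiled
form (per-experiment 0/1 aggregation of counts into footprints, then
subset-product weights over bitmasks) that evaluates whole populations in
a few vectorized operations. Tests assert the two routes agree and check
both against a per-neuron Bernoulli Monte-Carlo oracle.

## Surrogate data generation

`SurrogateSpec` defaults: *n* = 4 targets, 7 of the 15 patterns forced to
zero (not every pattern is expected to exist between a source and a given
target set), total count 20,000 — the magnitude of a combined cortical
source population; the simulation-study sweep uses 5,000 so that
per-pattern counts sit in the hundreds. Nonzero counts are drawn uniformly
(floor 0.05 of the raw range, so no type is vanishingly small), rescaled to
the target total and integer-rounded with largest-remainder correction;
the realized total matches the target exactly up to the ≥1 floor on
nonzero types. The uniform shape is a modeling choice — real count spectra
are unknown and likely heavier-tailed.

Labeling fractions are drawn from N(0.6, 0.2) truncated to (0, 1) by
rejection, reflecting that injections cover roughly half of a target
region with substantial variability. Repeated trials of the same target
subset resample fractions independently — this is what makes repeated
experiments informative (distinct constraints) rather than redundant.

Two observation modes: `expectation` (deterministic model expectations
given the drawn fractions; the default for the simulation study) and
`sampling` (per-neuron Bernoulli labeling, integer counts) for realism
checks. The null model keeps an experiment layout but replaces every
observation with Uniform(0, c) noise, c defaulting to the mean observed
constraint of the matched system so the comparison is on equal scale.

What the simulator does **not** emulate: counting/annotation error,
tracer spillover between regions, spatial injection geometry (coverage is
abstracted entirely into the fractions), and correlated labeling. Passing
recovery tests therefore demonstrate solvability of the idealized system,
not robustness to all experimental noise; the sampling mode adds only
binomial labeling noise.

## The solver

A (μ+λ) evolution strategy without any form of mutation adaptation.
Genome: 2<sup>n</sup> − 1 nonnegative integers plus one yield in (0, 1]
per (experiment, injected target). Fitness: RMSE over all constraints
between predicted and observed counts, normalized by the mean observed
constraint (scale-free, so systems of different magnitude are comparable).
Each generation λ offspring are cloned from uniformly chosen parents and
mutated; the best μ of parents ∪ offspring survive (elitist truncation,
stable sort, ties to insertion order), so best fitness is non-increasing.

Mutation operators and rates:

| parameter | default | meaning |
|---|---|---|
| `int_mutation_rate` | 0.1 | per-gene probability of an integer step |
| `int_step` | half the initialization cap | bound on integer step magnitude |
| `real_mutation_rate` | 0.1 | per-gene probability of a yield step |
| `real_sigma` | 0.05 | SD of the Gaussian yield step (~5% of scale) |
| `int_upper_bound` | 2·(total observed count)/(2ⁿ−1) | initialization cap |

Integer step magnitudes are drawn **log-uniformly** from [1, `int_step`]
with random sign, clipped at 0. A fixed small step bound cannot traverse
count scales of 10³ within a few hundred generations, while a uniform
large bound wastes most mutations far from convergence; the log-uniform
mixture provides coarse exploration and unit-step refinement at a fixed,
non-adaptive rate. Yield mutations clip to (0, 1] rather than re-drawing,
preserving the per-gene mutation-rate semantics. Out-of-range behavior at
the 0 boundary (clipping) slightly inflates the probability of exact
zeros, which suits count vectors where many types are genuinely absent.

Two profiles: `paper` (μ=50,000, λ=250,000, 2,500 generations, 50 trials)
for full-scale studies, and `desk` (μ=500, λ=2,500, 300 generations, 10
trials) sized so a complete simulation sweep runs in minutes on one CPU;
all bundled tests and the acceptance script use the desk profile. Trials
differ only in their RNG seed (spawned deterministically from the master
seed), execute independently, and are bit-reproducible. The adopted
solution is the per-variable median over the top 10 trials by best-ever
fitness (identical to final fitness under elitism), with IQRs from
linear-interpolation quartiles — medians of integer variables over an even
number of trials can be half-integers and are reported as-is. When yields
are known (e.g. calibration designs), `fit_fractions=False` holds them
fixed and the ES searches counts only; this is also the regime in which
tiny systems have closed-form solutions used as test oracles.

## The error metric

Ê = Σ<sub>i</sub> (1 + (M/I − m<sub>i</sub><sup>t</sup>)/M) ·
|m<sub>i</sub><sup>t</sup> − m<sub>i</sub><sup>e</sup>| / M. The
parenthesization is read so the weight is a dimensionless correction
around 1 that up-weights rarer-than-average types; the convention string
is recorded in every `ErrorReport`. A negative weight would require
m<sup>t</sup> > M/I + M, impossible for nonnegative counts, but weights
are used as computed and flagged, never clamped. Ê is zero iff recovery
is exact and undefined for M = 0.

## Numerical and design choices

- Targets are 1-based integer indices internally; a name↔index map travels
  in the constraint-file header (`target_names`).
- Constraint files: JSON with `"+"`-joined sorted-index combination keys,
  or an equivalent flat CSV (`float_precision="round_trip"` on read keeps
  write→read→write byte-stable).
- The multi-model study workflow (combined + per-layer constraint files)
  solves each file independently with non-overlapping RNG streams and
  reports both; sums of per-layer estimates are not forced to match the
  combined model.
- Degenerate inputs: all-zero observed constraints make the fitness
  normalizer zero and are rejected; empty experiment lists form valid
  design skeletons (tallies only).
- Simulation sizes in the test suite and acceptance script: surrogate
  total 5,000 (recovery sweep, designs of 4/8/12 triple injections, 5
  master seeds) and 20,000 (7-experiment null-model comparison, 5 seeds),
  both at the desk profile.

## Known limitations

- Desk-scale solver runs leave wide IQRs on weakly constrained patterns;
  tight censuses need the paper profile (hours to days of CPU).
- With unknown yields, small designs are not fully identifiable (count/yield
  trade-offs can fit the constraints with wrong censuses); more injections
  or repeated trials are the remedy, quantified by the recovery sweep.
- The ES is a heuristic: convergence to the global optimum is not
  guaranteed, which is precisely why multiple independent trials and the
  top-10 median are part of the procedure.
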