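# projcensus

Combinatorial quantification of neuronal projection patterns from
multi-color retrograde tracing.

## The problem

A source brain region projecting to *n* target regions can host up to
2<sup>n</sup> − 1 distinct projection neuron types — one for every nonempty
subset of targets an axon can reach. Counting the neurons of each type (a
"projectomics census") would require impractically many single-neuron
reconstructions. Multi-color retrograde tracing offers a shortcut: inject
*k* < *n* targets with distinguishable retrograde tracers and count the
somata in the source carrying each *exact* color combination. Because an
injection covers only part of a target region, a neuron projecting to
target *i* is labeled only with probability *k<sub>i</sub>* < 1 (the
labeling fraction, or yield). With labeling independent across tracers
within a neuron, the expected count for exact combination *C* in an
experiment injecting targets *S* is

```
E[count(C)] = Σ_{P ⊇ C}  T_P · Π_{i∈C} k_i · Π_{j∈(P∩S)\C} (1 − k_j)
```

where *T<sub>P</sub>* is the unknown number of neurons with projection
pattern *P*. Each experiment injecting *k* targets contributes
2<sup>k</sup> − 1 such constraints and *k* unknown yields; the
2<sup>n</sup> − 1 unknown counts are shared by all experiments. For
*n* = 4, *k* = 3 the four distinct triple injections give 28 equations for
27 unknowns, and repeating experiments (with naturally varying yields)
improves the constraints-to-unknowns ratio further.

`projcensus` builds these nonlinear systems from constraint files or from
simulation, solves them with a (μ+λ) evolution strategy over the mixed
integer (counts) / real (yields) genome, and scores recovery with a
weighted error metric Ê that up-weights rare types:

```
Ê = Σ_i (1 + (M/I − m_i^t)/M) · |m_i^t − m_i^e| / M
```

with *M* the true total count, *I* the number of types, and
*m<sup>t</sup>*, *m<sup>e</sup>* the true and estimated counts.

It is written for anatomists and computational neuroscientists planning or
analyzing multi-color retrograde tracing experiments.

## Worked example

Simulate a 12-triple-injection study on 4 targets from a surrogate ground
truth of ~5,000 neurons (7 of the 15 possible patterns absent), solve it at
desk scale, and score the recovery:

```python
import numpy as np
from dataclasses import replace
import projcensus as pc

rng = np.random.default_rng(0)
truth = pc.generate_surrogate_counts(
    pc.SurrogateSpec(n_targets=4, n_zero_types=7, total_count_target=5000), rng)
system, gt = pc.simulate_design(truth, n_targets=4, k=3, repetitions=2, rng=rng)
print(f"{len(system.experiments)} experiments, {system.n_constraints} constraints, "
      f"{system.n_unknowns} unknowns")

cfg = replace(pc.SolverConfig().with_profile("desk"), seed=0)
trials = pc.run_trials(system, cfg)
agg = pc.aggregate_trials(trials, top_k=10)        # median of the top 10 trials
report = pc.estimation_error(truth, agg.count_median)
```

which prints (pattern labels are `+`-joined target indices; `± IQR` over
the top-10 trials):

```
12 experiments, 84 constraints, 51 unknowns
best fitness: 0.0363
  T1+2     true   771  est   642.5 ± 152.8
  T1+4     true   588  est   187.5 ± 465.5
  T2+4     true   974  est   649.5 ± 197.8
  T1+2+4   true   857  est  1141.5 ± 579.0
  T3+4     true    55  est     0.0 ± 9.8
  T1+3+4   true   898  est   875.5 ± 183.5
  T2+3+4   true    85  est     0.0 ± 52.8
  T1+2+3+4 true   772  est   992.5 ± 201.8
E_hat: 0.3882
```

`best fitness` is the constraint RMSE normalized to the mean observed
count: 0.036 means the best genome reproduces the observations to within a
few percent of their average. The per-pattern medians recover the broad
structure of the truth while wide IQRs (e.g. `T1+4`) flag patterns the 12
experiments at this solver scale do not pin down; Ê summarizes the census
error. The `desk` profile (μ=500, λ=2,500, 300 generations, 10 trials) is
three orders of magnitude cheaper than the full-scale `paper` profile
(μ=50,000, λ=250,000, 2,500 generations, 50 trials), which correspondingly
tightens both fitness and Ê. Adding experiments helps at any scale: the
mean Ê over seeds drops steadily from 4 to 8 to 12 triple injections (the
acceptance script below recomputes this sweep).

The same workflows are scriptable from the shell:

```sh
projcensus simulate --n-targets 4 --k 3 --repetitions 2 --total 5000 \
    --seed 0 --out sim.json --truth-out truth.json
projcensus solve --constraints sim.json --profile desk --seed 0 --out sol.json
projcensus evaluate --truth truth.json --estimate sol.json
projcensus study --spec study.json --out results/   # combined + per-layer files
```

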