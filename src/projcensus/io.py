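"""Constraint-file and solution-file I/O, and the multi-model study workflow.

Constraint files (JSON, with an equivalent flat CSV dialect) carry a header
``{n_targets, target_names}`` and one entry per injection experiment with
its observed count for every exact color combination, keyed by
``"+"``-joined sorted target indices.  Layer-segregated datasets are just
additional constraint files solved independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    InjectionExperiment,
    ModelSystem,
    ObservationSet,
    build_system,
    combo_key,
    parse_combo_key,
)
from .simulate import GroundTruth
from .solve import AggregatedSolution, SolutionTrial, SolverConfig, aggregate_trials, run_trials

__all__ = [
    "read_constraints",
    "write_constraints",
    "write_ground_truth",
    "read_ground_truth",
    "write_solution",
    "StudyConfig",
    "run_study",
]


class ConstraintFileError(ValueError):
    """Schema violation in a constraint file, with field context."""


def _validate_experiment_entry(entry: Mapping, n_targets: int, idx: int):
    where = f"experiments[{idx}]"
    injected = entry.get("injected")
    if not injected or not all(isinstance(i, int) and 1 <= i <= n_targets for i in injected):
        raise ConstraintFileError(
            f"{where}.injected must be nonempty target indices in 1..{n_targets}"
        )
    injected_set = frozenset(injected)
    if len(injected_set) != len(injected):
        raise ConstraintFileError(f"{where}.injected contains duplicates")
    obs = entry.get("observations", {})
    counts = {}
    for key, value in obs.items():
        try:
            combo = parse_combo_key(str(key))
        except ValueError as exc:
            raise ConstraintFileError(f"{where}.observations key {key!r}: {exc}") from exc
        if not combo <= injected_set:
            raise ConstraintFileError(
                f"{where}.observations[{key!r}] references un-injected target(s) "
                f"{sorted(combo - injected_set)}"
            )
        if not isinstance(value, (int, float)) or value < 0 or not np.isfinite(value):
            raise ConstraintFileError(
                f"{where}.observations[{key!r}] must be a nonnegative finite number"
            )
        counts[combo] = float(value)
    expected = (1 << len(injected_set)) - 1
    if len(counts) != expected:
        raise ConstraintFileError(
            f"{where}: expected {expected} combinations for {len(injected_set)} "
            f"injected targets, found {len(counts)}"
        )
    fractions = entry.get("fractions") or {}
    fr = {}
    for key, value in fractions.items():
        t = int(key)
        if t not in injected_set:
            raise ConstraintFileError(f"{where}.fractions[{key!r}]: target not injected")
        fr[t] = float(value)
    experiment = InjectionExperiment(
        injected=injected_set, fractions=fr, label=str(entry.get("id", f"exp{idx}"))
    )
    return experiment, ObservationSet(experiment=experiment, counts=counts)


def _system_from_payload(payload: Mapping) -> tuple[ModelSystem, list[str]]:
    try:
        n_targets = int(payload["n_targets"])
    except (KeyError, TypeError, ValueError):
        raise ConstraintFileError("header must define integer n_targets")
    names = payload.get("target_names") or [f"T{i}" for i in range(1, n_targets + 1)]
    if len(names) != n_targets:
        raise ConstraintFileError(
            f"target_names has {len(names)} entries but n_targets={n_targets}"
        )
    experiments, observations = [], []
    for idx, entry in enumerate(payload.get("experiments", [])):
        e, o = _validate_experiment_entry(entry, n_targets, idx)
        experiments.append(e)
        observations.append(o)
    return build_system(n_targets, experiments, observations), list(names)


def read_constraints(path: str | Path) -> ModelSystem:
    """Read a JSON or CSV constraint file into a validated ModelSystem."""
    system, _ = read_constraints_with_names(path)
    return system


def read_constraints_with_names(path: str | Path) -> tuple[ModelSystem, list[str]]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        payload = _csv_to_payload(path)
    else:
        payload = json.loads(path.read_text())
    return _system_from_payload(payload)


def write_constraints(
    system: ModelSystem,
    path: str | Path,
    target_names: Sequence[str] | None = None,
    include_fractions: bool = False,
) -> None:
    """Write a system's experiments and observations to JSON or CSV.

    ``include_fractions`` embeds the true labeling fractions (simulation
    provenance); real experimental files leave them out — they are unknowns.
    """
    path = Path(path)
    names = list(target_names or [f"T{i}" for i in range(1, system.n_targets + 1)])
    payload = {"n_targets": system.n_targets, "target_names": names, "experiments": []}
    for e, o in zip(system.experiments, system.observations):
        entry = {
            "id": e.label,
            "injected": e.sorted_targets(),
            "observations": {k: float(v) for k, v in o.as_dict().items()},
        }
        if include_fractions and e.fractions:
            entry["fractions"] = {str(t): e.fractions[t] for t in e.sorted_targets()}
        payload["experiments"].append(entry)
    if path.suffix.lower() == ".csv":
        _payload_to_csv(payload, path)
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def _payload_to_csv(payload: Mapping, path: Path) -> None:
    rows = []
    for entry in payload["experiments"]:
        inj = combo_key(entry["injected"])
        for key, value in entry["observations"].items():
            rows.append(
                {"experiment": entry["id"], "injected": inj, "combination": key, "count": value}
            )
    header = f"# n_targets={payload['n_targets']} target_names={','.join(payload['target_names'])}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(rows, columns=["experiment", "injected", "combination", "count"]).to_csv(
            fh, index=False
        )


def _csv_to_payload(path: Path) -> dict:
    first = path.read_text().splitlines()[0]
    if not first.startswith("#"):
        raise ConstraintFileError(
            "CSV constraint file must start with '# n_targets=... target_names=...'"
        )
    meta = dict(
        tok.split("=", 1) for tok in first.lstrip("# ").split() if "=" in tok
    )
    try:
        n_targets = int(meta["n_targets"])
    except (KeyError, ValueError):
        raise ConstraintFileError("CSV header must define n_targets=<int>")
    names = meta.get("target_names", "").split(",") if meta.get("target_names") else None
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    experiments = []
    for exp_id, group in df.groupby("experiment", sort=False):
        injected = sorted(parse_combo_key(str(group["injected"].iloc[0])))
        experiments.append(
            {
                "id": str(exp_id),
                "injected": injected,
                "observations": {
                    str(r.combination): float(r.count) for r in group.itertuples()
                },
            }
        )
    payload = {"n_targets": n_targets, "experiments": experiments}
    if names:
        payload["target_names"] = names
    return payload


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.as_dict(), indent=2) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    """Ground-truth sidecar as a plain dict (pattern label -> true count, ...)."""
    return json.loads(Path(path).read_text())


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_solution(
    solution: AggregatedSolution,
    trials: Sequence[SolutionTrial],
    config: SolverConfig,
    path: str | Path,
    extra_metadata: Mapping | None = None,
) -> dict:
    """Write the adopted solution (median/IQR per pattern) plus provenance."""
    payload = {
        "patterns": solution.counts_table(),
        "sum_median": float(solution.count_median.sum()),
        "fractions": {
            "median": [float(v) for v in solution.fraction_median],
            "iqr": [float(v) for v in solution.fraction_iqr],
        },
        "metadata": {
            "config": asdict(config),
            "quartile_convention": "linear interpolation",
            "top_seeds": list(solution.top_seeds),
            "top_fitness": [float(f) for f in solution.top_fitness],
            "per_trial_final_fitness": [float(t.best.fitness) for t in trials],
            **(dict(extra_metadata) if extra_metadata else {}),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


@dataclass(frozen=True)
class StudyConfig:
    """A multi-model study: one constraint file per model, solved independently.

    Models (e.g. "combined" plus per-layer files) never share RNG streams:
    each gets its own seed spawned from the master seed.
    """

    constraint_files: Mapping[str, str]
    solver: SolverConfig = field(default_factory=SolverConfig)
    out_dir: str = "."
    master_seed: int = 0
    top_k: int = 10


def run_study(config: StudyConfig) -> dict[str, dict]:
    """Solve every model in the study and write one solution file each."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_names = list(config.constraint_files)
    seeds = np.random.SeedSequence(config.master_seed).generate_state(len(model_names))
    results = {}
    n_targets_seen = set()
    for name, seed in zip(model_names, seeds):
        path = config.constraint_files[name]
        system = read_constraints(path)
        n_targets_seen.add(system.n_targets)
        if len(n_targets_seen) > 1:
            raise ConstraintFileError("constraint files disagree on n_targets")
        cfg = replace(config.solver, seed=int(seed) % (2**31))
        trials = run_trials(system, cfg)
        agg = aggregate_trials(trials, top_k=min(config.top_k, cfg.trials))
        payload = write_solution(
            agg,
            trials,
            cfg,
            out_dir / f"{name}.solution.json",
            extra_metadata={
                "model": name,
                "constraints_file": str(path),
                "constraints_sha256": _file_sha256(path),
                "master_seed": config.master_seed,
                "n_constraints": system.n_constraints,
                "n_unknowns": system.n_unknowns,
            },
        )
        results[name] = payload
    return results
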