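"""Hyperparameter search over the NEAT configuration space.

The search space covers eleven evolutionary hyperparameters with closed
intervals (survivor fraction, speciation threshold, mutation-vs-crossover
probability, weight/structural mutation rates and the three compatibility
coefficients).  Trials run sequentially through a pluggable sampler: the
built-in fallback samples uniformly at random; a Tree-structured Parzen
Estimator sampler is available as a thin adapter when optuna is installed.

``near_best_counts`` summarizes how robust the landscape is: how many trials
landed within 95% of the best objective, and how many cleared an absolute
threshold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .neat import CompatibilityParams, EvolutionConfig

log = logging.getLogger(__name__)

# (config attribute, interval) for every searched hyperparameter
DEFAULT_INTERVALS: dict[str, tuple[float, float]] = {
    "keep_fraction": (0.40, 0.60),
    "compat_threshold": (2.0, 4.0),
    "fresh_mutation_prob": (0.15, 0.35),
    "weight_mut_prob": (0.70, 0.90),
    "add_node_small": (0.02, 0.04),
    "add_conn_small": (0.01, 0.05),
    "add_node_large": (0.02, 0.04),
    "add_conn_large": (0.01, 0.05),
    "c1": (0.5, 1.5),
    "c2": (0.5, 1.5),
    "c3": (0.3, 0.5),
}


@dataclass
class SearchSpace:
    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTERVALS))

    def __post_init__(self):
        for name, (lo, hi) in self.intervals.items():
            if not lo < hi:
                raise ValueError(f"empty interval for {name}")

    def contains(self, values: dict[str, float]) -> bool:
        return all(self.intervals[k][0] <= v <= self.intervals[k][1]
                   for k, v in values.items())


@dataclass
class TrialRecord:
    trial_id: int
    values: dict[str, float]
    config: EvolutionConfig
    objective: float | None
    seed: int
    status: str = "completed"   # completed | failed


def values_to_config(values: dict[str, float],
                     base: EvolutionConfig | None = None) -> EvolutionConfig:
    """Materialize sampled hyperparameter values into an EvolutionConfig
    (non-searched fields come from ``base``)."""
    base = base or EvolutionConfig()
    kwargs = {f.name: getattr(base, f.name)
              for f in dc_fields(EvolutionConfig)}
    compat = CompatibilityParams(c1=values.get("c1", base.compat.c1),
                                 c2=values.get("c2", base.compat.c2),
                                 c3=values.get("c3", base.compat.c3))
    for k, v in values.items():
        if k in ("c1", "c2", "c3"):
            continue
        kwargs[k] = v
    kwargs["compat"] = compat
    return EvolutionConfig(**kwargs)


def midpoint_config(space: SearchSpace | None = None,
                    base: EvolutionConfig | None = None) -> EvolutionConfig:
    """The interval midpoints of the search space as a config."""
    space = space or SearchSpace()
    mids = {k: (lo + hi) / 2.0 for k, (lo, hi) in space.intervals.items()}
    return values_to_config(mids, base)


def uniform_sampler(space: SearchSpace, rng: np.random.Generator,
                    history: list[TrialRecord]) -> dict[str, float]:
    """Fallback sampler: independent uniform draws per interval."""
    return {k: float(rng.uniform(lo, hi))
            for k, (lo, hi) in space.intervals.items()}


def tpe_sampler(seed: int = 0):
    """Adapter returning a sampler backed by optuna's Tree-structured Parzen
    Estimator.  Requires optuna; raises ImportError otherwise."""
    import optuna  # optional dependency, adapter only

    optuna.logging.set_verbosity(optuna.logging.WARNING)
    study = optuna.create_study(
        direction="maximize",
        sampler=optuna.samplers.TPESampler(seed=seed))
    pending = {}

    def sampler(space: SearchSpace, rng, history):
        trial = study.ask()
        values = {k: trial.suggest_float(k, lo, hi)
                  for k, (lo, hi) in space.intervals.items()}
        pending[len(history)] = trial
        if history:
            last = history[-1]
            t = pending.pop(last.trial_id, None)
            if t is not None and last.objective is not None:
                study.tell(t, last.objective)
        return values

    return sampler


def sample_config(space: SearchSpace, rng: np.random.Generator,
                  sampler=None, history: list[TrialRecord] | None = None,
                  base: EvolutionConfig | None = None
                  ) -> tuple[EvolutionConfig, dict[str, float]]:
    sampler = sampler or uniform_sampler
    values = sampler(space, rng, history or [])
    if not space.contains(values):
        raise ValueError("sampler produced out-of-range values")
    return values_to_config(values, base), values


def run_search(objective, space: SearchSpace | None = None,
               n_trials: int = 100, sampler=None, seed: int = 0,
               base: EvolutionConfig | None = None
               ) -> tuple[list[TrialRecord], EvolutionConfig]:
    """Sequentially sample ``n_trials`` configurations and evaluate
    ``objective(config, trial_seed) -> float`` on each.  Returns all trial
    records and the best configuration (ties -> earliest trial); failed
    objectives mark their trial failed and the search continues."""
    space = space or SearchSpace()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    records: list[TrialRecord] = []
    for t in range(n_trials):
        cfg, values = sample_config(space, rng, sampler, records, base)
        trial_seed = int(np.random.SeedSequence([seed, t])
                         .generate_state(1)[0] % (2 ** 31))
        try:
            score = float(objective(cfg, trial_seed))
            records.append(TrialRecord(t, values, cfg, score, trial_seed))
        except Exception:  # noqa: BLE001 - a failed trial must not kill the search
            log.exception("trial %d failed", t)
            records.append(TrialRecord(t, values, cfg, None, trial_seed,
                                       status="failed"))
    completed = [r for r in records if r.status == "completed"]
    if not completed:
        raise RuntimeError("every trial failed")
    best = max(completed, key=lambda r: (r.objective, -r.trial_id))
    return records, best.config


def replicate_best(config: EvolutionConfig, objective_full, n_runs: int = 31,
                   seed: int = 0) -> dict:
    """Re-run the selected configuration ``n_runs`` times with independent
    seeds; returns per-run values with their mean and standard deviation."""
    values = np.empty(n_runs)
    for r in range(n_runs):
        run_seed = int(np.random.SeedSequence([seed, 1000 + r])
                       .generate_state(1)[0] % (2 ** 31))
        values[r] = float(objective_full(config, run_seed))
    return {"values": values, "mean": float(values.mean()),
            "std": float(values.std(ddof=1)) if n_runs > 1 else 0.0,
            "n_runs": n_runs}


def near_best_counts(objectives, absolute_threshold: float | None = None,
                     worst_possible: float | None = None
                     ) -> tuple[int, int | None]:
    """(number of trials within 95% of the best objective, number strictly
    above ``absolute_threshold``).

    For tasks whose returns are negative (e.g. time-penalty control tasks)
    the 95% ratio is taken after shifting by ``worst_possible`` so it acts
    on a non-negative scale.
    """
    objs = np.asarray([o.objective if isinstance(o, TrialRecord) else o
                       for o in objectives], dtype=np.float64)
    objs = objs[np.isfinite(objs)]
    if objs.size == 0:
        raise ValueError("need at least one completed trial")
    shifted = objs.copy()
    if worst_possible is not None:
        shifted = shifted - worst_possible
        if np.any(shifted < 0):
            raise ValueError("objective below the stated worst_possible")
    elif shifted.max() <= 0:
        raise ValueError(
            "non-positive objectives: pass worst_possible to define the "
            "95% scale")
    n95 = int(np.sum(shifted >= 0.95 * shifted.max()))
    n_above = None
    if absolute_threshold is not None:
        n_above = int(np.sum(objs > absolute_threshold))
    return n95, n_above


def write_trial_ledger(records: list[TrialRecord], path) -> None:
    """CSV ledger: trial id, all sampled hyperparameters, objective, seed,
    status."""
    names = list(DEFAULT_INTERVALS)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", *names, "objective", "seed", "status"])
        for r in records:
            w.writerow([r.trial_id,
                        *[r.values.get(n, "") for n in names],
                        "" if r.objective is None else r.objective,
                        r.seed, r.status])
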