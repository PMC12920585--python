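"""Reference study protocols: evolve, select, and evaluate on the bundled
benchmarks.

Each protocol evolves a population of 50 spiking networks for up to 50
generations with interval-midpoint hyperparameters, then selects the final
"best network" by re-evaluating the top candidates of the last population
on a fresh validation batch (the desk-scale stand-in for selection under a
full 100-episode fitness), and finally reports its performance on held-out
evaluation episodes.  All randomness derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codecs import ClsCodecSpec, rl_codec
from .envs import make_reference_env
from .fixtures import SyntheticDatasetSpec, make_blobs
from .genome import Genome
from .hpo import midpoint_config
from .neat import EvolutionResult, evolve
from .tasks import (_episode_seed, evaluate_cls, evaluate_rl,
                    make_cls_objective, make_rl_objective)


@dataclass
class RLBenchmarkReport:
    best: Genome
    evolution: EvolutionResult
    validation_mean: float
    eval_mean: float
    eval_returns: np.ndarray
    best_episode_return: float


def _select_by_validation(result: EvolutionResult, env, codec, model, bank,
                          seed: int, top_k: int = 10,
                          validation_episodes: int = 30) -> tuple[Genome, float]:
    """Re-evaluate the top candidates of the final population on a fresh
    validation batch and return the winner (falls back to the best-ever
    genome if it beats the population)."""
    ranked = sorted(result.population,
                    key=lambda g: (-(g.fitness if g.fitness is not None
                                     else -np.inf), g.key))
    candidates = ranked[:top_k] + [result.best]
    best_g, best_v = None, -np.inf
    for g in candidates:
        v = evaluate_rl(g, env, codec, model=model,
                        episodes=validation_episodes,
                        seed=_episode_seed(seed, 0x5E1),
                        bank=bank).mean
        if v > best_v:
            best_g, best_v = g, v
    return best_g, best_v


def run_rl_benchmark(env_name: str, scheme: str, model: str, seed: int,
                     generations: int = 50, population: int = 50,
                     fitness_episodes: int = 10, eval_episodes: int = 50,
                     top_k: int = 10, validation_episodes: int = 30,
                     fitness_goal: float | None = None) -> RLBenchmarkReport:
    """Evolve on a bundled control task and report held-out performance."""
    env = make_reference_env(env_name)
    codec = rl_codec(scheme, model)
    cfg = midpoint_config()
    cfg.population_size = population
    cfg.generations = generations
    objective = make_rl_objective(env, codec, model, fitness_episodes, seed)
    n_in = codec.n_input_neurons(env.observation_dim)
    n_out = codec.n_output_neurons(env.n_actions)
    result = evolve(objective, n_in, n_out, cfg, seed=seed,
                    fitness_goal=fitness_goal)
    best, val = _select_by_validation(result, env, codec, model,
                                      objective.bank, seed, top_k,
                                      validation_episodes)
    report = evaluate_rl(best, env, codec, model=model,
                         episodes=eval_episodes,
                         seed=_episode_seed(seed, 0xE7A),
                         bank=objective.bank)
    return RLBenchmarkReport(best=best, evolution=result,
                             validation_mean=val, eval_mean=report.mean,
                             eval_returns=report.values,
                             best_episode_return=float(report.values.max()))


def cartpole_small_izhikevich(seed: int, generations: int = 50
                              ) -> RLBenchmarkReport:
    """Pole balancing with the sign-split two-neurons-per-feature encoding
    and Izhikevich neurons — the configuration that reaches the 500-step
    ceiling."""
    return run_rl_benchmark("cartpole", "small", "izhikevich", seed,
                            generations=generations)


def mountain_car_large_single_lif(seed: int, generations: int = 20
                                  ) -> RLBenchmarkReport:
    """Mountain Car with the 20-neurons-per-feature single-spike encoding
    and LIF neurons: a single input spike through a unit-scale synapse
    cannot fire a LIF neuron, so evolved agents stay at the -200 failure
    floor."""
    return run_rl_benchmark("mountain_car", "large_single", "lif", seed,
                            generations=generations)


@dataclass
class ClsBenchmarkReport:
    best: Genome
    evolution: EvolutionResult
    fitness: float
    eval_accuracy: float


def blobs_temporal_voting_izhikevich(seed: int, generations: int = 50,
                                     fitness_goal: float | None = None
                                     ) -> ClsBenchmarkReport:
    """Synthetic 3-class / 4-feature Gaussian-cluster classification
    (separation 3 sigma) with latency-coded inputs, voting outputs and
    Izhikevich neurons."""
    data = make_blobs(SyntheticDatasetSpec(n_classes=3, n_features=4,
                                           separation=3.0, noise=1.0,
                                           n_rows=150, seed=0))
    codec = ClsCodecSpec(input_scheme="temporal", output_scheme="voting")
    cfg = midpoint_config()
    cfg.population_size = 50
    cfg.generations = generations
    objective = make_cls_objective(data, codec, "izhikevich", subsets=50,
                                   subset_size=50, run_seed=seed)
    result = evolve(objective, codec.n_input_neurons(data.n_features),
                    data.n_classes, cfg, seed=seed,
                    fitness_goal=fitness_goal)
    report = evaluate_cls(result.best, data, codec, model="izhikevich",
                          subsets=50, subset_size=50,
                          seed=_episode_seed(seed, 0xE7A))
    return ClsBenchmarkReport(best=result.best, evolution=result,
                              fitness=result.best_fitness,
                              eval_accuracy=report.mean)
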