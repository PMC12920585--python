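"""Synthetic data, toy genomes, and a scripted environment with a known
optimum.

These generators are first-class package surface, not test scaffolding:
``make_blobs`` produces an Iris-scale Gaussian-cluster classification table
(3 classes x 4 features x 150 rows by default) already normalized to
[0, 1]; ``make_toy_genomes`` builds canonical small genomes with
hand-assigned innovation numbers; ``ScriptedEnv`` is a deterministic
one-feature sign-following task whose optimal return equals its step limit
and is achievable by a minimal 2-input / 2-output network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.datasets import make_blobs as _sk_make_blobs

from .genome import (ConnectionGene, Genome, InnovationRegistry, NodeGene,
                     ROLE_HIDDEN, ROLE_INPUT, ROLE_OUTPUT)
from .tasks import DatasetTable, normalize


@dataclass
class SyntheticDatasetSpec:
    n_classes: int = 3
    n_features: int = 4
    separation: float = 3.0   # center spacing in units of the noise sigma
    noise: float = 1.0        # within-class Gaussian sigma
    n_rows: int = 150
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.n_features, self.n_rows) < 1:
            raise ValueError("counts must be positive")
        if self.n_rows % self.n_classes:
            raise ValueError("n_rows must divide evenly across classes")


def make_blobs(spec: SyntheticDatasetSpec) -> DatasetTable:
    """Balanced Gaussian class clusters at axis-aligned centers spaced
    ``separation * noise`` apart, min-max normalized to [0, 1]."""
    centers = np.zeros((spec.n_classes, spec.n_features))
    for c in range(spec.n_classes):
        centers[c, c % spec.n_features] = spec.separation * spec.noise
    per_class = spec.n_rows // spec.n_classes
    X, y = _sk_make_blobs(n_samples=[per_class] * spec.n_classes,
                          centers=centers, cluster_std=spec.noise,
                          random_state=spec.seed % (2 ** 32), shuffle=True)
    return normalize(DatasetTable(features=X, labels=y))


def make_toy_genomes(kind: str):
    """Canonical hand-built genomes used throughout the test suite.

    ``minimal``        2-in / 2-out fully connected (4 nodes, 4 connections,
                       innovations 0-3, weights 0.5).
    ``split``          the minimal genome after splitting connection 0
                       (5 nodes, 6 connections, 1 disabled).
    ``disjoint_pair``  two genomes with innovation sets {1,2,3} and
                       {1,2,4,5}; matching weights differ by 0.5, giving
                       E = 2 excess and D = 1 disjoint genes.
    """
    if kind == "minimal":
        nodes = [NodeGene(0, ROLE_INPUT), NodeGene(1, ROLE_INPUT),
                 NodeGene(2, ROLE_OUTPUT), NodeGene(3, ROLE_OUTPUT)]
        conns = [ConnectionGene(0, 0, 2, 0.5), ConnectionGene(1, 0, 3, 0.5),
                 ConnectionGene(2, 1, 2, 0.5), ConnectionGene(3, 1, 3, 0.5)]
        return Genome(nodes=nodes, connections=conns)
    if kind == "split":
        g = make_toy_genomes("minimal")
        g.connections[0].enabled = False
        g.nodes.append(NodeGene(4, ROLE_HIDDEN))
        g.connections.append(ConnectionGene(4, 0, 4, 1.0))
        g.connections.append(ConnectionGene(5, 4, 2, 0.5))
        return g
    if kind == "disjoint_pair":
        nodes = [NodeGene(0, ROLE_INPUT), NodeGene(1, ROLE_OUTPUT),
                 NodeGene(2, ROLE_HIDDEN)]
        g1 = Genome(nodes=list(nodes), connections=[
            ConnectionGene(1, 0, 1, 1.0),
            ConnectionGene(2, 0, 2, 1.0),
            ConnectionGene(3, 2, 1, 1.0),
        ])
        g2 = Genome(nodes=list(nodes), connections=[
            ConnectionGene(1, 0, 1, 0.5),
            ConnectionGene(2, 0, 2, 1.5),
            ConnectionGene(4, 2, 2, 1.0),
            ConnectionGene(5, 1, 2, 1.0),
        ])
        return g1, g2
    raise ValueError(f"unknown toy-genome kind {kind!r}")


@dataclass
class ScriptedEnvSpec:
    step_limit: int = 20
    seed: int = 0


class ScriptedEnv:
    """Sign-following task: the observation is a single value in {-1, +1};
    action 0 is correct for negative observations, action 1 for positive,
    each correct step earns +1.  The optimal return is ``step_limit``."""

    observation_dim = 1
    n_actions = 2
    observation_ranges = np.array([[-1.0, 1.0]])
    observation_scales = np.array([1.0])

    def __init__(self, step_limit: int = 20):
        self.step_limit = step_limit
        self._rng = None
        self._obs = None
        self._steps = 0

    def reset(self, seed: int | None = None) -> np.ndarray:
        ss = np.random.SeedSequence(seed) if seed is not None \
            else np.random.SeedSequence()
        self._rng = np.random.Generator(np.random.PCG64(ss))
        self._steps = 0
        self._obs = np.array([self._rng.choice([-1.0, 1.0])])
        return self._obs.copy()

    def step(self, action: int):
        if self._obs is None:
            raise RuntimeError("call reset() before step()")
        correct = 1 if self._obs[0] > 0 else 0
        reward = 1.0 if action == correct else 0.0
        self._steps += 1
        self._obs = np.array([self._rng.choice([-1.0, 1.0])])
        truncated = self._steps >= self.step_limit
        return self._obs.copy(), reward, False, truncated

    @staticmethod
    def optimal_policy(obs: np.ndarray) -> int:
        return 1 if obs[0] > 0 else 0

    def optimal_return(self) -> int:
        return self.step_limit


def scripted_optimum_by_search(step_limit: int = 6, seed: int = 0) -> float:
    """Best achievable return on the scripted env found by exhaustive search
    over all reactive policies (mappings observation sign -> action).
    Serves as an independent optimum oracle for small step limits."""
    best = -np.inf
    for a_neg in (0, 1):
        for a_pos in (0, 1):
            env = ScriptedEnv(step_limit=step_limit)
            obs = env.reset(seed=seed)
            total = 0.0
            while True:
                action = a_pos if obs[0] > 0 else a_neg
                obs, r, term, trunc = env.step(action)
                total += r
                if term or trunc:
                    break
            best = max(best, total)
    return best
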