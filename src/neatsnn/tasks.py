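"""Fitness evaluation for episodic control and classification.

Control fitness is the mean episode return over repeated episodes; every
environment step encodes the observation into a 50 ms spike window, runs the
network from rest, and decodes the action with the most output spikes.
Classification fitness is the mean accuracy over bootstrap subsets drawn
with replacement from the (min-max normalized) dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codecs import (ClsCodecSpec, IntervalBank, RLCodecSpec,
                     build_interval_bank, decode_action, decode_class,
                     encode_cls, encode_rl_large, encode_rl_small)
from .envs import EnvAdapter
from .genome import Genome
from .snn import build_network


@dataclass
class DatasetTable:
    features: np.ndarray              # (rows, F)
    labels: np.ndarray                # (rows,) integer classes
    feature_ranges: np.ndarray | None = None  # (F, 2) pre-normalization
    label_names: list[str] | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on row count")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_rows else 0


@dataclass
class FitnessReport:
    """Per-candidate evaluation result: the fitness (mean over episodes or
    subsets), the individual values, and the seed that reproduces them."""
    mean: float
    values: np.ndarray
    n_evaluations: int
    seed: int

    @property
    def std(self) -> float:
        return float(np.std(self.values, ddof=1)) \
            if len(self.values) > 1 else 0.0


def normalize(data: DatasetTable) -> DatasetTable:
    """Min-max normalize every feature to [0, 1] (constant features map to
    0); the original ranges are stored for inverse mapping."""
    if data.n_rows < 1:
        raise ValueError("empty dataset")
    lo = data.features.min(axis=0)
    hi = data.features.max(axis=0)
    span = hi - lo
    out = np.zeros_like(data.features)
    nz = span > 0
    out[:, nz] = (data.features[:, nz] - lo[nz]) / span[nz]
    return DatasetTable(features=out, labels=data.labels,
                        feature_ranges=np.column_stack([lo, hi]),
                        label_names=data.label_names)


def load_dataset(path: str | Path, label_column: str,
                 delimiter: str = ",") -> DatasetTable:
    """Read a delimited text table with a header row; every non-label column
    must be numeric.  String labels are mapped to integer classes in sorted
    order."""
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in header")
    feats = df.drop(columns=[label_column])
    bad = [c for c in feats.columns
           if not np.issubdtype(feats[c].dtype, np.number)]
    if bad:
        rows = feats[bad[0]].map(
            lambda v: not isinstance(v, (int, float, np.number)))
        raise ValueError(
            f"non-numeric cells in column {bad[0]!r} "
            f"(first bad row index: {int(np.argmax(rows.values))})")
    names = sorted(df[label_column].astype(str).unique())
    mapping = {name: i for i, name in enumerate(names)}
    labels = df[label_column].astype(str).map(mapping).to_numpy()
    return DatasetTable(features=feats.to_numpy(dtype=np.float64),
                        labels=labels, label_names=names)


def _episode_seed(*parts: int) -> int:
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def default_bank(env: EnvAdapter, seed: int = 0, n: int = 20) -> IntervalBank:
    return build_interval_bank(env.observation_ranges, n=n, seed=seed)


def evaluate_rl(genome: Genome, env: EnvAdapter, codec: RLCodecSpec,
                model: str = "izhikevich", episodes: int = 100,
                seed: int = 0, bank: IntervalBank | None = None,
                scales: np.ndarray | None = None, dt: float = 1.0,
                params=None, episode_seeds: list[int] | None = None
                ) -> FitnessReport:
    """Mean episode return of a genome on an episodic environment.

    Each environment step: encode the observation, simulate one decision
    window from rest, pick the action whose output group spiked most.
    Episode seeds are derived deterministically from ``seed`` unless given
    explicitly.
    """
    n_in = codec.n_input_neurons(env.observation_dim)
    n_out = codec.n_output_neurons(env.n_actions)
    if len(genome.input_ids) != n_in or len(genome.output_ids) != n_out:
        raise ValueError(
            f"genome has {len(genome.input_ids)} inputs / "
            f"{len(genome.output_ids)} outputs; codec needs "
            f"{n_in} / {n_out}")
    if codec.scheme in ("large_single", "large_multi") and bank is None:
        bank = default_bank(env, seed=0, n=codec.neurons_per_feature)
    if codec.scheme == "small" and scales is None:
        scales = getattr(env, "observation_scales", None)

    net = build_network(genome, model=model, dt=dt, params=params)
    out_lo, out_hi = net.output_slice.start, net.output_slice.stop
    I_full = np.zeros(net.n, dtype=np.float64)
    if episode_seeds is None:
        episode_seeds = [_episode_seed(seed, ep) for ep in range(episodes)]
    returns = np.empty(len(episode_seeds))
    for ep, ep_seed in enumerate(episode_seeds):
        obs = env.reset(seed=ep_seed)
        total = 0.0
        while True:
            if codec.scheme == "small":
                I_full[:n_in] = encode_rl_small(obs, codec, scales)
                counts, _ = net.run_window_counts(I_full,
                                                  window=codec.window)
            else:
                drive = encode_rl_large(obs, bank, codec)
                if drive.currents is not None:
                    I_full[:n_in] = drive.currents
                    counts, _ = net.run_window_counts(I_full,
                                                      window=codec.window)
                else:
                    fn = np.array([i for i, _ in drive.spikes],
                                  dtype=np.int64)
                    fk = np.zeros(len(fn), dtype=np.int64)
                    I_full[:n_in] = 0.0
                    counts, _ = net.run_window_counts(
                        I_full, fn, fk, window=codec.window)
            action = decode_action(counts[out_lo:out_hi], env.n_actions,
                                   codec.outputs_per_action)
            obs, reward, terminated, truncated = env.step(action)
            total += reward
            if terminated or truncated:
                break
        returns[ep] = total
    return FitnessReport(mean=float(returns.mean()), values=returns,
                         n_evaluations=len(returns), seed=seed)


def predict_rows(genome: Genome, data: DatasetTable, codec: ClsCodecSpec,
                 model: str = "izhikevich", dt: float = 1.0, params=None
                 ) -> np.ndarray:
    """Deterministic per-row class predictions (-1 where the network stayed
    silent).  The network is reset to rest before every sample, so each
    row's prediction is independent of presentation order."""
    n_in = codec.n_input_neurons(data.n_features)
    n_out = data.n_classes
    if len(genome.input_ids) != n_in or len(genome.output_ids) != n_out:
        raise ValueError(
            f"genome has {len(genome.input_ids)} inputs / "
            f"{len(genome.output_ids)} outputs; codec needs "
            f"{n_in} / {n_out}")
    net = build_network(genome, model=model, dt=dt, params=params)
    out_lo, out_hi = net.output_slice.start, net.output_slice.stop
    preds = np.empty(data.n_rows, dtype=np.int64)
    for r in range(data.n_rows):
        spikes = encode_cls(data.features[r], codec)
        fn = np.array([i for i, _ in spikes], dtype=np.int64)
        fk = np.array([int(round(t / dt)) for _, t in spikes],
                      dtype=np.int64)
        counts, first = net.run_window_counts(None, fn, fk,
                                              window=codec.window)
        first_t = first[out_lo:out_hi].astype(np.float64) * dt
        first_t[first[out_lo:out_hi] < 0] = -1.0
        pred = decode_class(counts[out_lo:out_hi], first_t, codec, n_out)
        preds[r] = -1 if pred is None else pred
    return preds


def evaluate_cls(genome: Genome, data: DatasetTable, codec: ClsCodecSpec,
                 model: str = "izhikevich", subsets: int = 50,
                 subset_size: int = 50, seed: int = 0, dt: float = 1.0,
                 params=None) -> FitnessReport:
    """Bootstrap-subset classification fitness: draw ``subsets`` subsets of
    ``subset_size`` rows with replacement; fitness is the mean per-subset
    accuracy.  A silent network (no prediction) scores a miss."""
    if data.n_rows < 1:
        raise ValueError("empty dataset")
    lo = data.features.min()
    hi = data.features.max()
    if lo < 0.0 or hi > 1.0:
        raise ValueError("dataset must be normalized to [0, 1] first")
    preds = predict_rows(genome, data, codec, model=model, dt=dt,
                         params=params)
    correct = preds == data.labels
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    acc = np.empty(subsets)
    for s in range(subsets):
        idx = rng.integers(0, data.n_rows, size=subset_size)
        acc[s] = correct[idx].mean()
    return FitnessReport(mean=float(acc.mean()), values=acc,
                         n_evaluations=subsets, seed=seed)


# ---------------------------------------------------------------------------
# objective builders for the evolutionary loop
# ---------------------------------------------------------------------------

def make_rl_objective(env: EnvAdapter, codec: RLCodecSpec, model: str,
                      episodes: int, run_seed: int,
                      bank: IntervalBank | None = None, dt: float = 1.0,
                      params=None, common_random_numbers: bool = False):
    """Fitness callback for :func:`neatsnn.neat.evolve`.  Episode i of
    candidate c in generation g is seeded from (run_seed, g, c, i), so runs
    replay exactly; with ``common_random_numbers`` the candidate index is
    dropped and all candidates of a generation share episode seeds."""
    if codec.scheme in ("large_single", "large_multi") and bank is None:
        bank = default_bank(env, seed=run_seed,
                            n=codec.neurons_per_feature)

    def objective(genome: Genome, gen: int, idx: int) -> float:
        cand = 0 if common_random_numbers else idx
        seeds = [_episode_seed(run_seed, gen, cand, i)
                 for i in range(episodes)]
        report = evaluate_rl(genome, env, codec, model=model, seed=run_seed,
                             bank=bank, dt=dt, params=params,
                             episode_seeds=seeds)
        return report.mean

    objective.bank = bank
    return objective


def make_cls_objective(data: DatasetTable, codec: ClsCodecSpec, model: str,
                       subsets: int, subset_size: int, run_seed: int,
                       dt: float = 1.0, params=None):
    """Classification fitness callback.  The bootstrap subsets are drawn
    once per run and shared by every candidate in every generation, so a
    candidate's fitness is deterministic and comparisons across candidates
    are exact."""
    subset_seed = _episode_seed(run_seed, 0xC15)

    def objective(genome: Genome, gen: int, idx: int) -> float:
        report = evaluate_cls(genome, data, codec, model=model,
                              subsets=subsets, subset_size=subset_size,
                              seed=subset_seed, dt=dt, params=params)
        return report.mean

    return objective
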