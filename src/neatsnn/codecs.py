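"""Spike encoders and decoders for control and classification tasks.

Reinforcement-learning input schemes
------------------------------------
``small``        two neurons per state feature (one for positive, one for
                 negative values); the relevant neuron receives a constant
                 current proportional to the feature magnitude.  One output
                 neuron per action.
``large_single`` 20 neurons per feature, each tuned to an interval of the
                 feature's range with Gaussian-sampled centers; the matching
                 neuron(s) emit a single spike at t = 0.  10 output neurons
                 per action.
``large_multi``  same interval bank, but matching neurons receive a constant
                 injected current for the whole window (75 for LIF, 20 for
                 Izhikevich), producing sustained firing.

Actions are decoded by spike count: the action whose output group fired the
most within the 50 ms decision window wins (ties and the all-silent case
resolve to the lowest action index).

Classification schemes
----------------------
``bins5``     each feature's [0, 1] range is split into five equal intervals,
              one input neuron each; the matching neuron spikes once at t=0.
``temporal``  one input neuron per feature; the value maps affinely to a
              spike latency in [0, t_max] (larger values spike later).
Outputs: ``voting`` (most spikes wins) or ``first_spike`` (earliest output
spike wins; a silent network predicts nothing and is scored incorrect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .snn import WindowDrive

RL_SCHEMES = ("small", "large_single", "large_multi")
INJECT_CURRENT = {"lif": 75.0, "izhikevich": 20.0}


@dataclass
class RLCodecSpec:
    scheme: str
    neurons_per_feature: int
    outputs_per_action: int
    window: float = 50.0
    gain: float = 40.0            # small scheme: current per unit feature
    inject_current: float | None = None  # large_multi: model-dependent

    def __post_init__(self):
        if self.scheme not in RL_SCHEMES:
            raise ValueError(f"unknown RL scheme {self.scheme!r}")

    def n_input_neurons(self, n_features: int) -> int:
        return self.neurons_per_feature * n_features

    def n_output_neurons(self, n_actions: int) -> int:
        return self.outputs_per_action * n_actions


def rl_codec(scheme: str, model: str = "izhikevich", window: float = 50.0,
             gain: float = 40.0) -> RLCodecSpec:
    """Build the codec spec a scheme implies: the small scheme uses 2 neurons
    per feature and 1 output per action; both large schemes use 20 neurons
    per feature and 10 outputs per action."""
    if scheme == "small":
        return RLCodecSpec(scheme, 2, 1, window=window, gain=gain)
    if scheme == "large_single":
        return RLCodecSpec(scheme, 20, 10, window=window)
    if scheme == "large_multi":
        return RLCodecSpec(scheme, 20, 10, window=window,
                           inject_current=INJECT_CURRENT[model])
    raise ValueError(f"unknown RL scheme {scheme!r}")


def encode_rl_small(state: np.ndarray, spec: RLCodecSpec,
                    scales: np.ndarray | None = None) -> np.ndarray:
    """Sign-split rate coding: feature x_i drives its positive neuron with
    gain*max(x_i, 0) and its negative neuron with gain*max(-x_i, 0).
    ``scales`` optionally normalizes each feature by a characteristic
    magnitude before the gain is applied.  Returns currents of length 2F
    ordered (pos_0, neg_0, pos_1, neg_1, ...)."""
    if spec.scheme != "small":
        raise ValueError("encode_rl_small requires the small scheme")
    x = np.asarray(state, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    if scales is not None:
        x = x / np.asarray(scales, dtype=np.float64)
    currents = np.zeros(2 * x.shape[0], dtype=np.float64)
    currents[0::2] = spec.gain * np.maximum(x, 0.0)
    currents[1::2] = spec.gain * np.maximum(-x, 0.0)
    return currents


@dataclass
class IntervalBank:
    """Per-feature interval tuning: ``centers[f]`` holds the sorted Gaussian
    -sampled interval centers for feature f; ``half_widths[f]`` is half the
    mean gap between adjacent centers.  A value matches every neuron whose
    center lies within its half-width (overlapping intervals may both
    fire)."""
    centers: np.ndarray      # (F, n) sorted along axis 1
    half_widths: np.ndarray  # (F,)
    seed: int
    mean: np.ndarray         # (F,)
    sigma: np.ndarray        # (F,)

    @property
    def n_features(self) -> int:
        return self.centers.shape[0]

    @property
    def neurons_per_feature(self) -> int:
        return self.centers.shape[1]

    def matches(self, feature: int, value: float) -> np.ndarray:
        """Indices (within the feature's neuron group) whose interval
        contains ``value``."""
        c = self.centers[feature]
        return np.flatnonzero(np.abs(c - value) <= self.half_widths[feature])

    def to_dict(self) -> dict:
        return {"schema_version": 1, "seed": self.seed,
                "centers": self.centers.tolist(),
                "half_widths": self.half_widths.tolist(),
                "mean": self.mean.tolist(), "sigma": self.sigma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalBank":
        return cls(centers=np.asarray(d["centers"], dtype=np.float64),
                   half_widths=np.asarray(d["half_widths"], dtype=np.float64),
                   seed=int(d["seed"]),
                   mean=np.asarray(d["mean"], dtype=np.float64),
                   sigma=np.asarray(d["sigma"], dtype=np.float64))


def build_interval_bank(feature_ranges: np.ndarray, n: int = 20,
                        seed: int = 0, mean: np.ndarray | None = None,
                        sigma: np.ndarray | None = None) -> IntervalBank:
    """Sample ``n`` interval centers per feature from a Gaussian (default:
    mean at the range midpoint, sigma = range/4), sorted ascending.  The
    half-width of every interval is half the mean gap between adjacent
    centers of its feature."""
    ranges = np.asarray(feature_ranges, dtype=np.float64)
    if ranges.ndim != 2 or ranges.shape[1] != 2:
        raise ValueError("feature_ranges must have shape (F, 2)")
    if not np.all(np.isfinite(ranges)):
        raise ValueError("feature ranges must be finite")
    widths = ranges[:, 1] - ranges[:, 0]
    if np.any(widths <= 0):
        raise ValueError("degenerate feature range (max <= min)")
    mu = ranges.mean(axis=1) if mean is None else np.asarray(mean, float)
    sd = widths / 4.0 if sigma is None else np.asarray(sigma, float)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    centers = np.sort(mu[:, None] + sd[:, None]
                      * rng.standard_normal((ranges.shape[0], n)), axis=1)
    gaps = np.diff(centers, axis=1).mean(axis=1)
    return IntervalBank(centers=centers, half_widths=gaps / 2.0, seed=seed,
                        mean=mu, sigma=sd)


def encode_rl_large(state: np.ndarray, bank: IntervalBank, spec: RLCodecSpec
                    ) -> WindowDrive:
    """Interval (population) coding over the bank.  ``large_single``: every
    matching neuron is scheduled one spike at t = 0.  ``large_multi``: every
    matching neuron receives the spec's injected current for the whole
    window.  A value matching no interval drives nothing for that
    feature."""
    x = np.asarray(state, dtype=np.float64)
    if x.shape[0] != bank.n_features:
        raise ValueError(
            f"state has {x.shape[0]} features, bank expects "
            f"{bank.n_features}")
    npf = bank.neurons_per_feature
    if spec.scheme == "large_single":
        spikes = [(f * npf + int(j), 0.0)
                  for f in range(bank.n_features)
                  for j in bank.matches(f, x[f])]
        return WindowDrive(currents=None, spikes=spikes)
    if spec.scheme == "large_multi":
        if spec.inject_current is None:
            raise ValueError("large_multi spec needs inject_current")
        currents = np.zeros(bank.n_features * npf, dtype=np.float64)
        for f in range(bank.n_features):
            currents[f * npf + bank.matches(f, x[f])] = spec.inject_current
        return WindowDrive(currents=currents, spikes=[])
    raise ValueError(f"encode_rl_large got scheme {spec.scheme!r}")


def decode_action(output_counts: np.ndarray, n_actions: int,
                  outputs_per_action: int) -> int:
    """Spike-count decoding: per-action counts are summed over each action's
    output group; argmax wins, ties and the all-zero case resolve to the
    lowest action index."""
    counts = np.asarray(output_counts)
    if counts.shape[0] != n_actions * outputs_per_action:
        raise ValueError(
            f"expected {n_actions * outputs_per_action} output counts, "
            f"got {counts.shape[0]}")
    per_action = counts.reshape(n_actions, outputs_per_action).sum(axis=1)
    return int(np.argmax(per_action))


# ---------------------------------------------------------------------------
# classification codecs
# ---------------------------------------------------------------------------

@dataclass
class ClsCodecSpec:
    input_scheme: str = "temporal"    # {bins5 | temporal}
    output_scheme: str = "voting"     # {voting | first_spike}
    n_bins: int = 5
    t_max: float = 40.0               # ms, latency-coding endpoint
    window: float = 50.0

    def __post_init__(self):
        if self.input_scheme not in ("bins5", "temporal"):
            raise ValueError(f"unknown input scheme {self.input_scheme!r}")
        if self.output_scheme not in ("voting", "first_spike"):
            raise ValueError(f"unknown output scheme {self.output_scheme!r}")
        if self.input_scheme == "bins5" and self.n_bins != 5:
            raise ValueError("bins5 coding uses exactly five intervals")
        if not 0.0 < self.t_max < self.window:
            raise ValueError("t_max must lie inside the window")

    def n_input_neurons(self, n_features: int) -> int:
        return (self.n_bins if self.input_scheme == "bins5" else 1) \
            * n_features


def encode_cls_bins(features: np.ndarray, n_bins: int = 5
                    ) -> list[tuple[int, float]]:
    """One-hot interval coding: each feature's [0, 1] range is split into
    ``n_bins`` equal intervals; the matching neuron spikes at t = 0 (values
    at 1.0 clamp into the last bin).  Returns (input index, time) pairs."""
    x = np.asarray(features, dtype=np.float64)
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise ValueError("features must be normalized to [0, 1]")
    bins = np.minimum((x * n_bins).astype(int), n_bins - 1)
    return [(int(f * n_bins + b), 0.0) for f, b in enumerate(bins)]


def encode_cls_temporal(features: np.ndarray, spec: ClsCodecSpec
                        ) -> list[tuple[int, float]]:
    """Latency coding: feature value v spikes its neuron at t = v * t_max,
    so larger values spike strictly later."""
    x = np.asarray(features, dtype=np.float64)
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise ValueError("features must be normalized to [0, 1]")
    # keep times strictly inside the window (v = 1 -> t_max < window)
    return [(f, float(v * spec.t_max)) for f, v in enumerate(x)]


def encode_cls(features: np.ndarray, spec: ClsCodecSpec
               ) -> list[tuple[int, float]]:
    if spec.input_scheme == "bins5":
        return encode_cls_bins(features, spec.n_bins)
    return encode_cls_temporal(features, spec)


def decode_class(output_counts: np.ndarray, first_spike_times: np.ndarray,
                 spec: ClsCodecSpec, n_classes: int) -> int | None:
    """Voting: class with most output spikes (ties -> lowest class).
    First-spike: class of the earliest output spike (simultaneous -> lowest
    neuron id); a network with no output spikes predicts None."""
    counts = np.asarray(output_counts)
    if counts.shape[0] != n_classes:
        raise ValueError(f"expected {n_classes} output counts")
    if spec.output_scheme == "voting":
        if counts.sum() == 0:
            return None
        return int(np.argmax(counts))
    first = np.asarray(first_spike_times, dtype=np.float64).copy()
    first[first < 0] = np.inf
    if not np.isfinite(first).any():
        return None
    return int(np.argmin(first))  # argmin ties break to lowest neuron id
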