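"""Clock-driven simulation of recurrent spiking networks.

Two neuron models are supported, both with a single conductance-like
synaptic variable ``g`` that jumps by the (signed) synaptic weight on every
presynaptic spike and decays exponentially toward zero between spikes:

* conductance-driven leaky integrate-and-fire (LIF),
      tau dv/dt = -v + g + I,
  integrated with the exact exponential update of the linear membrane
  equation (the drive g + I is held piecewise-constant over a step), spike
  when v >= v_thresh, reset to -65;

* the Izhikevich model (regular-spiking parameterization),
      dv/dt = 0.04 v^2 + 5 v + 140 - u + I + g,
      du/dt = a (b v - u),
  integrated with forward Euler; on a spike v resets to -65 and the
  recovery variable u is incremented by d = 8, producing spike-frequency
  adaptation.

Spikes emitted at step k are delivered to their targets at step k+1
(one-step synaptic delay), which makes the update independent of neuron
ordering within a step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome import Genome, GenomeError, ROLE_HIDDEN, ROLE_INPUT, ROLE_OUTPUT

MODEL_LIF = 0
MODEL_IZHIKEVICH = 1
_MODEL_CODES = {"lif": MODEL_LIF, "izhikevich": MODEL_IZHIKEVICH}


class SimulationError(RuntimeError):
    """Raised when a membrane state diverges (non-finite values)."""


@dataclass
class LIFParams:
    """Membrane time constant and thresholds of the LIF neuron.  The model
    has no explicit resting-potential term, so the subthreshold fixed point
    under zero drive is v = 0 while the post-spike reset sits at -65; both
    follow the model equations as given and are overridable here."""
    tau: float = 10.0        # ms
    v_thresh: float = 30.0
    v_reset: float = -65.0
    v_rest: float = 0.0      # initial membrane potential
    g_tau: float = 20.0      # ms, conductance decay

    def __post_init__(self):
        if self.tau <= 0 or self.g_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.v_thresh <= self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")


@dataclass
class IzhikevichParams:
    """Regular-spiking Izhikevich parameterization (a=0.02, b=0.2, c=-65,
    d=8) with a spike cutoff at v = 30."""
    a: float = 0.02
    b: float = 0.2
    v_reset: float = -65.0
    d: float = 8.0
    v_thresh: float = 30.0
    g_tau: float = 20.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("recovery rate a must be positive")
        if self.g_tau <= 0:
            raise ValueError("g_tau must be positive")

    @property
    def v_rest(self) -> float:
        # stable root of 0.04 v^2 + (5 - b) v + 140 = 0 (-70 for b = 0.2)
        disc = math.sqrt((5.0 - self.b) ** 2 - 4 * 0.04 * 140.0)
        return (-(5.0 - self.b) - disc) / (2 * 0.04)


@dataclass
class NeuronState:
    """Scalar state of one neuron, for single-neuron stepping and tests."""
    v: float = 0.0
    u: float = 0.0
    g: float = 0.0
    last_spike_time: float | None = None


@dataclass(frozen=True)
class SpikeRecord:
    neuron_id: int
    time: float  # ms within the window


def step_lif(s: NeuronState, p: LIFParams, I: float, dt: float
             ) -> tuple[NeuronState, bool]:
    """Advance one LIF neuron by dt (exact exponential membrane update);
    returns the new state and whether it spiked."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-dt / p.tau)
    v = s.v * decay + (1.0 - decay) * (s.g + I)
    if not math.isfinite(v):
        raise SimulationError(f"LIF membrane diverged (v={v})")
    spiked = v >= p.v_thresh
    if spiked:
        v = p.v_reset
    g = s.g * math.exp(-dt / p.g_tau)
    return NeuronState(v=v, u=s.u, g=g), spiked


def step_izhikevich(s: NeuronState, p: IzhikevichParams, I: float, dt: float
                    ) -> tuple[NeuronState, bool]:
    """Advance one Izhikevich neuron by dt (forward Euler)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = s.v + dt * (0.04 * s.v * s.v + 5.0 * s.v + 140.0 - s.u + I + s.g)
    u = s.u + dt * p.a * (p.b * s.v - s.u)
    if not (math.isfinite(v) and math.isfinite(u)):
        raise SimulationError(f"Izhikevich state diverged (v={v}, u={u})")
    spiked = v >= p.v_thresh
    if spiked:
        v = p.v_reset
        u = u + p.d
    g = s.g * math.exp(-dt / p.g_tau)
    return NeuronState(v=v, u=u, g=g), spiked


def deliver_spike(s: NeuronState, weight: float) -> NeuronState:
    """A presynaptic spike increments the conductance by the signed weight
    (negative weights act as effective inhibition)."""
    return NeuronState(v=s.v, u=s.u, g=s.g + weight,
                       last_spike_time=s.last_spike_time)


@dataclass
class WindowDrive:
    """External drive for one decision window: a constant current per input
    neuron plus optional scheduled (forced) spikes on input neurons,
    expressed in input-local indices."""
    currents: np.ndarray | None = None       # shape (n_inputs,)
    spikes: list[tuple[int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# compiled window kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simulate_window(model, n_steps, dt, v, u, g, pending,
                     syn_ptr, syn_idx, syn_w, I,
                     forced_n, forced_k,
                     lif_decay, izh_a, izh_b, izh_d,
                     v_thresh, v_reset, g_decay,
                     counts, first, last_k, rec_n, rec_k, record):
    n = v.shape[0]
    nrec = 0
    nf = forced_n.shape[0]
    for k in range(n_steps):
        for i in range(n):
            g[i] += pending[i]
            pending[i] = 0.0
        for i in range(n):
            if model == 0:
                v[i] = v[i] * lif_decay + (1.0 - lif_decay) * (g[i] + I[i])
            else:
                vi = v[i]
                v[i] = vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0
                                  - u[i] + I[i] + g[i])
                u[i] = u[i] + dt * izh_a * (izh_b * vi - u[i])
            if not np.isfinite(v[i]):
                return -(i + 1)  # divergence: offending neuron encoded
        for i in range(n):
            if v[i] >= v_thresh:
                v[i] = v_reset
                if model == 1:
                    u[i] += izh_d
                counts[i] += 1
                last_k[i] = k
                if first[i] < 0:
                    first[i] = k
                if record:
                    rec_n[nrec] = i
                    rec_k[nrec] = k
                nrec += 1
                for s in range(syn_ptr[i], syn_ptr[i + 1]):
                    pending[syn_idx[s]] += syn_w[s]
        for j in range(nf):
            if forced_k[j] == k:
                i = forced_n[j]
                if last_k[i] == k:
                    continue  # at most one spike per neuron per step
                v[i] = v_reset
                if model == 1:
                    u[i] += izh_d
                counts[i] += 1
                last_k[i] = k
                if first[i] < 0:
                    first[i] = k
                if record:
                    rec_n[nrec] = i
                    rec_k[nrec] = k
                nrec += 1
                for s in range(syn_ptr[i], syn_ptr[i + 1]):
                    pending[syn_idx[s]] += syn_w[s]
        for i in range(n):
            g[i] *= g_decay
    return nrec


class NetworkInstance:
    """A simulable network built 1:1 from a genome's enabled connections.

    Neuron ordering is deterministic: inputs (ascending node id), then
    outputs, then hidden nodes.  State arrays persist between windows when
    ``reset=False`` is passed to :meth:`run_window`.
    """

    def __init__(self, genome: Genome, model: str = "izhikevich",
                 dt: float = 1.0,
                 params: LIFParams | IzhikevichParams | None = None):
        if model not in _MODEL_CODES:
            raise ValueError(f"unknown neuron model {model!r}")
        genome.validate()
        self.genome = genome
        self.model = model
        self.model_code = _MODEL_CODES[model]
        self.dt = float(dt)
        if params is None:
            params = LIFParams() if model == "lif" else IzhikevichParams()
        self.params = params

        order = genome.input_ids + genome.output_ids + genome.hidden_ids
        self.node_order = order
        self.index_of = {nid: i for i, nid in enumerate(order)}
        self.n = len(order)
        self.n_inputs = len(genome.input_ids)
        self.n_outputs = len(genome.output_ids)
        self.input_slice = slice(0, self.n_inputs)
        self.output_slice = slice(self.n_inputs,
                                  self.n_inputs + self.n_outputs)

        # CSR adjacency over enabled connections
        out_lists: list[list[tuple[int, float]]] = [[] for _ in range(self.n)]
        for c in genome.enabled_connections():
            try:
                si, ti = self.index_of[c.source], self.index_of[c.target]
            except KeyError as e:  # pragma: no cover - validate() catches it
                raise GenomeError(
                    f"connection {c.innovation} references missing node {e}")
            out_lists[si].append((ti, c.weight))
        ptr = np.zeros(self.n + 1, dtype=np.int64)
        for i, lst in enumerate(out_lists):
            ptr[i + 1] = ptr[i] + len(lst)
        self.syn_ptr = ptr
        self.syn_idx = np.array(
            [t for lst in out_lists for t, _ in lst], dtype=np.int64)
        self.syn_w = np.array(
            [w for lst in out_lists for _, w in lst], dtype=np.float64)

        self.v = np.empty(self.n, dtype=np.float64)
        self.u = np.zeros(self.n, dtype=np.float64)
        self.g = np.zeros(self.n, dtype=np.float64)
        self._pending = np.zeros(self.n, dtype=np.float64)
        self._counts = np.zeros(self.n, dtype=np.int64)
        self._first = np.empty(self.n, dtype=np.int64)
        self._last_k = np.empty(self.n, dtype=np.int64)
        self._empty_i64 = np.empty(0, dtype=np.int64)
        self.reset_state()

    # -- state --------------------------------------------------------------
    def reset_state(self) -> None:
        """Return every neuron to the model's rest configuration."""
        if self.model_code == MODEL_LIF:
            self.v[:] = self.params.v_rest
            self.u[:] = 0.0
        else:
            vr = self.params.v_rest
            self.v[:] = vr
            self.u[:] = self.params.b * vr
        self.g[:] = 0.0
        self._pending[:] = 0.0

    def state_dict(self) -> dict:
        return {"v": self.v.tolist(), "u": self.u.tolist(),
                "g": self.g.tolist()}

    # -- simulation ---------------------------------------------------------
    def _kernel_args(self):
        p = self.params
        lif_decay = math.exp(-self.dt / p.tau) if self.model_code == 0 else 0.0
        izh_a = getattr(p, "a", 0.0)
        izh_b = getattr(p, "b", 0.0)
        izh_d = getattr(p, "d", 0.0)
        g_decay = math.exp(-self.dt / p.g_tau)
        return lif_decay, izh_a, izh_b, izh_d, p.v_thresh, p.v_reset, g_decay

    def run_window_counts(self, currents: np.ndarray | None = None,
                          forced_n: np.ndarray | None = None,
                          forced_k: np.ndarray | None = None,
                          window: float = 50.0, reset: bool = True
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Fast path: advance the network ``window`` ms and return
        (per-neuron spike counts, per-neuron first-spike step; -1 if none).
        ``currents`` is a full-length per-neuron current vector; forced
        spikes are given as network indices + step numbers."""
        n_steps = int(round(window / self.dt))
        if abs(n_steps * self.dt - window) > 1e-9:
            raise ValueError("window must be a multiple of dt")
        if reset:
            self.reset_state()
        I = currents if currents is not None \
            else np.zeros(self.n, dtype=np.float64)
        fn = forced_n if forced_n is not None else self._empty_i64
        fk = forced_k if forced_k is not None else self._empty_i64
        self._counts[:] = 0
        self._first[:] = -1
        self._last_k[:] = -1
        args = self._kernel_args()
        status = _simulate_window(
            self.model_code, n_steps, self.dt, self.v, self.u, self.g,
            self._pending, self.syn_ptr, self.syn_idx, self.syn_w, I,
            fn, fk, *args, self._counts, self._first, self._last_k,
            self._empty_i64, self._empty_i64, False)
        if status < 0:
            nid = self.node_order[-status - 1]
            raise SimulationError(
                f"membrane potential diverged at neuron {nid} "
                f"(model={self.model}, dt={self.dt})")
        return self._counts, self._first

    def run_window(self, drive: WindowDrive | None = None,
                   window: float = 50.0, reset: bool = True
                   ) -> list[SpikeRecord]:
        """Advance the network ``window`` ms under ``drive`` and return all
        spike records (neuron id, time in ms).  Network state at the end of
        the window persists on the instance for optional reuse."""
        drive = drive or WindowDrive()
        n_steps = int(round(window / self.dt))
        if abs(n_steps * self.dt - window) > 1e-9:
            raise ValueError("window must be a multiple of dt")
        if reset:
            self.reset_state()
        I = np.zeros(self.n, dtype=np.float64)
        if drive.currents is not None:
            cur = np.asarray(drive.currents, dtype=np.float64)
            if cur.shape[0] != self.n_inputs:
                raise ValueError(
                    f"drive currents has length {cur.shape[0]}, "
                    f"expected n_inputs={self.n_inputs}")
            I[self.input_slice] = cur
        fn, fk = [], []
        for idx, t in drive.spikes:
            if not 0 <= idx < self.n_inputs:
                raise ValueError(
                    f"scheduled spike on index {idx}: only input neurons "
                    f"(0..{self.n_inputs - 1}) may be driven")
            if not 0.0 <= t < window:
                raise ValueError(f"spike time {t} outside [0, {window})")
            fn.append(idx)
            fk.append(int(round(t / self.dt)))
        fn = np.array(fn, dtype=np.int64)
        fk = np.array(fk, dtype=np.int64)
        self._counts[:] = 0
        self._first[:] = -1
        self._last_k[:] = -1
        cap = self.n * n_steps + len(fn)
        rec_n = np.empty(cap, dtype=np.int64)
        rec_k = np.empty(cap, dtype=np.int64)
        args = self._kernel_args()
        status = _simulate_window(
            self.model_code, n_steps, self.dt, self.v, self.u, self.g,
            self._pending, self.syn_ptr, self.syn_idx, self.syn_w, I,
            fn, fk, *args, self._counts, self._first, self._last_k,
            rec_n, rec_k, True)
        if status < 0:
            nid = self.node_order[-status - 1]
            raise SimulationError(
                f"membrane potential diverged at neuron {nid} "
                f"(model={self.model}, dt={self.dt})")
        recs = [SpikeRecord(self.node_order[rec_n[i]], rec_k[i] * self.dt)
                for i in range(status)]
        recs.sort(key=lambda r: (r.time, r.neuron_id))
        return recs


def build_network(genome: Genome, model: str = "izhikevich", dt: float = 1.0,
                  params=None) -> NetworkInstance:
    """Instantiate a simulable network from a genome: one neuron per node
    gene, one synapse per enabled connection gene, state at rest."""
    return NetworkInstance(genome, model=model, dt=dt, params=params)


def spike_counts(records: list[SpikeRecord], neuron_ids: list[int]
                 ) -> np.ndarray:
    """Per-neuron spike counts for the given ids, from a record list."""
    idx = {nid: i for i, nid in enumerate(neuron_ids)}
    out = np.zeros(len(neuron_ids), dtype=np.int64)
    for r in records:
        i = idx.get(r.neuron_id)
        if i is not None:
            out[i] += 1
    return out


def export_spikes_csv(records: list[SpikeRecord], path) -> None:
    """Two-column CSV (neuron_id, time_ms)."""
    with open(path, "w") as fh:
        fh.write("neuron_id,time_ms\n")
        for r in records:
            fh.write(f"{r.neuron_id},{r.time}\n")
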