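# Methods

This note documents the models, the numerical choices, and the places
where the design was genuinely open, so results can be interpreted and
reproduced.

## Neuron models and integration

Both models share one synaptic state variable per neuron: a conductance
*g* incremented by the signed synaptic weight on every presynaptic spike
and decaying as g(t) = g₀·e^(−t/τ_g) between spikes.  Negative weights
give effective inhibition without a separate synapse type.

**LIF.**  τ dv/dt = −v + g + I with τ = 10 ms, threshold 30, reset −65.
The equation has no resting-potential term, so the zero-drive fixed point
is v = 0 while the reset sits at −65; both are taken literally from the
model definition and are overridable (`LIFParams`).  The membrane is
integrated with the *exponential (exact-leak) update*
v ← v·e^(−dt/τ) + (1 − e^(−dt/τ))(g + I), holding g + I constant over
the step.  Plain forward Euler accumulates ≈2.5% relative error over 5τ
at dt = 0.1 ms; the exponential update makes free decay exact at any dt
and threshold-crossing times accurate to one step.

**Izhikevich.**  dv/dt = 0.04v² + 5v + 140 − u + I + g,
du/dt = a(bv − u), regular-spiking parameterization a = 0.02, b = 0.2,
spike cutoff 30, reset c = −65, post-spike increment d = 8 (fixed across
all experiments; it controls spike-frequency adaptation).  Forward Euler,
as is canonical for this model; the threshold check runs after each step
so the quadratic overshoot is clipped by the reset.  The rest state is
the stable root of the nullclines, (−70, −14) for the defaults.

**Timing conventions.**  dt = 1 ms by default (property tests guard that
halving dt moves 50 ms spike counts by at most one per neuron).  Spikes
emitted at step k are delivered at step k + 1, making the update
independent of neuron ordering; at most one spike per neuron per step.
Network state is reset to rest at the start of every decision window
(every environment step, every classification sample); persistence across
windows is available (`reset=False`) but off, since whether membrane
state carried across control steps in comparable studies is not
documented, and resetting maximizes reproducibility.

**Synaptic decay τ_g = 20 ms (both models).**  The source model leaves
this constant open.  It is chosen commensurate with the 50 ms decision
window and the 40 ms latency-code span: conductances from spikes arriving
tens of milliseconds apart must still overlap for a postsynaptic neuron
to compute on relative spike timing.  With a much shorter τ_g the
single-spike codings become nearly unlearnable at the study's scale
(50 generations); with τ_g = 20 ms a single spike through a weight-5
synapse fires the Izhikevich neuron while the LIF neuron still needs
weight ≈ 59 — preserving the qualitative asymmetry that makes single-spike
+ LIF configurations fail.

## Synaptic weight scale

Initial and replacement weights are uniform in [−5, 5].  The range is
calibrated to the neurons' excitability: ±5 spans sub- to suprathreshold
single-spike synapses for the regular-spiking Izhikevich neuron, so the
initial population already contains functional pathways for every coding
scheme.  (With a [−1, 1] range the whole population starts an order of
magnitude below the functional scale for single-spike codings, fitness is
identically zero, and the mutation random walk needs far more than the
budgeted 50 generations to produce any spike.)  Weight mutation follows
standard NEAT practice: each connection, with probability P_w, receives
Gaussian noise (σ = 0.5) 90% of the time and is otherwise replaced by a
fresh uniform draw.  All of these are `EvolutionConfig` fields.

## NEAT specifics

- **Minimal start:** every input connected to every output; innovation
  numbers for identical structural changes are shared population-wide via
  a registry, including across generations.
- **Compatibility distance:** δ = c₁E/N + c₂D/N + c₃W̄; N = 1 when the
  larger genome has fewer than 20 genes, else its gene count (the
  original convention; pluggable via `norm_policy`).  Excess genes lie
  beyond the other genome's maximum innovation; disjoint genes inside it.
- **Speciation:** first representative (in order) within the threshold T
  wins; representatives are random members of the previous generation's
  species.
- **Survival and reproduction:** the top K fraction of each species
  survives unchanged; remaining slots are offspring allocated to species
  by largest-remainder on shifted mean fitness, produced by mutation alone
  with probability N (the "fresh mutation" rate) or within-species
  crossover followed by mutation.  Single-member species reproduce by
  mutation only; interspecies mating is a config option defaulting to 0.
- **Crossover:** matching genes from a random parent; disjoint/excess from
  the fitter parent (ties: one random draw decides); a gene disabled in
  either parent stays disabled with probability 0.75.
- **Add-node split:** the chosen connection is disabled and replaced by a
  relay whose afferent weight is 5.0 — a single presynaptic spike must be
  able to fire the relay, otherwise every split severs its pathway in a
  spiking substrate (the classic weight-1 convention presumes rate
  units).  The efferent connection keeps the old weight.
- **Add-connection:** any ordered pair with a non-input target, self-loops
  and recurrence included; a fully connected genome makes it a logged
  no-op.
- **Tie-breaking:** stable sort by fitness then genome id, with ids
  assigned so offspring precede the elites they tie; equal-fitness ties
  therefore resolve toward the younger genome, which permits neutral
  drift on flat fitness plateaus (with parent-favoring ties a plateaued
  population cannot move at all).
- **No stagnation-based extinction** by default (`species_stagnation`
  opt-in): best fitness per run is non-decreasing under a deterministic
  objective whenever K > 0.

## Fitness procedures

**Control:** fitness is the mean return over repeated episodes; episode i
of candidate c in generation g is seeded from (run_seed, g, c, i), so
runs replay exactly while each generation sees fresh initial states
(common random numbers across candidates is a config option).  The full
protocol evaluates 100 episodes per candidate; the desk-scale protocols
in `neatsnn.benchmarks` use 10 and compensate at selection time: after
the last generation the top 10 candidates are re-scored on a 30-episode
validation batch and the winner is reported, standing in for selection
under the full 100-episode fitness.

**Classification:** features are min-max normalized to [0, 1] (constant
columns map to 0).  Fitness is the mean accuracy over 50 bootstrap
subsets of 50 rows drawn with replacement *once per run* and shared by
every candidate — the literal reading of the evaluation procedure, which
also makes fitness deterministic.  Because networks are reset before
every sample, per-row predictions are computed once and reused across
subsets; this is numerically identical to re-simulating each subset.  A
silent network predicts nothing and scores a miss.

## Bundled environments

CartPole (+1 per step, 500-step cap, termination at ±2.4 cart excursion
or ±12° pole angle, Euler at 0.02 s), Mountain Car (−1 per step, 200-step
cap, goal at x ≥ 0.5), and Acrobot (−1 per step, 500-step cap, RK4 at
0.2 s, termination when the tip passes the bar) follow the standard
published benchmark dynamics and observation spaces, with seedable
initial-state randomization.  `observation_scales` on each environment
feeds the sign-split encoder (gain 40 per normalized feature unit);
`observation_ranges` parameterizes the interval banks.

## Hyperparameter search

Eleven hyperparameters are searched over closed intervals (survivor
fraction 0.40–0.60, speciation threshold 2.0–4.0, fresh-mutation
probability 0.15–0.35, weight-mutation probability 0.7–0.9, add-node
0.02–0.04 and add-connection 0.01–0.05 for both size regimes, and
c₁, c₂ ∈ 0.5–1.5, c₃ ∈ 0.3–0.5).  The built-in sampler draws uniformly;
a Tree-structured Parzen Estimator adapter is available when optuna is
installed and is exercised only through an interface test.  A trial's
objective is the best-ever fitness of its evolution run (configurable to
final-generation best).  `near_best_counts` reports how many trials came
within 95% of the best objective — on negative-return tasks after
shifting by the worst possible return so the ratio acts on a non-negative
scale — plus a strict count above an absolute threshold.
`replicate_best` re-runs a chosen configuration over independent seeds
(default 31) and reports mean and standard deviation.

## Synthetic data

`make_blobs` emulates an Iris-scale table: 3 balanced classes × 4
features × 150 rows, Gaussian clusters (σ = 1) with centers placed
`separation·σ` along distinct coordinate axes, min-max normalized.  It
reproduces the row/feature/class geometry and near-separability of small
UCI tables but not their feature correlations, class imbalance, or
measurement noise structure — so passing tests demonstrate that the
method learns timing-coded class structure at this scale, not that it
matches any particular real-data accuracy.  The scripted sign-following
environment (`ScriptedEnv`) gives the control harness a deterministic
optimum (return = step limit) that a 2-input/2-output network can reach,
with an exhaustive-search oracle over reactive policies confirming it.

## Problem sizes used by the test suite and acceptance script

Desk-scale runs keep the study-fixed population of 50 and the 50 ms
window: CartPole 50 generations with 10-episode fitness (~3–4 min),
Mountain Car failure-floor 8–20 generations (~1–2 min), synthetic
classification ≤50 generations (~10–60 s).  The two full-scale
replications (Mountain Car and Acrobot with the sign-split coding, 31
runs × 100-episode fitness) are exposed through the same APIs but are
overnight computations; the suite exercises their configurations at micro
scale without asserting their full-scale means.

## Known limitations

- Exactly one synapse per ordered neuron pair; no axonal delays beyond
  the one-step convention; no plasticity during an episode.
- The latency code maps larger values to later spikes — the simple
  monotone convention, not biological latency coding.
- Single Izhikevich parameterization (regular spiking); other firing
  regimes would need different d, a, b and likely a different weight
  calibration.
- The TPE adapter is untested against a live optuna in CI environments
  without the extra installed.
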