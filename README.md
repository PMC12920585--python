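# neatsnn

Neuroevolution of recurrent **spiking neural networks**: the NEAT algorithm
jointly evolving the topology and synaptic weights of networks built from
conductance-driven **leaky integrate-and-fire (LIF)** or **Izhikevich**
neurons, for episodic control and tabular classification.

The package is for researchers in neuromorphic computing and evolutionary
machine learning who want to compare neuron models and spike
encoding/decoding schemes under a gradient-free trainer: everything —
simulator, genetic operators, codecs, benchmark environments, and the
hyperparameter-search protocol with near-best robustness analysis — is
importable Python, with a thin `neatsnn` command-line wrapper.

## The model

**Neurons.** Each network node is a point neuron with a synaptic
conductance *g* that jumps by the (signed) synaptic weight on every
presynaptic spike and decays exponentially between spikes
(τ<sub>g</sub> = 20 ms by default):

- LIF: τ dv/dt = −v + g + I, spike at v ≥ 30, reset to −65 (τ = 10 ms);
- Izhikevich (regular-spiking): dv/dt = 0.04v² + 5v + 140 − u + I + g,
  du/dt = a(bv − u) with a = 0.02, b = 0.2; on a spike v ← −65 and
  u ← u + d with d = 8, producing spike-frequency adaptation.

Weights may be negative, so evolved networks exhibit both excitatory and
inhibitory effective interactions through a single synapse type.
Simulation is clock-driven (dt = 1 ms default) with a one-step synaptic
delay, compiled with numba.

**Evolution.** NEAT grows networks from a minimal all-input-to-all-output
structure through weight perturbation, connection insertion, and node
splitting, with innovation numbers aligning homologous genes.  Genomes are
clustered into species by the compatibility distance

δ = c₁·E/N + c₂·D/N + c₃·W̄

(E excess genes, D disjoint genes, W̄ mean absolute weight difference of
matching genes, N a size normalization); selection and crossover act
within species.  A network is "large" above 20 neurons, switching the
structural mutation rates.

**Codecs.** Control observations enter as constant currents on a
two-neurons-per-feature sign-split code, or through 20-neuron interval
(population) codes with Gaussian-sampled tuning centers firing a single
spike or receiving a sustained current (75 for LIF, 20 for Izhikevich).
Actions are decoded by spike count over a 50 ms window.  Classification
features (normalized to [0, 1]) use five-interval one-hot coding or
latency coding (larger value ⇒ later spike), decoded by voting or
first-spike.  Fitness is the mean return over episodes (control) or the
mean accuracy over 50 bootstrap subsets of 50 rows (classification).

## Worked example

```bash
python examples/classify_blobs.py
```

```
reached fitness 0.900 after 27 generations
re-evaluated accuracy on fresh bootstrap subsets: 0.899
best network: 7 neurons, 13 active synapses
```

A population of 50 genomes evolved a 7-neuron recurrent spiking network
that reads 4 latency-coded features and classifies 3 Gaussian clusters at
~0.90 accuracy (chance is 0.33) — the class identity is decoded from
relative spike timings alone.  `examples/simulate_neurons.py` shows the
two neuron models' spike trains (the Izhikevich inter-spike intervals
lengthen under constant drive — adaptation the LIF model lacks),
`examples/evolve_cartpole.py` evolves a pole balancer, and
`examples/hyperparameter_search.py` runs a small search over the eleven
published hyperparameter intervals and prints the near-best count.

The same protocols from a shell:

```bash
neatsnn evolve --task cartpole --model izhikevich --encoding small \
    --pop 50 --gens 50 --seed 1 --out runs/cp1
neatsnn evaluate --genome runs/cp1/best_genome.json --task cartpole
neatsnn report --runs runs --threshold 450
```

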