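"""NEAT: speciated neuroevolution of network topology and weights.

Implements the compatibility distance

    delta = c1 * E / N + c2 * D / N + c3 * Wbar

where E and D are the numbers of excess and disjoint genes (non-matching
genes outside / inside the other genome's innovation range), N is a
normalization factor and Wbar the mean absolute weight difference of
matching genes.  Genomes within a threshold T of a species representative
share that species; selection, crossover and mutation act within species.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import (ConnectionGene, Genome, GenomeError, InnovationRegistry,
                     NodeGene, ROLE_HIDDEN, ROLE_INPUT, minimal_genome)

log = logging.getLogger(__name__)

# weight given to the afferent connection of a node inserted by the
# add-node mutation: strong enough that one presynaptic spike fires the
# relay (single-spike threshold is ~5 for the regular-spiking Izhikevich
# neuron at the default conductance decay)
RELAY_WEIGHT = 5.0


def neat_norm(size1: int, size2: int, small_cutoff: int = 20) -> float:
    """Original NEAT normalization: 1 for small genomes, else the larger
    genome's gene count."""
    larger = max(size1, size2)
    return 1.0 if larger < small_cutoff else float(larger)


@dataclass
class CompatibilityParams:
    c1: float = 1.0
    c2: float = 1.0
    c3: float = 0.4
    norm_policy = staticmethod(neat_norm)

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3) < 0:
            raise ValueError("compatibility coefficients must be >= 0")


@dataclass
class EvolutionConfig:
    """Hyperparameters of the evolutionary loop.

    ``fresh_mutation_prob`` is the probability that an offspring is produced
    by mutation alone rather than crossover-then-mutation.  ``*_small`` /
    ``*_large`` structural rates apply below / above ``large_threshold``
    neurons.
    """
    keep_fraction: float = 0.5
    compat_threshold: float = 3.0
    fresh_mutation_prob: float = 0.25
    weight_mut_prob: float = 0.8
    add_node_small: float = 0.03
    add_conn_small: float = 0.03
    add_node_large: float = 0.03
    add_conn_large: float = 0.03
    population_size: int = 50
    generations: int = 50
    large_threshold: int = 20
    compat: CompatibilityParams = field(default_factory=CompatibilityParams)
    # weight-mutation mechanics (standard NEAT practice, exposed here)
    weight_perturb_sigma: float = 0.5
    weight_replace_prob: float = 0.1
    # calibrated to the neuron models' excitability: +-5 spans sub- to
    # suprathreshold single-spike synapses for the Izhikevich neuron, so
    # the initial population already contains functional pathways
    weight_init_range: tuple[float, float] = (-5.0, 5.0)
    disable_inherit_prob: float = 0.75
    interspecies_mating_prob: float = 0.0
    species_stagnation: int | None = None  # generations; None = never extinct

    def __post_init__(self):
        probs = (self.fresh_mutation_prob, self.weight_mut_prob,
                 self.add_node_small, self.add_conn_small,
                 self.add_node_large, self.add_conn_large,
                 self.disable_inherit_prob, self.interspecies_mating_prob)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.population_size <= 1:
            raise ValueError("population_size must exceed 1")
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must lie in (0, 1]")


@dataclass
class Species:
    representative: Genome
    members: list[Genome] = field(default_factory=list)


# ---------------------------------------------------------------------------
# compatibility distance
# ---------------------------------------------------------------------------

def compatibility_distance(g1: Genome, g2: Genome,
                           p: CompatibilityParams) -> float:
    m1 = g1.innovations()
    m2 = g2.innovations()
    if not m1 and not m2:
        return 0.0
    max1 = max(m1) if m1 else -1
    max2 = max(m2) if m2 else -1
    cutoff = min(max1, max2)
    matching = m1.keys() & m2.keys()
    excess = disjoint = 0
    for innov in m1.keys() ^ m2.keys():
        if innov > cutoff:
            excess += 1
        else:
            disjoint += 1
    if matching:
        wbar = sum(abs(m1[i].weight - m2[i].weight) for i in matching)
        wbar /= len(matching)
    else:
        wbar = 0.0
    n = p.norm_policy(len(m1), len(m2))
    return p.c1 * excess / n + p.c2 * disjoint / n + p.c3 * wbar


def is_large(g: Genome, threshold: int = 20) -> bool:
    """A network is considered large if it has more than ``threshold``
    neurons."""
    return len(g.nodes) > threshold


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

def mutate(g: Genome, cfg: EvolutionConfig, reg: InnovationRegistry,
           rng: np.random.Generator) -> Genome:
    """Return a mutated copy of ``g``: per-connection weight perturbation,
    then (rate-gated) add-node and add-connection structural mutations."""
    child = g.copy()
    child.fitness = None
    lo, hi = cfg.weight_init_range
    for c in child.connections:
        if rng.random() < cfg.weight_mut_prob:
            if rng.random() < cfg.weight_replace_prob:
                c.weight = float(rng.uniform(lo, hi))
            else:
                c.weight = float(c.weight +
                                 rng.normal(0.0, cfg.weight_perturb_sigma))
    large = is_large(child, cfg.large_threshold)
    p_node = cfg.add_node_large if large else cfg.add_node_small
    p_conn = cfg.add_conn_large if large else cfg.add_conn_small
    if rng.random() < p_node:
        _mutate_add_node(child, reg, rng)
    if rng.random() < p_conn:
        _mutate_add_connection(child, cfg, reg, rng)
    return child


def _mutate_add_node(g: Genome, reg: InnovationRegistry,
                     rng: np.random.Generator) -> None:
    enabled = g.enabled_connections()
    if not enabled:
        return
    conn = enabled[int(rng.integers(len(enabled)))]
    conn.enabled = False
    node_id, in_innov, out_innov = reg.split_innovations(conn.innovation)
    existing = g.innovations()
    if in_innov in existing or out_innov in existing or node_id in g.node_ids:
        conn.enabled = True  # same split already present in this genome
        return
    g.nodes.append(NodeGene(node_id, ROLE_HIDDEN))
    # the in-connection must be suprathreshold for a single presynaptic
    # spike, otherwise the new relay neuron is silent and every split
    # severs its pathway; the out-connection keeps the old weight
    g.connections.append(ConnectionGene(in_innov, conn.source, node_id,
                                        RELAY_WEIGHT))
    g.connections.append(ConnectionGene(out_innov, node_id, conn.target,
                                        conn.weight))


def _mutate_add_connection(g: Genome, cfg: EvolutionConfig,
                           reg: InnovationRegistry,
                           rng: np.random.Generator) -> None:
    taken = {(c.source, c.target) for c in g.connections}
    sources = sorted(g.node_ids)
    # recurrent topology: any node may project to any non-input node
    targets = [n.id for n in sorted(g.nodes, key=lambda n: n.id)
               if n.role != ROLE_INPUT]
    candidates = [(s, t) for s in sources for t in targets
                  if (s, t) not in taken]
    if not candidates:
        log.debug("add-connection no-op: genome %d fully connected", g.key)
        return
    s, t = candidates[int(rng.integers(len(candidates)))]
    lo, hi = cfg.weight_init_range
    innov = reg.connection_innovation(s, t)
    g.connections.append(
        ConnectionGene(innov, s, t, float(rng.uniform(lo, hi))))


def crossover(p1: Genome, p2: Genome, rng: np.random.Generator,
              disable_inherit_prob: float = 0.75) -> Genome:
    """Recombine two parents.  Matching genes come from a random parent;
    disjoint and excess genes come from the fitter parent (ties broken by a
    single random draw).  A gene disabled in either parent stays disabled in
    the child with probability ``disable_inherit_prob``."""
    if p1.fitness is None or p2.fitness is None:
        raise ValueError("crossover requires evaluated parents")
    if p1.fitness > p2.fitness:
        fitter, other = p1, p2
    elif p2.fitness > p1.fitness:
        fitter, other = p2, p1
    else:
        fitter, other = (p1, p2) if rng.random() < 0.5 else (p2, p1)
    mf = fitter.innovations()
    mo = other.innovations()
    child_conns: list[ConnectionGene] = []
    for innov in sorted(mf):
        gene_f = mf[innov]
        gene_o = mo.get(innov)
        if gene_o is not None:
            src = gene_f if rng.random() < 0.5 else gene_o
            gene = src.copy()
            if (not gene_f.enabled) or (not gene_o.enabled):
                gene.enabled = not (rng.random() < disable_inherit_prob)
        else:
            gene = gene_f.copy()
        child_conns.append(gene)
    # nodes: the fitter parent's node set always covers every inherited gene
    child = Genome(nodes=list(fitter.nodes), connections=child_conns,
                   key=fitter.key)
    return child


# ---------------------------------------------------------------------------
# speciation and reproduction
# ---------------------------------------------------------------------------

def speciate(pop: list[Genome], reps: list[Genome], threshold: float,
             p: CompatibilityParams) -> list[Species]:
    """Assign every genome to the first representative within ``threshold``
    (in representative order) or found a new species with it."""
    if threshold <= 0:
        raise ValueError("compatibility threshold must be positive")
    species = [Species(representative=r) for r in reps]
    for g in pop:
        for sp in species:
            if compatibility_distance(g, sp.representative, p) < threshold:
                sp.members.append(g)
                break
        else:
            species.append(Species(representative=g, members=[g]))
    return [sp for sp in species if sp.members]


def _sorted_by_fitness(members: list[Genome]) -> list[Genome]:
    # stable: fitness descending, then genome key for reproducible ties
    return sorted(members, key=lambda g: (-g.fitness, g.key))


def next_generation(species: list[Species], cfg: EvolutionConfig,
                    reg: InnovationRegistry,
                    rng: np.random.Generator) -> list[Genome]:
    """Produce the next population: the top ``keep_fraction`` of each species
    survive unchanged; remaining slots are filled by offspring bred within
    species (mutation-only with probability ``fresh_mutation_prob``, else
    crossover followed by mutation)."""
    species = [sp for sp in species if sp.members]
    if not species:
        raise RuntimeError("cannot reproduce: every species is empty")
    if any(g.fitness is None for sp in species for g in sp.members):
        raise ValueError("all members need fitness before reproduction")

    survivors: list[list[Genome]] = []
    elites: list[Genome] = []
    for sp in species:
        ranked = _sorted_by_fitness(sp.members)
        n_keep = max(1, int(np.floor(cfg.keep_fraction * len(ranked))))
        survivors.append(ranked[:n_keep])
    for group in survivors:
        elites.extend(group)
    if len(elites) > cfg.population_size:
        elites = _sorted_by_fitness(elites)[:cfg.population_size]
        kept = {id(g) for g in elites}
        survivors = [[g for g in group if id(g) in kept] or group[:1]
                     for group in survivors]

    n_offspring = cfg.population_size - len(elites)
    quotas = _offspring_quotas(species, n_offspring)
    offspring: list[Genome] = []
    for sp_idx, quota in enumerate(quotas):
        pool = survivors[sp_idx]
        for _ in range(quota):
            if len(pool) == 1 or rng.random() < cfg.fresh_mutation_prob:
                parent = pool[int(rng.integers(len(pool)))]
                child = mutate(parent, cfg, reg, rng)
            else:
                i, j = rng.choice(len(pool), size=2, replace=False)
                child = crossover(pool[int(i)], pool[int(j)], rng,
                                  cfg.disable_inherit_prob)
                child = mutate(child, cfg, reg, rng)
            offspring.append(child)

    # offspring get the lowest keys: fitness ties then resolve toward the
    # younger genome, letting neutral drift proceed on flat landscapes
    new_pop = offspring + [g.copy() for g in elites]
    for idx, g in enumerate(new_pop):
        g.key = idx
    return new_pop


def _offspring_quotas(species: list[Species], n_offspring: int) -> list[int]:
    """Largest-remainder allocation proportional to species mean fitness,
    shifted so the worst species still has positive share."""
    means = np.array([np.mean([g.fitness for g in sp.members])
                      for sp in species], dtype=float)
    shifted = means - means.min() + 1e-9
    shares = shifted / shifted.sum() * n_offspring
    quotas = np.floor(shares).astype(int)
    remainder = n_offspring - int(quotas.sum())
    order = np.argsort(-(shares - quotas), kind="stable")
    for k in range(remainder):
        quotas[order[k]] += 1
    return quotas.tolist()


# ---------------------------------------------------------------------------
# generational loop
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    best: Genome
    best_fitness: float
    history: list[dict]
    population: list[Genome]
    registry: InnovationRegistry
    generations_run: int

    def write_log(self, path) -> None:
        write_run_log(self.history, path)


def write_run_log(history: list[dict], path) -> None:
    """One CSV row per generation."""
    fields = ["generation", "best_fitness", "mean_fitness", "n_species",
              "n_nodes_best", "n_conns_best"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for row in history:
            w.writerow({k: row[k] for k in fields})


def evolve(eval_fn, n_inputs: int, n_outputs: int, cfg: EvolutionConfig,
           seed: int = 0, fitness_goal: float | None = None,
           on_generation=None) -> EvolutionResult:
    """Run the NEAT loop from a minimal-structure population.

    ``eval_fn(genome, generation, index) -> float`` assigns fitness; it is
    called once per candidate per generation and must not depend on
    evaluation order.  Evolution stops after ``cfg.generations`` generations
    or as soon as the generation's best fitness reaches ``fitness_goal``.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    reg = InnovationRegistry()
    population = [minimal_genome(n_inputs, n_outputs, reg, rng,
                                 cfg.weight_init_range, key=i)
                  for i in range(cfg.population_size)]
    reps: list[Genome] = []
    history: list[dict] = []
    best: Genome | None = None
    best_fitness = -np.inf
    gen = 0
    for gen in range(cfg.generations):
        for idx, g in enumerate(population):
            g.fitness = float(eval_fn(g, gen, idx))
        ranked = _sorted_by_fitness(population)
        gen_best = ranked[0]
        if gen_best.fitness > best_fitness:
            best_fitness = gen_best.fitness
            best = gen_best.copy()
            best.fitness = gen_best.fitness
        species = speciate(population, reps, cfg.compat_threshold, cfg.compat)
        row = {
            "generation": gen,
            "best_fitness": gen_best.fitness,
            "mean_fitness": float(np.mean([g.fitness for g in population])),
            "n_species": len(species),
            "n_nodes_best": len(gen_best.nodes),
            "n_conns_best": len(gen_best.connections),
        }
        history.append(row)
        log.info("gen %3d  best %.3f  mean %.3f  species %d", gen,
                 row["best_fitness"], row["mean_fitness"], row["n_species"])
        if on_generation is not None:
            on_generation(row, population)
        if fitness_goal is not None and gen_best.fitness >= fitness_goal:
            break
        if gen < cfg.generations - 1:
            # representative: random member of the species just observed
            reps = [sp.members[int(rng.integers(len(sp.members)))].copy()
                    for sp in species]
            population = next_generation(species, cfg, reg, rng)
    return EvolutionResult(best=best, best_fitness=best_fitness,
                           history=history, population=population,
                           registry=reg, generations_run=gen + 1)
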