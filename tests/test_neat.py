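import numpy as np
import pytest

from neatsnn.fixtures import make_toy_genomes
from neatsnn.genome import InnovationRegistry, minimal_genome
from neatsnn.neat import (CompatibilityParams, EvolutionConfig, Species,
                          compatibility_distance, crossover, evolve,
                          is_large, mutate, neat_norm, next_generation,
                          speciate)

from conftest import oracle_distance, random_genome


def unit_params(c3=0.4):
    return CompatibilityParams(c1=1.0, c2=1.0, c3=c3)


class TestCompatibilityDistance:
    def test_zero_for_identical_genome(self, minimal22):
        assert compatibility_distance(minimal22, minimal22,
                                      unit_params()) == 0.0

    def test_disjoint_pair_worked_example(self):
        g1, g2 = make_toy_genomes("disjoint_pair")
        # innovations {1,2,3} vs {1,2,4,5}: E=2, D=1, matching weights
        # differ by 0.5 each
        d = compatibility_distance(g1, g2, unit_params())
        assert d == pytest.approx(1.0 * 2 + 1.0 * 1 + 0.4 * 0.5)

    def test_identical_structure_weight_shift(self, minimal22):
        shifted = minimal22.copy()
        for c in shifted.connections:
            c.weight += 1.0
        d = compatibility_distance(minimal22, shifted, unit_params())
        assert d == pytest.approx(0.4)

    def test_symmetry_and_nonnegativity(self, rng):
        p = unit_params()
        for _ in range(50):
            a, b = random_genome(rng), random_genome(rng)
            dab = compatibility_distance(a, b, p)
            assert dab == pytest.approx(compatibility_distance(b, a, p))
            assert dab >= 0.0

    def test_agrees_with_alignment_oracle(self, rng):
        """Production distance equals the brute-force gene-alignment oracle
        on 1,000 random small genome pairs."""
        p = CompatibilityParams(c1=1.2, c2=0.8, c3=0.4)
        for _ in range(1000):
            a, b = random_genome(rng), random_genome(rng)
            expect = oracle_distance(a, b, 1.2, 0.8, 0.4, neat_norm)
            assert compatibility_distance(a, b, p) == pytest.approx(expect)

    def test_norm_policy_switches_at_twenty_genes(self):
        assert neat_norm(5, 19) == 1.0
        assert neat_norm(5, 20) == 20.0
        assert neat_norm(25, 3) == 25.0


class TestIsLarge:
    @pytest.mark.parametrize("n_nodes,expected",
                             [(1, False), (20, False), (21, True)])
    def test_boundary_at_twenty_neurons(self, rng, n_nodes, expected):
        reg = InnovationRegistry()
        g = minimal_genome(max(1, n_nodes - 1), 1, reg, rng)
        assert len(g.nodes) == max(1, n_nodes - 1) + 1
        if len(g.nodes) == n_nodes:
            assert is_large(g) is expected


class TestMutate:
    def test_zero_rates_is_identity(self, minimal22, registry, rng):
        cfg = EvolutionConfig(weight_mut_prob=0.0, add_node_small=0.0,
                              add_conn_small=0.0, add_node_large=0.0,
                              add_conn_large=0.0)
        child = mutate(minimal22, cfg, registry, rng)
        assert child.to_dict() == minimal22.copy().to_dict()

    def test_weight_mutation_changes_all_and_is_reproducible(
            self, minimal22, registry):
        cfg = EvolutionConfig(weight_mut_prob=1.0, add_node_small=0.0,
                              add_conn_small=0.0)
        rng1 = np.random.Generator(np.random.PCG64(7))
        rng2 = np.random.Generator(np.random.PCG64(7))
        c1 = mutate(minimal22, cfg, registry, rng1)
        c2 = mutate(minimal22, cfg, InnovationRegistry(), rng2)
        for orig, new in zip(minimal22.connections, c1.connections):
            assert new.weight != orig.weight
        assert c1.to_dict() == c2.to_dict()

    def test_add_node_split_convention(self, registry, rng):
        cfg = EvolutionConfig(weight_mut_prob=0.0, add_node_small=1.0,
                              add_conn_small=0.0)
        g = minimal_genome(1, 1, registry, rng)
        child = mutate(g, cfg, registry, rng)
        assert len(child.nodes) == len(g.nodes) + 1
        assert len(child.connections) == len(g.connections) + 2
        assert sum(not c.enabled for c in child.connections) == 1
        child.validate()

    def test_add_connection_on_fully_connected_is_noop(self, registry, rng):
        cfg = EvolutionConfig(weight_mut_prob=0.0, add_node_small=0.0,
                              add_conn_small=1.0)
        g = minimal_genome(1, 1, registry, rng)
        # saturate: 1 input, 1 output -> pairs (0,1) taken; (1,1) remains
        child = g
        for _ in range(5):
            child = mutate(child, cfg, registry, rng)
        n = len(child.connections)
        again = mutate(child, cfg, registry, rng)
        assert len(again.connections) == n  # fully connected: no-op
        again.validate()

    def test_input_output_sets_never_change(self, minimal22, registry, rng):
        cfg = EvolutionConfig(weight_mut_prob=1.0, add_node_small=0.5,
                              add_conn_small=0.5)
        g = minimal22
        for _ in range(30):
            g = mutate(g, cfg, registry, rng)
        assert g.input_ids == minimal22.input_ids
        assert g.output_ids == minimal22.output_ids
        g.validate()


class TestCrossover:
    def test_identical_parents_reproduce_structure(self, minimal22, rng):
        minimal22.fitness = 1.0
        child = crossover(minimal22, minimal22, rng)
        assert {c.innovation for c in child.connections} == \
            {c.innovation for c in minimal22.connections}
        assert {n.id for n in child.nodes} == {n.id for n in minimal22.nodes}

    def test_child_innovations_subset_of_parents(self, rng):
        for _ in range(50):
            a, b = random_genome(rng), random_genome(rng)
            a.fitness, b.fitness = float(rng.random()), float(rng.random())
            child = crossover(a, b, rng)
            union = {c.innovation for c in a.connections} | \
                {c.innovation for c in b.connections}
            assert {c.innovation for c in child.connections} <= union

    def test_exclusive_genes_come_from_fitter_parent(self):
        """Exhaustive check on the disjoint toy pair: the fitter parent's
        exclusive genes are inherited, the other's never are."""
        for _ in range(20):
            g1, g2 = make_toy_genomes("disjoint_pair")
            g1.fitness, g2.fitness = 2.0, 1.0
            rng = np.random.Generator(np.random.PCG64(_))
            child = crossover(g1, g2, rng)
            innovs = {c.innovation for c in child.connections}
            assert 3 in innovs       # g1-exclusive, g1 fitter
            assert 4 not in innovs and 5 not in innovs

    def test_requires_evaluated_parents(self, minimal22, rng):
        with pytest.raises(ValueError, match="evaluated"):
            crossover(minimal22, minimal22, rng)


class TestSpeciate:
    def test_clone_population_forms_single_species(self, minimal22):
        pop = [minimal22.copy() for _ in range(10)]
        species = speciate(pop, [], 3.0, unit_params())
        assert len(species) == 1
        assert len(species[0].members) == 10

    def test_two_distant_groups_form_two_species(self, minimal22):
        far = minimal22.copy()
        for c in far.connections:
            c.weight += 100.0   # delta = 0.4 * 100 >> T
        pop = [minimal22.copy() for _ in range(3)] + \
            [far.copy() for _ in range(3)]
        d = compatibility_distance(minimal22, far, unit_params())
        assert d > 3.0
        species = speciate(pop, [], 3.0, unit_params())
        assert len(species) == 2
        assert sum(len(sp.members) for sp in species) == 6

    def test_empty_rep_list_bootstraps_first_genome(self, minimal22):
        species = speciate([minimal22], [], 2.0, unit_params())
        assert species[0].representative is minimal22


class TestNextGeneration:
    def _species_of(self, genomes):
        return [Species(representative=genomes[0], members=list(genomes))]

    def test_population_size_preserved(self, registry, rng):
        cfg = EvolutionConfig(population_size=50)
        pop = [minimal_genome(2, 2, registry, rng, key=i) for i in range(50)]
        for i, g in enumerate(pop):
            g.fitness = float(i)
        nxt = next_generation(self._species_of(pop), cfg, registry, rng)
        assert len(nxt) == 50

    def test_top_keep_fraction_survive_unchanged(self, registry, rng):
        cfg = EvolutionConfig(population_size=10, keep_fraction=0.6)
        pop = [minimal_genome(2, 2, registry, rng, key=i) for i in range(10)]
        for i, g in enumerate(pop):
            g.fitness = float(i)
        nxt = next_generation(self._species_of(pop), cfg, registry, rng)
        top6 = sorted(pop, key=lambda g: -g.fitness)[:6]
        next_dicts = [{k: v for k, v in g.to_dict().items()
                       if k not in ("key", "fitness")} for g in nxt]
        for elite in top6:
            d = {k: v for k, v in elite.to_dict().items()
                 if k not in ("key", "fitness")}
            assert d in next_dicts

    def test_reproducible_given_seed(self, registry, rng):
        cfg = EvolutionConfig(population_size=20)
        pop = [minimal_genome(2, 2, registry, rng, key=i) for i in range(20)]
        for i, g in enumerate(pop):
            g.fitness = float(i % 7)
        a = next_generation(self._species_of(pop), cfg, registry,
                            np.random.Generator(np.random.PCG64(3)))
        b = next_generation(self._species_of(pop), cfg, registry,
                            np.random.Generator(np.random.PCG64(3)))
        assert [g.to_dict() for g in a] == [g.to_dict() for g in b]

    def test_empty_species_is_fatal(self, registry, rng):
        with pytest.raises(RuntimeError, match="empty"):
            next_generation([], EvolutionConfig(), registry, rng)


class TestEvolveLoop:
    def test_invariants_over_twenty_generations(self):
        """Population size constant, innovation numbers unique per genome,
        every genome simulable, best fitness non-decreasing under a
        deterministic objective with elitism."""
        cfg = EvolutionConfig(population_size=20, generations=20,
                              add_node_small=0.2, add_conn_small=0.2)
        seen_sizes = []

        def fitness(g, gen, idx):  # deterministic: connection richness
            return sum(c.enabled for c in g.connections) \
                + 0.001 * len(g.nodes)

        def on_gen(row, population):
            seen_sizes.append(len(population))
            for g in population:
                innovs = [c.innovation for c in g.connections]
                assert len(innovs) == len(set(innovs))
                g.validate()   # all endpoints exist -> simulable

        result = evolve(fitness, 2, 2, cfg, seed=5, on_generation=on_gen)
        assert seen_sizes == [20] * 20
        bests = [h["best_fitness"] for h in result.history]
        assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))

    def test_run_is_reproducible(self):
        cfg = EvolutionConfig(population_size=10, generations=5)

        def fitness(g, gen, idx):
            return float(len(g.connections))

        r1 = evolve(fitness, 2, 2, cfg, seed=9)
        r2 = evolve(fitness, 2, 2, cfg, seed=9)
        assert r1.best.to_dict() == r2.best.to_dict()
        assert r1.history == r2.history

    def test_run_log_csv(self, tmp_path):
        cfg = EvolutionConfig(population_size=10, generations=3)
        result = evolve(lambda g, gen, idx: 1.0, 2, 2, cfg, seed=0)
        path = tmp_path / "log.csv"
        result.write_log(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == ("generation,best_fitness,mean_fitness,"
                            "n_species,n_nodes_best,n_conns_best")
        assert len(lines) == 4
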