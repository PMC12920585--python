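import numpy as np
import pytest

from neatsnn.genome import (ConnectionGene, Genome, InnovationRegistry,
                            NodeGene, minimal_genome)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def registry():
    return InnovationRegistry()


@pytest.fixture
def minimal22(registry, rng):
    """2-input / 2-output minimal genome with reproducible weights."""
    return minimal_genome(2, 2, registry, rng)


def random_genome(rng, max_genes: int = 12, n_in: int = 2,
                  n_out: int = 2) -> Genome:
    """Small random genome with arbitrary innovation numbers for
    distance-oracle property tests."""
    n_hidden = int(rng.integers(0, 3))
    nodes = [NodeGene(i, "input") for i in range(n_in)]
    nodes += [NodeGene(n_in + j, "output") for j in range(n_out)]
    nodes += [NodeGene(n_in + n_out + k, "hidden") for k in range(n_hidden)]
    ids = [n.id for n in nodes]
    non_input = [n.id for n in nodes if n.role != "input"]
    n_genes = int(rng.integers(1, max_genes + 1))
    innovs = rng.choice(50, size=n_genes, replace=False)
    conns, seen = [], set()
    for innov in sorted(int(i) for i in innovs):
        s = int(rng.choice(ids))
        t = int(rng.choice(non_input))
        enabled = bool(rng.random() < 0.9)
        if enabled and (s, t) in seen:
            enabled = False
        if enabled:
            seen.add((s, t))
        conns.append(ConnectionGene(innov, s, t,
                                    float(rng.normal(0, 2)), enabled))
    return Genome(nodes=nodes, connections=conns)


def oracle_distance(g1: Genome, g2: Genome, c1, c2, c3, norm) -> float:
    """Brute-force gene-alignment distance: classify every innovation by
    exhaustive comparison against the other genome's full innovation list.
    Independent of the production implementation."""
    m1 = {c.innovation: c.weight for c in g1.connections}
    m2 = {c.innovation: c.weight for c in g2.connections}
    if not m1 and not m2:
        return 0.0
    excess = disjoint = 0
    diffs = []
    for innov in set(m1) | set(m2):
        in1, in2 = innov in m1, innov in m2
        if in1 and in2:
            diffs.append(abs(m1[innov] - m2[innov]))
        elif in1:
            if all(innov > other for other in m2) or not m2:
                excess += 1
            else:
                disjoint += 1
        else:
            if all(innov > other for other in m1) or not m1:
                excess += 1
            else:
                disjoint += 1
    wbar = sum(diffs) / len(diffs) if diffs else 0.0
    n = norm(len(m1), len(m2))
    return c1 * excess / n + c2 * disjoint / n + c3 * wbar
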