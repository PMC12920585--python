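"""Genome representation for NEAT-evolved spiking networks.

A genome is a direct encoding of a recurrent spiking network: node genes
declare neurons (input / output / hidden), connection genes declare synapses
with a signed real weight and an *innovation number* — a historical marker
that lets homologous genes be aligned across genomes during crossover and
compatibility-distance computation.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

SCHEMA_VERSION = 1

ROLE_INPUT = "input"
ROLE_OUTPUT = "output"
ROLE_HIDDEN = "hidden"
_ROLES = (ROLE_INPUT, ROLE_OUTPUT, ROLE_HIDDEN)


class GenomeError(ValueError):
    """Raised when a genome violates its structural invariants."""


@dataclass(frozen=True)
class NodeGene:
    id: int
    role: str

    def __post_init__(self):
        if self.id < 0:
            raise GenomeError(f"node id must be non-negative, got {self.id}")
        if self.role not in _ROLES:
            raise GenomeError(f"unknown node role {self.role!r}")


@dataclass
class ConnectionGene:
    innovation: int
    source: int
    target: int
    weight: float
    enabled: bool = True

    def copy(self) -> "ConnectionGene":
        return ConnectionGene(self.innovation, self.source, self.target,
                              self.weight, self.enabled)


@dataclass
class Genome:
    nodes: list[NodeGene]
    connections: list[ConnectionGene]
    fitness: float | None = None
    key: int = 0  # stable identifier used for reproducible tie-breaking

    # -- derived views ------------------------------------------------------
    @property
    def node_ids(self) -> set[int]:
        return {n.id for n in self.nodes}

    @property
    def input_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.role == ROLE_INPUT)

    @property
    def output_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.role == ROLE_OUTPUT)

    @property
    def hidden_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.role == ROLE_HIDDEN)

    def innovations(self) -> dict[int, ConnectionGene]:
        return {c.innovation: c for c in self.connections}

    def enabled_connections(self) -> list[ConnectionGene]:
        return [c for c in self.connections if c.enabled]

    def size(self) -> tuple[int, int]:
        """(node count, connection count)."""
        return len(self.nodes), len(self.connections)

    def copy(self) -> "Genome":
        return Genome(nodes=list(self.nodes),
                      connections=[c.copy() for c in self.connections],
                      fitness=self.fitness, key=self.key)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise GenomeError naming the defect."""
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise GenomeError("duplicate node ids")
        if not self.input_ids or not self.output_ids:
            raise GenomeError("genome must contain input and output nodes")
        innovs = [c.innovation for c in self.connections]
        if len(innovs) != len(set(innovs)):
            raise GenomeError("duplicate innovation numbers")
        node_ids = set(ids)
        for c in self.connections:
            if c.source not in node_ids or c.target not in node_ids:
                raise GenomeError(
                    f"connection {c.innovation} has dangling endpoint "
                    f"({c.source}->{c.target})")
        seen: set[tuple[int, int]] = set()
        for c in self.enabled_connections():
            pair = (c.source, c.target)
            if pair in seen:
                raise GenomeError(f"duplicate enabled connection {pair}")
            seen.add(pair)

    # -- serialization ------------------------------------------------------
    def to_dict(self, metadata: dict | None = None) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "nodes": [{"id": n.id, "role": n.role} for n in self.nodes],
            "connections": [
                {"innovation": c.innovation, "source": c.source,
                 "target": c.target, "weight": c.weight, "enabled": c.enabled}
                for c in self.connections
            ],
            "fitness": self.fitness,
            "key": self.key,
            "metadata": dict(metadata) if metadata else {},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        g = cls(
            nodes=[NodeGene(n["id"], n["role"]) for n in d["nodes"]],
            connections=[
                ConnectionGene(c["innovation"], c["source"], c["target"],
                               float(c["weight"]), bool(c["enabled"]))
                for c in d["connections"]
            ],
            fitness=d.get("fitness"),
            key=int(d.get("key", 0)),
        )
        g.validate()
        return g


def save_genome(genome: Genome, path: str | Path,
                metadata: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(genome.to_dict(metadata), indent=1, sort_keys=True) + "\n")


def load_genome(path: str | Path) -> Genome:
    return Genome.from_dict(json.loads(Path(path).read_text()))


class InnovationRegistry:
    """Assigns innovation numbers and node ids to structural changes.

    Identical structural changes (same source/target pair, or splitting the
    same connection gene) receive identical innovation numbers so that
    homologous structure stays alignable across the population.
    """

    def __init__(self, next_innovation: int = 0, next_node_id: int = 0):
        self.next_innovation = next_innovation
        self.next_node_id = next_node_id
        self._conn_memo: dict[tuple[int, int], int] = {}
        self._split_memo: dict[int, tuple[int, int, int]] = {}

    def connection_innovation(self, source: int, target: int) -> int:
        key = (source, target)
        if key not in self._conn_memo:
            self._conn_memo[key] = self.next_innovation
            self.next_innovation += 1
        return self._conn_memo[key]

    def split_innovations(self, conn_innovation: int) -> tuple[int, int, int]:
        """(new node id, in-connection innovation, out-connection innovation)
        for splitting the connection gene with the given innovation number."""
        if conn_innovation not in self._split_memo:
            node_id = self.next_node_id
            self.next_node_id += 1
            in_innov = self.next_innovation
            out_innov = self.next_innovation + 1
            self.next_innovation += 2
            self._split_memo[conn_innovation] = (node_id, in_innov, out_innov)
        return self._split_memo[conn_innovation]


def minimal_genome(n_inputs: int, n_outputs: int, registry: InnovationRegistry,
                   rng, weight_range: tuple[float, float] = (-1.0, 1.0),
                   key: int = 0) -> Genome:
    """The classic NEAT minimal start: every input connected to every output,
    weights drawn uniformly from ``weight_range``."""
    if n_inputs < 1 or n_outputs < 1:
        raise GenomeError("need at least one input and one output")
    nodes = [NodeGene(i, ROLE_INPUT) for i in range(n_inputs)]
    nodes += [NodeGene(n_inputs + j, ROLE_OUTPUT) for j in range(n_outputs)]
    registry.next_node_id = max(registry.next_node_id, n_inputs + n_outputs)
    lo, hi = weight_range
    conns = []
    for i in range(n_inputs):
        for j in range(n_outputs):
            innov = registry.connection_innovation(i, n_inputs + j)
            conns.append(ConnectionGene(innov, i, n_inputs + j,
                                        float(rng.uniform(lo, hi)), True))
    return Genome(nodes=nodes, connections=conns, key=key)
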