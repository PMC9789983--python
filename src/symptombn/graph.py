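"""Directed acyclic graphs and conditional probability tables.

A discrete Bayesian network over binary variables factorises the joint
distribution as ``P(x_1..x_n) = prod_i P(x_i | parents(x_i))``.  Variables
are coded present = 1 / absent = 0 and each CPT stores only
``P(child = 1 | parent configuration)``; the absent probability is the
complement, which keeps normalisation exact by construction.

Parent configurations are indexed by reading the parent values, in the
CPT's parent order, as binary digits with the first parent most
significant: for parents ``(a, b)`` the table rows are the configurations
``(1,1), (1,0), (0,1), (0,0)`` at indices 3, 2, 1, 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DAG",
    "CPT",
    "DiscreteBayesianNetwork",
    "is_acyclic",
    "topological_order",
    "joint_probability",
]


def _check_edges(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> None:
    declared = set(nodes)
    for u, v in edges:
        if u not in declared or v not in declared:
            raise ValueError(f"edge ({u!r}, {v!r}) references an undeclared node")
        if u == v:
            raise ValueError(f"self-loop on {u!r}")


def is_acyclic(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> bool:
    """True iff the directed graph (nodes, edges) contains no directed cycle.

    Raises ``ValueError`` if an edge endpoint is not a declared node.
    """
    edges = list(edges)
    _check_edges(nodes, edges)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.is_directed_acyclic_graph(g)


@dataclass(frozen=True)
class DAG:
    """A directed acyclic graph over named variables.

    ``nodes`` fixes the canonical variable order used for every
    deterministic tie-break downstream (topological sorting, search move
    enumeration, report row order).
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        edges = frozenset((str(u), str(v)) for u, v in edges)
        _check_edges(nodes, edges)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            cycle = nx.find_cycle(self.to_networkx())
            raise ValueError(f"graph contains a directed cycle: {cycle}")

    # -- structure queries -------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in canonical node order."""
        ps = {u for u, v in self.edges if v == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {v for u, v in self.edges if u == node}
        return tuple(n for n in self.nodes if n in cs)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- serialisation -----------------------------------------------------

    def to_dot(self) -> str:
        """DOT rendering of the graph (edges point parent -> child)."""
        lines = ["digraph symptoms {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.edges, key=lambda e: (self.nodes.index(e[0]), self.nodes.index(e[1]))):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def topological_order(dag: DAG) -> tuple[str, ...]:
    """A topological order of ``dag``, ties broken by canonical node order.

    Every parent precedes every child; re-running is bit-identical because
    the tie-break is the fixed position of each node in ``dag.nodes``.
    """
    idx = {n: i for i, n in enumerate(dag.nodes)}
    return tuple(nx.lexicographical_topological_sort(dag.to_networkx(), key=idx.get))


def parent_config_index(values: Sequence[int]) -> int:
    """Row index of a parent configuration (first parent most significant)."""
    idx = 0
    for v in values:
        idx = (idx << 1) | int(v)
    return idx


@dataclass(frozen=True)
class CPT:
    """P(child = present | each parent configuration) for one node.

    ``table`` has ``2 ** len(parents)`` entries; for a root node it is the
    single marginal probability of presence.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray = field(compare=False)

    def __init__(self, child: str, parents: Sequence[str], table):
        table = np.asarray(table, dtype=float).reshape(-1)
        parents = tuple(parents)
        if table.shape[0] != 2 ** len(parents):
            raise ValueError(
                f"CPT for {child!r}: expected {2 ** len(parents)} entries, got {table.shape[0]}"
            )
        if np.any(table < 0) or np.any(table > 1):
            raise ValueError(f"CPT for {child!r}: probabilities must lie in [0, 1]")
        table.setflags(write=False)
        object.__setattr__(self, "child", str(child))
        object.__setattr__(self, "parents", parents)
        object.__setattr__(self, "table", table)

    def p_present(self, parent_values: Sequence[int]) -> float:
        """P(child = 1) for one parent configuration (values in parent order)."""
        if len(parent_values) != len(self.parents):
            raise ValueError("parent configuration length mismatch")
        return float(self.table[parent_config_index(parent_values)])

    def config_key(self, row: int) -> str:
        """Human-readable key for table row ``row``, e.g. ``"fatigue=1,anxiety=0"``."""
        k = len(self.parents)
        bits = [(row >> (k - 1 - i)) & 1 for i in range(k)]
        return ",".join(f"{p}={b}" for p, b in zip(self.parents, bits))


class DiscreteBayesianNetwork:
    """A DAG plus one CPT per node, over binary (present/absent) variables."""

    def __init__(self, dag: DAG, cpts: Mapping[str, CPT] | Iterable[CPT]):
        if not isinstance(cpts, Mapping):
            cpts = {c.child: c for c in cpts}
        if set(cpts) != set(dag.nodes):
            missing = set(dag.nodes) - set(cpts)
            extra = set(cpts) - set(dag.nodes)
            raise ValueError(f"CPT/node mismatch (missing={missing}, extra={extra})")
        for node, cpt in cpts.items():
            if cpt.child != node:
                raise ValueError(f"CPT stored under {node!r} describes {cpt.child!r}")
            if cpt.parents != dag.parents(node):
                raise ValueError(
                    f"CPT parents {cpt.parents} for {node!r} disagree with DAG "
                    f"parents {dag.parents(node)}"
                )
        self.dag = dag
        self.cpts = dict(cpts)
        self.diagnostics: dict = {}

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    # -- probability -------------------------------------------------------

    def joint_probability(self, assignment: Mapping[str, int]) -> float:
        return joint_probability(self, assignment)

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "nodes": list(self.dag.nodes),
            "edges": sorted(
                self.dag.edges,
                key=lambda e: (self.dag.nodes.index(e[0]), self.dag.nodes.index(e[1])),
            ),
            "cpts": {
                node: {
                    "parents": list(cpt.parents),
                    "table": {cpt.config_key(r): float(cpt.table[r]) for r in range(len(cpt.table))},
                }
                for node, cpt in self.cpts.items()
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesianNetwork":
        doc = json.loads(text)
        dag = DAG(doc["nodes"], [tuple(e) for e in doc["edges"]])
        cpts = {}
        for node, spec in doc["cpts"].items():
            parents = tuple(spec["parents"])
            table = np.zeros(2 ** len(parents))
            for key, p in spec["table"].items():
                if key:
                    values = [int(part.split("=")[1]) for part in key.split(",")]
                else:
                    values = []
                table[parent_config_index(values)] = p
            cpts[node] = CPT(node, parents, table)
        return cls(dag, cpts)


def joint_probability(network: DiscreteBayesianNetwork, assignment: Mapping[str, int]) -> float:
    """Probability of one full assignment under the network factorisation.

    ``assignment`` must give a 0/1 value for every node; the result is the
    product over nodes of the CPT entry for the node's value given its
    parents' assigned values.
    """
    missing = set(network.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)}")
    p = 1.0
    for node in network.nodes:
        cpt = network.cpts[node]
        p1 = cpt.p_present([assignment[q] for q in cpt.parents])
        p *= p1 if assignment[node] else 1.0 - p1
    return p
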