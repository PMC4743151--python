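"""Causal Bayesian network data model.

A causal Bayesian network (CBN) is a Bayesian network whose edges are
asserted to point from cause to effect, which licenses interventional
semantics: forcing a node to a value is modelled by graph surgery rather
than by conditioning.  This module holds the in-memory model — the DAG
(:class:`Topology`), the discrete state spaces (:class:`StateSpace`), the
conditional probability tables (:class:`CPT`) and their bundle
(:class:`CausalNetwork`) — together with graph-level validity checks.

Nodes are named by strings.  States are canonically the integers
``0..k-1``; optional display labels (e.g. ``low/medium/high``) are
cosmetic and resolved back to indices on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CycleError",
    "Topology",
    "StateSpace",
    "CPT",
    "CausalNetwork",
    "topological_order",
    "is_ancestor",
    "validate_network",
]

#: Tolerance for CPT row normalisation checks.
ROW_SUM_TOL = 1e-9


class CycleError(ValueError):
    """Raised when a set of edges does not admit a topological order."""

    def __init__(self, nodes: Iterable[str]):
        self.nodes = frozenset(nodes)
        super().__init__(f"cycle detected involving nodes {sorted(self.nodes)}")


class Topology:
    """A directed acyclic graph over named nodes.

    Invariants enforced at construction: non-empty unique node names, no
    self-loops, all edge endpoints declared, and acyclicity.
    """

    __slots__ = ("_nodes", "_edges", "_graph")

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        node_tuple = tuple(sorted(set(nodes)))
        if any(not isinstance(n, str) or not n for n in node_tuple):
            raise ValueError("node names must be non-empty strings")
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        declared = set(node_tuple)
        for u, v in edge_set:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in declared or v not in declared:
                raise ValueError(f"edge ({u!r}, {v!r}) references an undeclared node")
        g = nx.DiGraph()
        g.add_nodes_from(node_tuple)
        g.add_edges_from(edge_set)
        if not nx.is_directed_acyclic_graph(g):
            offending = set()
            for comp in nx.strongly_connected_components(g):
                if len(comp) > 1:
                    offending |= comp
            raise CycleError(offending or declared)
        self._nodes = node_tuple
        self._edges = edge_set
        self._graph = g

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node names, sorted."""
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying :class:`networkx.DiGraph` (do not mutate)."""
        return self._graph

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of *node*, sorted lexicographically (the canonical CPT axis order)."""
        self._check(node)
        return tuple(sorted(self._graph.predecessors(node)))

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(self._graph.successors(node)))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._edges

    def with_edge_added(self, u: str, v: str) -> "Topology":
        if (u, v) in self._edges:
            raise ValueError(f"edge ({u!r}, {v!r}) already present")
        return Topology(self._nodes, self._edges | {(u, v)})

    def with_edge_removed(self, u: str, v: str) -> "Topology":
        if (u, v) not in self._edges:
            raise ValueError(f"edge ({u!r}, {v!r}) not present")
        return Topology(self._nodes, self._edges - {(u, v)})

    def _check(self, node: str) -> None:
        if node not in self._graph:
            raise KeyError(f"unknown node {node!r}")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Topology)
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Topology(nodes={len(self._nodes)}, edges={len(self._edges)})"


class StateSpace:
    """Ordered discrete state spaces, one per node.

    States are the integers ``0..k-1``; each may carry a display label
    (unique within its node).  Labels default to ``"0", "1", ...``.
    """

    def __init__(self, labels: Mapping[str, Sequence[str]]):
        self._labels: dict[str, tuple[str, ...]] = {}
        for node, labs in labels.items():
            labs = tuple(str(l) for l in labs)
            if len(labs) < 2:
                raise ValueError(f"node {node!r} needs at least 2 states, got {len(labs)}")
            if len(set(labs)) != len(labs):
                raise ValueError(f"duplicate state labels for node {node!r}")
            self._labels[node] = labs

    @classmethod
    def from_cards(cls, cards: Mapping[str, int]) -> "StateSpace":
        """Build from plain state counts; labels are the state indices."""
        return cls({n: tuple(str(i) for i in range(k)) for n, k in cards.items()})

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._labels))

    def card(self, node: str) -> int:
        """Number of states of *node*."""
        return len(self._labels[node])

    def labels(self, node: str) -> tuple[str, ...]:
        return self._labels[node]

    def index(self, node: str, token: str | int) -> int:
        """Resolve a state index or display label to an index.

        Labels are matched case-sensitively before integer parsing so a
        numeric-looking label wins over its positional reading.
        """
        labs = self._labels[node]
        if isinstance(token, str) and token in labs:
            return labs.index(token)
        try:
            idx = int(token)
        except (TypeError, ValueError):
            raise ValueError(f"unknown state {token!r} for node {node!r}") from None
        if not 0 <= idx < len(labs):
            raise ValueError(
                f"state {idx} out of range for node {node!r} (has {len(labs)} states)"
            )
        return idx

    def __contains__(self, node: str) -> bool:
        return node in self._labels

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StateSpace) and self._labels == other._labels


@dataclass(frozen=True)
class CPT:
    """Conditional probability table P(child | parents).

    ``table`` has one axis per parent (in ``parents`` order) followed by
    the child axis; entry ``table[p1, ..., pk, c]`` is
    P(child = c | parents = (p1, ..., pk)).
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(self.parents))
        arr = np.asarray(self.table, dtype=float)
        if arr.ndim != len(self.parents) + 1:
            raise ValueError(
                f"CPT for {self.child!r}: table has {arr.ndim} axes, "
                f"expected {len(self.parents) + 1}"
            )
        object.__setattr__(self, "table", arr)

    def problems(self) -> list[str]:
        """Invariant violations, as human-readable strings (empty if valid)."""
        out: list[str] = []
        arr = self.table
        if np.any(arr < -ROW_SUM_TOL) or np.any(arr > 1 + ROW_SUM_TOL):
            out.append(f"CPT for {self.child!r}: entries outside [0, 1]")
        rows = arr.reshape(-1, arr.shape[-1])
        sums = rows.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > 1e-9)[0]
        for i in bad[:10]:
            config = np.unravel_index(i, arr.shape[:-1]) if self.parents else ()
            out.append(
                f"CPT for {self.child!r}: row for parent configuration "
                f"{tuple(int(c) for c in config)} sums to {sums[i]:.6g}, not 1"
            )
        return out


@dataclass(frozen=True)
class CausalNetwork:
    """A DAG, per-node state spaces, one CPT per node, and optionally the
    discretised training data it was fitted from.

    Retained training data (variables x samples, ``NaN`` marking missing
    entries) is what allows edge interventions to re-estimate the affected
    CPT instead of guessing it.
    """

    topology: Topology
    states: StateSpace
    cpts: Mapping[str, CPT]
    training_data: Optional[pd.DataFrame] = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "cpts", dict(self.cpts))

    def card(self, node: str) -> int:
        return self.states.card(node)

    def parents(self, node: str) -> tuple[str, ...]:
        return self.topology.parents(node)

    def cpt(self, node: str) -> CPT:
        return self.cpts[node]

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.topology.nodes

    def with_cpts(self, updates: Mapping[str, CPT]) -> "CausalNetwork":
        new = dict(self.cpts)
        new.update(updates)
        return replace(self, cpts=new)

    def with_training_data(self, data: Optional[pd.DataFrame]) -> "CausalNetwork":
        return replace(self, training_data=data)


def topological_order(t: Topology) -> list[str]:
    """A topological order of *t*, ties broken by lexicographic node name.

    Deterministic: the same topology always yields the same order.
    """
    return list(nx.lexicographical_topological_sort(t.graph))


def is_ancestor(t: Topology, a: str, b: str) -> bool:
    """True iff a directed path ``a -> ... -> b`` exists.

    A node is not its own ancestor: ``is_ancestor(t, x, x)`` is False.
    """
    t._check(a)
    t._check(b)
    if a == b:
        return False
    return b in nx.descendants(t.graph, a)


def validate_network(n: CausalNetwork) -> list[str]:
    """Report every violated network invariant (empty list iff valid).

    Checks: every node has a state space and a CPT; CPT parent lists
    mirror the graph; table shapes match the state spaces; rows are
    normalised probability distributions.
    """
    report: list[str] = []
    for node in n.topology.nodes:
        if node not in n.states:
            report.append(f"node {node!r}: no state space declared")
            continue
        cpt = n.cpts.get(node)
        if cpt is None:
            report.append(f"node {node!r}: missing CPT")
            continue
        graph_parents = n.topology.parents(node)
        if tuple(cpt.parents) != graph_parents:
            report.append(
                f"node {node!r}: parent mismatch (CPT has {list(cpt.parents)}, "
                f"graph has {list(graph_parents)})"
            )
            continue
        expected_shape = tuple(n.states.card(p) for p in cpt.parents) + (
            n.states.card(node),
        )
        if cpt.table.shape != expected_shape:
            report.append(
                f"node {node!r}: CPT shape {cpt.table.shape} does not match "
                f"state spaces {expected_shape}"
            )
            continue
        report.extend(cpt.problems())
    for extra in set(n.cpts) - set(n.topology.nodes):
        report.append(f"CPT for undeclared node {extra!r}")
    return report
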