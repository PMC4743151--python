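"""Graph surgery for interventions and twin networks for counterfactuals.

A do-intervention ``do(X=x)`` models an external manipulation: the
mutilated network drops every edge into X and fixes X at x, so the
downstream effect of X is kept while all inference *into* X is cut.
This is exactly what distinguishes P(Y | do(X=x)) from P(Y | X=x).

Edge interventions add or remove a causal arc; the affected child's CPT
is re-estimated from the network's retained training data when present
(restricted EM over the family when relevant entries are missing).

Counterfactuals ("given that we observed e, what if X had been x?") use
the twin-network construction: the factual world keeps the original
network, the counterfactual world copies only the intervened nodes and
their descendants, and every other node is shared between the worlds so
the factual evidence informs the counterfactual prediction.

Semantic caveat: the model stores CPTs, not structural equations with
explicit exogenous noise.  Shared non-descendants carry all the
evidence coupling the two worlds, but each copied node's own stochastic
response is redrawn independently given its parents.  This is the
strongest coupling derivable from CPTs alone; response-function
counterfactuals that share noise between worlds are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .factors import Factor
from .inference import variable_elimination
from .learning import _family_posterior, _unique_patterns
from .model import CPT, CausalNetwork, StateSpace, Topology

__all__ = [
    "Intervention",
    "TwinNetwork",
    "apply_do",
    "apply_edge_intervention",
    "apply_interventions",
    "build_twin_network",
    "counterfactual_query",
]

COUNTERFACTUAL_SUFFIX = "*"


@dataclass(frozen=True)
class Intervention:
    """One intervention: a do-assignment or an edge addition/removal."""

    kind: Literal["do_assignment", "add_edge", "remove_edge"]
    node: Optional[str] = None
    state: Optional[int] = None
    source: Optional[str] = None
    target: Optional[str] = None

    @classmethod
    def do(cls, node: str, state: int) -> "Intervention":
        return cls(kind="do_assignment", node=node, state=int(state))

    @classmethod
    def add_edge(cls, source: str, target: str) -> "Intervention":
        return cls(kind="add_edge", source=source, target=target)

    @classmethod
    def remove_edge(cls, source: str, target: str) -> "Intervention":
        return cls(kind="remove_edge", source=source, target=target)

    @property
    def affected_child(self) -> str:
        return self.node if self.kind == "do_assignment" else self.target


def apply_do(
    net: CausalNetwork, assignments: Sequence[tuple[str, int]]
) -> CausalNetwork:
    """Mutilate the network: intervened nodes lose all incoming edges and
    get point-mass CPTs on the assigned state; everything else is untouched."""
    assignments = list(assignments)
    nodes = [n for n, _ in assignments]
    if len(set(nodes)) != len(nodes):
        raise ValueError("a node appears more than once in the do-assignments")
    for node, state in assignments:
        if node not in net.topology.nodes:
            raise KeyError(f"unknown node {node!r}")
        if not 0 <= int(state) < net.card(node):
            raise ValueError(f"state {state} out of range for {node!r}")
    intervened = set(nodes)
    edges = {(u, v) for u, v in net.topology.edges if v not in intervened}
    topology = Topology(net.topology.nodes, edges)
    cpts = dict(net.cpts)
    for node, state in assignments:
        table = np.zeros(net.card(node))
        table[int(state)] = 1.0
        cpts[node] = CPT(child=node, parents=(), table=table)
    return CausalNetwork(
        topology=topology,
        states=net.states,
        cpts=cpts,
        training_data=net.training_data,
    )


def _refit_family(
    net: CausalNetwork,
    child: str,
    data: pd.DataFrame,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> CPT:
    """Re-estimate one family's CPT from data, all other CPTs held fixed.

    With the family's columns fully observed this is a single expected-
    counts pass equal to plain conditional frequencies; with missing
    entries it iterates EM updates of the one CPT to convergence.
    """
    family = net.parents(child) + (child,)
    shape = tuple(net.card(v) for v in family)
    patterns = _unique_patterns(net, data)
    current = net
    prev: Optional[np.ndarray] = None
    for _ in range(max_iter):
        counts = np.zeros(shape)
        for evidence, count in patterns:
            post = _family_posterior(current, family, evidence)
            if post is not None:
                counts += count * post
        totals = counts.sum(axis=-1, keepdims=True)
        k = shape[-1]
        probs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 1.0 / k)
        cpt = CPT(child=child, parents=net.parents(child), table=probs)
        if prev is not None and np.abs(probs - prev).max() < tol:
            return cpt
        prev = probs
        current = current.with_cpts({child: cpt})
    return cpt


def apply_edge_intervention(
    net: CausalNetwork, kind: Literal["add", "remove"], source: str, target: str
) -> CausalNetwork:
    """Add or remove the causal arc ``source -> target``.

    The child's CPT over the new parent set is re-estimated from the
    retained training data when available.  Without data: an added
    parent's axis replicates the existing CPT (initial independence); a
    removed parent is averaged out weighted by its marginal.
    """
    for n in (source, target):
        if n not in net.topology.nodes:
            raise KeyError(f"unknown node {n!r}")
    if kind == "add":
        topology = net.topology.with_edge_added(source, target)
    elif kind == "remove":
        topology = net.topology.with_edge_removed(source, target)
    else:
        raise ValueError(f"unknown edge intervention kind {kind!r}")
    new_parents = topology.parents(target)
    skeleton = CausalNetwork(
        topology=topology,
        states=net.states,
        cpts=dict(net.cpts),
        training_data=net.training_data,
    )
    if net.training_data is not None:
        # other families are untouched; only the child needs re-estimation
        base = dict(net.cpts)
        base[target] = CPT(
            child=target,
            parents=new_parents,
            table=np.full(
                tuple(net.card(p) for p in new_parents) + (net.card(target),),
                1.0 / net.card(target),
            ),
        )
        skeleton = CausalNetwork(
            topology=topology,
            states=net.states,
            cpts=base,
            training_data=net.training_data,
        )
        new_cpt = _refit_family(skeleton, target, net.training_data)
        return skeleton.with_cpts({target: new_cpt})

    old_cpt = net.cpt(target)
    if kind == "add":
        pos = new_parents.index(source)
        table = np.expand_dims(old_cpt.table, axis=pos)
        table = np.broadcast_to(
            table,
            tuple(net.card(p) for p in new_parents) + (net.card(target),),
        ).copy()
    else:
        old_parents = net.parents(target)
        pos = old_parents.index(source)
        marginal = variable_elimination(net, [source]).values
        weights = marginal.reshape(
            tuple(net.card(source) if i == pos else 1 for i in range(len(old_parents)))
            + (1,)
        )
        table = (old_cpt.table * weights).sum(axis=pos)
    new_cpt = CPT(child=target, parents=new_parents, table=table)
    return skeleton.with_cpts({target: new_cpt})


def apply_interventions(
    net: CausalNetwork, interventions: Sequence[Intervention]
) -> CausalNetwork:
    """Apply edge interventions in order, then all do-assignments."""
    current = net
    dos: list[tuple[str, int]] = []
    for iv in interventions:
        if iv.kind == "do_assignment":
            dos.append((iv.node, iv.state))
        elif iv.kind == "add_edge":
            current = apply_edge_intervention(current, "add", iv.source, iv.target)
        else:
            current = apply_edge_intervention(current, "remove", iv.source, iv.target)
    if dos:
        current = apply_do(current, dos)
    return current


@dataclass(frozen=True)
class TwinNetwork:
    """A factual and a counterfactual world in one network.

    ``mapping[name] = (factual_name, counterfactual_name)``; the two
    coincide for nodes shared between the worlds.
    """

    network: CausalNetwork
    mapping: Mapping[str, tuple[str, str]]

    def factual(self, node: str) -> str:
        return self.mapping[node][0]

    def counterfactual(self, node: str) -> str:
        return self.mapping[node][1]


def build_twin_network(
    net: CausalNetwork, interventions: Sequence[Intervention]
) -> TwinNetwork:
    """Construct the twin network for the given interventions.

    Nodes that are not descendants of an intervened node in the
    post-intervention graph are shared between the worlds; each
    intervened node and descendant gets a counterfactual copy (suffixed
    ``*``) whose parents are the counterfactual counterparts of its
    post-intervention parents and whose CPT is the post-intervention
    CPT.  Do-assignments act only on the copies.
    """
    # counterfactual-world network after edge interventions (CPTs re-estimated)
    post = net
    affected: set[str] = set()
    dos: list[tuple[str, int]] = []
    for iv in interventions:
        if iv.kind == "do_assignment":
            dos.append((iv.node, iv.state))
            affected.add(iv.node)
        elif iv.kind == "add_edge":
            post = apply_edge_intervention(post, "add", iv.source, iv.target)
            affected.add(iv.target)
        else:
            post = apply_edge_intervention(post, "remove", iv.source, iv.target)
            affected.add(iv.target)
    for node, state in dos:
        if node not in net.topology.nodes:
            raise KeyError(f"unknown node {node!r}")
        if not 0 <= int(state) < net.card(node):
            raise ValueError(f"state {state} out of range for {node!r}")

    g = post.topology.graph.copy()
    g.remove_edges_from([(u, v) for u, v in list(g.edges) if v in {n for n, _ in dos}])
    copied: set[str] = set(affected)
    for node in affected:
        copied |= nx.descendants(g, node)

    def cf_name(node: str) -> str:
        return node + COUNTERFACTUAL_SUFFIX if node in copied else node

    nodes = list(net.topology.nodes) + [n + COUNTERFACTUAL_SUFFIX for n in sorted(copied)]
    edges = set(net.topology.edges)
    for child in copied:
        for parent in g.predecessors(child):
            edges.add((cf_name(parent), child + COUNTERFACTUAL_SUFFIX))
    labels = {n: net.states.labels(n) for n in net.topology.nodes}
    for n in copied:
        labels[n + COUNTERFACTUAL_SUFFIX] = net.states.labels(n)
    cpts = dict(net.cpts)
    do_nodes = {n for n, _ in dos}
    for n in copied:
        if n in do_nodes:
            continue  # overwritten below by the point-mass CPT
        src = post.cpt(n)
        cpts[n + COUNTERFACTUAL_SUFFIX] = CPT(
            child=n + COUNTERFACTUAL_SUFFIX,
            parents=tuple(sorted(cf_name(p) for p in src.parents)),
            table=_reorder_parent_axes(src, cf_name),
        )
    twin = CausalNetwork(
        topology=Topology(nodes, edges),
        states=StateSpace(labels),
        cpts=cpts,
        training_data=None,
    )
    if dos:
        twin = apply_do(
            twin, [(n + COUNTERFACTUAL_SUFFIX, s) for n, s in dos]
        )
    mapping = {
        n: (n, n + COUNTERFACTUAL_SUFFIX if n in copied else n)
        for n in net.topology.nodes
    }
    return TwinNetwork(network=twin, mapping=mapping)


def _reorder_parent_axes(cpt: CPT, rename) -> np.ndarray:
    """Permute a CPT's parent axes so renamed parents stay sorted."""
    renamed = [rename(p) for p in cpt.parents]
    order = sorted(range(len(renamed)), key=lambda i: renamed[i])
    return cpt.table.transpose(tuple(order) + (len(renamed),))


def counterfactual_query(
    net: CausalNetwork,
    targets: Sequence[str],
    factual_evidence,
    interventions: Sequence[Intervention],
) -> Factor:
    """P(targets in the intervened world | factual evidence).

    The factual evidence is asserted on the factual/shared nodes of the
    twin network; the targets are read off their counterfactual
    counterparts.  The returned factor's scope uses the original node
    names.
    """
    if not targets:
        raise ValueError("targets must be nonempty")
    twin = build_twin_network(net, interventions)
    ev = dict(factual_evidence or {})
    cf_targets = [twin.counterfactual(t) for t in targets]
    factor = variable_elimination(twin.network, cf_targets, ev)
    factor.scope = list(targets)
    return factor
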