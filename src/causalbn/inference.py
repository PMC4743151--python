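"""Exact posterior inference by variable elimination.

Queries P(targets | evidence) are answered exactly: every CPT becomes a
factor, evidence is asserted by zeroing inconsistent rows, and all
non-target variables are summed out along a min-fill elimination order
(ties broken lexicographically so results are reproducible down to the
floating-point operation order).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from .factors import Factor
from .model import CausalNetwork

__all__ = [
    "InconsistentEvidenceError",
    "variable_elimination",
    "posterior_probability",
    "argmax_posterior",
    "evidence_probability",
    "min_fill_order",
]


class InconsistentEvidenceError(ValueError):
    """The asserted evidence has probability zero under the network."""

    def __init__(self, evidence: Mapping[str, int]):
        self.evidence = dict(evidence)
        items = ", ".join(f"{k}={v}" for k, v in sorted(self.evidence.items()))
        super().__init__(f"evidence has probability 0: {{{items}}}")


def _as_evidence(evidence) -> dict[str, int]:
    if evidence is None:
        return {}
    items = evidence.items() if isinstance(evidence, Mapping) else evidence
    out: dict[str, int] = {}
    for node, state in items:
        if node in out:
            raise ValueError(f"duplicate evidence for node {node!r}")
        out[node] = int(state)
    return out


def min_fill_order(
    scopes: Iterable[Sequence[str]],
    elim_vars: Iterable[str],
    reverse_ties: bool = False,
) -> list[str]:
    """Elimination order by the min-fill heuristic.

    At each step the variable whose elimination adds the fewest fill-in
    edges to the interaction graph is chosen; ties are broken by
    lexicographic name (reversed when *reverse_ties*, which must not
    change any inference result — only cost).
    """
    neighbors: dict[str, set[str]] = {}
    for scope in scopes:
        for v in scope:
            neighbors.setdefault(v, set()).update(u for u in scope if u != v)
    remaining = set(elim_vars)
    order: list[str] = []
    while remaining:

        def fill(v: str) -> int:
            nbrs = [u for u in neighbors.get(v, ()) if u in neighbors]
            return sum(
                1
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1 :]
                if b not in neighbors[a]
            )

        key = (lambda v: (fill(v), tuple(-ord(c) for c in v))) if reverse_ties else (
            lambda v: (fill(v), v)
        )
        best = min(remaining, key=key)
        nbrs = [u for u in neighbors.get(best, ()) if u in neighbors]
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                neighbors[a].add(b)
                neighbors[b].add(a)
        for u in nbrs:
            neighbors[u].discard(best)
        neighbors.pop(best, None)
        remaining.discard(best)
        order.append(best)
    return order


def _eliminate(factors: list[Factor], order: Sequence[str]) -> list[Factor]:
    for var in order:
        related = [f for f in factors if var in f.scope]
        if not related:
            continue
        factors = [f for f in factors if var not in f.scope]
        prod = related[0]
        for f in related[1:]:
            prod = prod.product(f)
        factors.append(prod.marginalize(var))
    return factors


def variable_elimination(
    net: CausalNetwork,
    targets: Sequence[str],
    evidence=None,
    *,
    _reverse_ties: bool = False,
) -> Factor:
    """Joint posterior P(targets | evidence), normalised to sum 1.

    Parameters
    ----------
    net
        A valid discrete causal network.
    targets
        Non-empty list of query nodes, disjoint from the evidence.
    evidence
        Mapping or (node, state) pairs of observed states.

    Raises
    ------
    InconsistentEvidenceError
        If the evidence has probability zero.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("targets must be nonempty")
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate target nodes")
    ev = _as_evidence(evidence)
    for node in targets:
        if node not in net.topology.nodes:
            raise KeyError(f"unknown node {node!r}")
        if node in ev:
            raise ValueError(f"target {node!r} also appears in the evidence")
    for node, state in ev.items():
        if node not in net.topology.nodes:
            raise KeyError(f"unknown evidence node {node!r}")
        if not 0 <= state < net.card(node):
            raise ValueError(f"evidence state {state} out of range for {node!r}")

    factors = [Factor.from_cpt(net, n).reduce(ev) for n in net.topology.nodes]
    elim = [v for v in net.topology.nodes if v not in targets]
    order = min_fill_order(
        [f.scope for f in factors], elim, reverse_ties=_reverse_ties
    )
    remaining = _eliminate(factors, order)
    result = remaining[0]
    for f in remaining[1:]:
        result = result.product(f)
    total = result.total()
    if not total > 0:
        raise InconsistentEvidenceError(ev)
    return result.transpose(targets).normalized()


def posterior_probability(
    net: CausalNetwork,
    target: Sequence[tuple[str, int]],
    evidence=None,
) -> float:
    """Joint posterior probability of the target assignments given evidence."""
    assignments = list(target)
    nodes = [n for n, _ in assignments]
    factor = variable_elimination(net, nodes, evidence)
    idx = tuple(int(s) for _, s in assignments)
    for (node, state), card in zip(assignments, factor.cards):
        if not 0 <= int(state) < card:
            raise ValueError(f"state {state} out of range for {node!r}")
    return float(factor.values[idx])


def argmax_posterior(
    net: CausalNetwork,
    target: str,
    evidence=None,
) -> tuple[int, float]:
    """Most likely state of *target* given evidence, with its probability.

    Ties are broken towards the smallest state index.
    """
    factor = variable_elimination(net, [target], evidence)
    state = int(factor.values.argmax())
    return state, float(factor.values[state])


def evidence_probability(net: CausalNetwork, evidence=None) -> float:
    """P(evidence) under the network; 1.0 for empty evidence."""
    ev = _as_evidence(evidence)
    if not ev:
        return 1.0
    for node, state in ev.items():
        if node not in net.topology.nodes:
            raise KeyError(f"unknown evidence node {node!r}")
        if not 0 <= state < net.card(node):
            raise ValueError(f"evidence state {state} out of range for {node!r}")
    factors = [Factor.from_cpt(net, n).reduce(ev) for n in net.topology.nodes]
    order = min_fill_order([f.scope for f in factors], net.topology.nodes)
    remaining = _eliminate(factors, order)
    return float(math.prod(f.total() for f in remaining))
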