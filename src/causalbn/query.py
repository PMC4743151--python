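"""The hypothesis query language: parser, validator, evaluator.

Grammar (tokens are whitespace-separated; ``(``, ``)``, ``=``, ``?``,
``|``, ``!``, ``+``, ``-`` also self-delimit)::

    query  := "?" target {target} [ "|" evid {evid} ] [ "!" ivn {ivn} ]
    target := NODE "=" STATE | "argmax" "(" NODE ")"
    evid   := NODE "=" STATE
    ivn    := "do" NODE "=" STATE | "+" NODE NODE | "-" NODE NODE

``?`` introduces the targets, ``|`` the conditioning evidence, and ``!``
the interventions, e.g. ``? argmax(AKT) ! do ERK = 2``.  STATE is an
integer state index or a display label.  ``do`` and ``argmax`` are
reserved words and cannot name nodes.

Dispatch: a query with interventions only is evaluated on the mutilated
/ modified network; evidence only (or neither) is plain posterior
inference; a query that both conditions and intervenes is a
counterfactual and is evaluated on the twin network (``worlds="single"``
forces evidence and interventions into one world instead).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

from .inference import variable_elimination
from .interventions import (
    Intervention,
    apply_interventions,
    build_twin_network,
)
from .model import CausalNetwork, is_ancestor

__all__ = [
    "QuerySyntaxError",
    "AssignTarget",
    "ArgmaxTarget",
    "Query",
    "QueryResult",
    "parse_query",
    "unparse_query",
    "validate_query",
    "evaluate_query",
]

RESERVED = {"do", "argmax"}


class QuerySyntaxError(ValueError):
    """Syntax error with the character position of the offending token."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


@dataclass(frozen=True)
class AssignTarget:
    node: str
    state: str  # raw token; resolved against the state space at evaluation


@dataclass(frozen=True)
class ArgmaxTarget:
    node: str


Target = Union[AssignTarget, ArgmaxTarget]


@dataclass(frozen=True)
class Query:
    """Parsed query AST."""

    targets: tuple[Target, ...]
    evidence: tuple[tuple[str, str], ...] = ()
    interventions: tuple[Intervention, ...] = ()

    # intervention payloads keep raw state tokens in ``state`` via str


@dataclass
class QueryResult:
    """Evaluation outcome.

    ``argmax`` holds one ``(node, state, probability)`` triple per
    argmax target; ``joint_probability`` is the joint posterior of all
    assignment targets (None if the query has none).
    """

    query: str
    argmax: list[tuple[str, int, float]] = field(default_factory=list)
    joint_probability: Optional[float] = None


_TOKEN_RE = re.compile(r"[?|!=()+\-]|[^\s?|!=()+\-]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append((m.group(), m.start()))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def here(self) -> int:
        if self.pos < len(self.tokens):
            return self.tokens[self.pos][1]
        return len(self.text)

    def next(self) -> str:
        if self.pos >= len(self.tokens):
            raise QuerySyntaxError("unexpected end of query", len(self.text))
        tok, _ = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, token: str) -> None:
        at = self.here()
        got = self.next()
        if got != token:
            raise QuerySyntaxError(f"expected {token!r}, got {got!r}", at)

    def node(self) -> str:
        at = self.here()
        tok = self.next()
        if tok in RESERVED or not re.fullmatch(r"[^\s?|!=()+\-]+", tok):
            raise QuerySyntaxError(f"expected a node name, got {tok!r}", at)
        return tok

    def state(self) -> str:
        at = self.here()
        tok = self.next()
        if tok in {"?", "|", "!", "=", "(", ")", "+", "-"}:
            raise QuerySyntaxError(f"expected a state, got {tok!r}", at)
        return tok


def parse_query(text: str) -> Query:
    """Parse the query language into an AST.

    Raises :class:`QuerySyntaxError` (with the character position) on
    malformed input, including a structurally valid but empty target
    list.
    """
    p = _Parser(text)
    p.expect("?")
    targets: list[Target] = []
    while p.peek() is not None and p.peek() not in ("|", "!"):
        if p.peek() == "argmax":
            p.next()
            p.expect("(")
            node = p.node()
            p.expect(")")
            targets.append(ArgmaxTarget(node=node))
        else:
            node = p.node()
            p.expect("=")
            targets.append(AssignTarget(node=node, state=p.state()))
    if not targets:
        raise QuerySyntaxError("query has no targets", p.here())
    evidence: list[tuple[str, str]] = []
    if p.peek() == "|":
        p.next()
        while p.peek() is not None and p.peek() != "!":
            node = p.node()
            p.expect("=")
            evidence.append((node, p.state()))
        if not evidence:
            raise QuerySyntaxError("'|' must be followed by evidence", p.here())
    interventions: list[Intervention] = []
    if p.peek() == "!":
        p.next()
        while p.peek() is not None:
            at = p.here()
            tok = p.next()
            if tok == "do":
                node = p.node()
                p.expect("=")
                interventions.append(Intervention(kind="do_assignment", node=node, state=p.state()))
            elif tok == "+":
                interventions.append(Intervention.add_edge(p.node(), p.node()))
            elif tok == "-":
                interventions.append(Intervention.remove_edge(p.node(), p.node()))
            else:
                raise QuerySyntaxError(
                    f"expected 'do', '+' or '-', got {tok!r}", at
                )
        if not interventions:
            raise QuerySyntaxError("'!' must be followed by interventions", p.here())
    if p.peek() is not None:
        raise QuerySyntaxError(f"unexpected token {p.peek()!r}", p.here())
    do_nodes = [iv.node for iv in interventions if iv.kind == "do_assignment"]
    if len(set(do_nodes)) != len(do_nodes):
        raise QuerySyntaxError("a node appears more than once as a do-target", 0)
    ev_nodes = [n for n, _ in evidence]
    if len(set(ev_nodes)) != len(ev_nodes):
        raise QuerySyntaxError("a node appears more than once in the evidence", 0)
    return Query(
        targets=tuple(targets),
        evidence=tuple(evidence),
        interventions=tuple(interventions),
    )


def unparse_query(q: Query) -> str:
    """Render an AST back to the surface syntax (inverse of parsing)."""
    parts = ["?"]
    for t in q.targets:
        if isinstance(t, ArgmaxTarget):
            parts.append(f"argmax({t.node})")
        else:
            parts.append(f"{t.node} = {t.state}")
    if q.evidence:
        parts.append("|")
        parts.extend(f"{n} = {s}" for n, s in q.evidence)
    if q.interventions:
        parts.append("!")
        for iv in q.interventions:
            if iv.kind == "do_assignment":
                parts.append(f"do {iv.node} = {iv.state}")
            elif iv.kind == "add_edge":
                parts.append(f"+ {iv.source} {iv.target}")
            else:
                parts.append(f"- {iv.source} {iv.target}")
    return " ".join(parts)


def validate_query(q: Query, net: CausalNetwork) -> list[str]:
    """Report everything that would make the query unevaluable
    (unknown nodes, out-of-range states, cycle-creating edge additions,
    removals of absent edges); empty list iff evaluable."""
    report: list[str] = []
    known = set(net.topology.nodes)

    def check_node(node: str, where: str) -> bool:
        if node not in known:
            report.append(f"unknown node {node!r} in {where}")
            return False
        return True

    def check_state(node: str, token: str, where: str) -> None:
        try:
            net.states.index(node, token)
        except ValueError as exc:
            report.append(f"{where}: {exc}")

    for t in q.targets:
        if isinstance(t, ArgmaxTarget):
            check_node(t.node, "argmax target")
        else:
            if check_node(t.node, "target"):
                check_state(t.node, t.state, "target")
    for node, state in q.evidence:
        if check_node(node, "evidence"):
            check_state(node, state, "evidence")
    topo = net.topology
    for iv in q.interventions:
        if iv.kind == "do_assignment":
            if check_node(iv.node, "do-intervention"):
                check_state(iv.node, iv.state, "do-intervention")
        else:
            ok = check_node(iv.source, "edge intervention") and check_node(
                iv.target, "edge intervention"
            )
            if not ok:
                continue
            if iv.kind == "add_edge":
                if topo.has_edge(iv.source, iv.target):
                    report.append(
                        f"edge {iv.source}->{iv.target} already present"
                    )
                elif iv.source == iv.target or is_ancestor(topo, iv.target, iv.source):
                    report.append(
                        f"adding edge {iv.source}->{iv.target} would create a cycle"
                    )
                else:
                    topo = topo.with_edge_added(iv.source, iv.target)
            else:
                if not topo.has_edge(iv.source, iv.target):
                    report.append(f"edge {iv.source}->{iv.target} not present")
                else:
                    topo = topo.with_edge_removed(iv.source, iv.target)
    target_nodes = [
        t.node for t in q.targets
    ]
    if len(set(target_nodes)) != len(target_nodes):
        report.append("duplicate target nodes")
    overlap = set(target_nodes) & {n for n, _ in q.evidence}
    if overlap and not q.interventions:
        # with interventions the query is counterfactual: the target lives
        # in the intervened world, the evidence in the factual one
        report.append(f"targets also appear in the evidence: {sorted(overlap)}")
    return report


def _resolve_interventions(
    q: Query, net: CausalNetwork
) -> list[Intervention]:
    out = []
    for iv in q.interventions:
        if iv.kind == "do_assignment":
            out.append(
                Intervention.do(iv.node, net.states.index(iv.node, iv.state))
            )
        else:
            out.append(iv)
    return out


def evaluate_query(
    q: Query,
    net: CausalNetwork,
    worlds: Literal["twin", "single"] = "twin",
) -> QueryResult:
    """Evaluate a validated query on the network.

    With both evidence and interventions the query is counterfactual and
    evaluated on the twin network (unless ``worlds="single"``, which
    conditions and intervenes in one world).
    """
    problems = validate_query(q, net)
    if problems:
        raise ValueError("invalid query: " + "; ".join(problems))
    evidence = {n: net.states.index(n, s) for n, s in q.evidence}
    interventions = _resolve_interventions(q, net)

    if interventions and evidence and worlds == "twin":
        twin = build_twin_network(net, interventions)
        work = twin.network
        rename = {n: twin.counterfactual(n) for n in net.topology.nodes}
        ev = evidence  # factual evidence stays on the original names
    elif interventions:
        # covers both interventions-only queries and single-world semantics
        work = apply_interventions(net, interventions)
        ev = evidence
        rename = {n: n for n in net.topology.nodes}
    else:
        work = net
        ev = evidence
        rename = {n: n for n in net.topology.nodes}

    result = QueryResult(query=unparse_query(q))
    for t in q.targets:
        if isinstance(t, ArgmaxTarget):
            factor = variable_elimination(work, [rename[t.node]], ev)
            state = int(factor.values.argmax())
            result.argmax.append((t.node, state, float(factor.values[state])))
    assigns = [t for t in q.targets if isinstance(t, AssignTarget)]
    if assigns:
        factor = variable_elimination(
            work, [rename[t.node] for t in assigns], ev
        )
        idx = tuple(net.states.index(t.node, t.state) for t in assigns)
        result.joint_probability = float(factor.values[idx])
    return result
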