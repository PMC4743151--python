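"""Readers and writers for topologies, observation matrices,
discretisation specs, and learned parameters.

Topologies come in two plain-text dialects: SIF (simple interaction
format, ``source relation target1 [target2 ...]`` per line) and TGF
(trivial graph format, a node section and an edge section separated by
``#``).  Observations are a whitespace-separated matrix with variables
as rows and samples as columns; ``NA``/``na``/``nan`` (case-insensitive)
mark missing entries.  Discretisation specs are JSON.
"""

from __future__ import annotations

import io as _io
import json
import re

import numpy as np
import pandas as pd

from .discretise import METHODS, DiscretisationSpec, MethodSpec
from .model import CPT, CausalNetwork, Topology

__all__ = [
    "read_sif",
    "write_sif",
    "read_tgf",
    "write_tgf",
    "read_data_matrix",
    "write_data_matrix",
    "read_discretisation_spec",
    "write_parameters",
    "parse_parameters",
]

_MISSING_TOKENS = {"na", "nan"}


def read_sif(text: str) -> Topology:
    """Parse a simple-interaction-format topology.

    Each line is ``source relation target [target ...]``; the relation
    token is read and ignored and one edge ``source -> target_i`` is
    created per target.  A single-token line declares an isolated node.
    Blank lines are skipped.
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) == 1:
            nodes.add(tokens[0])
            continue
        if len(tokens) == 2:
            raise ValueError(
                f"SIF line {lineno}: source and relation but no target"
            )
        source, _relation, *targets = tokens
        nodes.add(source)
        for t in targets:
            nodes.add(t)
            edges.add((source, t))
    return Topology(nodes, edges)


def write_sif(t: Topology, relation: str = "interacts") -> str:
    """Serialise a topology to SIF; round-trips through :func:`read_sif`."""
    lines = []
    linked: set[str] = set()
    for u, v in sorted(t.edges):
        lines.append(f"{u} {relation} {v}")
        linked.add(u)
        linked.add(v)
    for n in t.nodes:
        if n not in linked:
            lines.append(n)
    return "\n".join(lines) + "\n"


def read_tgf(text: str) -> Topology:
    """Parse a trivial-graph-format topology.

    Node lines are ``id [label]`` (the label, if present, becomes the
    node name, otherwise the id itself); a line holding ``#`` separates
    the node section from edge lines ``fromId toId``.
    """
    lines = text.splitlines()
    try:
        sep = next(i for i, l in enumerate(lines) if l.strip() == "#")
    except StopIteration:
        raise ValueError("TGF: missing '#' separator between nodes and edges")
    names: dict[str, str] = {}
    for lineno, line in enumerate(lines[:sep], start=1):
        tokens = line.split(maxsplit=1)
        if not tokens:
            continue
        node_id = tokens[0]
        if node_id in names:
            raise ValueError(f"TGF line {lineno}: duplicate node id {node_id!r}")
        names[node_id] = tokens[1].strip() if len(tokens) > 1 else node_id
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines[sep + 1 :], start=sep + 2):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 2:
            raise ValueError(f"TGF line {lineno}: expected 'fromId toId'")
        u, v = tokens
        for node_id in (u, v):
            if node_id not in names:
                raise ValueError(
                    f"TGF line {lineno}: edge references undeclared node {node_id}"
                )
        edges.add((names[u], names[v]))
    return Topology(names.values(), edges)


def write_tgf(t: Topology) -> str:
    """Serialise a topology to TGF; round-trips through :func:`read_tgf`."""
    ids = {n: str(i) for i, n in enumerate(t.nodes, start=1)}
    lines = [f"{ids[n]} {n}" for n in t.nodes]
    lines.append("#")
    lines.extend(f"{ids[u]} {ids[v]}" for u, v in sorted(t.edges))
    return "\n".join(lines) + "\n"


def read_data_matrix(text: str, transpose: bool = False) -> pd.DataFrame:
    """Parse a whitespace-separated observation matrix.

    The first row holds sample identifiers (with or without a corner
    cell), the first column of each subsequent row a variable name.
    Returns a variables x samples float DataFrame with NaN for missing
    entries.  With ``transpose=True`` the file is read samples x
    variables and flipped.
    """
    rows = [line.split() for line in text.splitlines() if line.strip()]
    if not rows:
        raise ValueError("no data")
    header, *body = rows
    if not body:
        raise ValueError("no data rows below the header")
    width = len(body[0])
    if len(header) == width - 1:
        samples = header
    elif len(header) == width:
        samples = header[1:]  # corner cell present
    else:
        raise ValueError(
            f"row 1: header has {len(header)} tokens but data rows have {width}"
        )
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample identifiers")
    variables: list[str] = []
    values = np.empty((len(body), len(samples)))
    for r, row in enumerate(body, start=2):
        if len(row) != width:
            raise ValueError(f"row {r}: expected {width} tokens, got {len(row)}")
        name, *cells = row
        if name in variables:
            raise ValueError(f"row {r}: duplicate variable name {name!r}")
        variables.append(name)
        for c, tok in enumerate(cells):
            if tok.lower() in _MISSING_TOKENS:
                values[r - 2, c] = np.nan
            else:
                try:
                    values[r - 2, c] = float(tok)
                except ValueError:
                    raise ValueError(
                        f"row {r}, column {c + 2}: non-numeric token {tok!r}"
                    ) from None
    df = pd.DataFrame(values, index=variables, columns=samples)
    return df.T if transpose else df


def write_data_matrix(df: pd.DataFrame) -> str:
    """Serialise a variables x samples matrix; NaN becomes ``NA``."""
    buf = _io.StringIO()
    buf.write("\t".join([""] + [str(c) for c in df.columns]) + "\n")
    for var in df.index:
        cells = [
            "NA" if np.isnan(v) else f"{v:g}" for v in df.loc[var].to_numpy(float)
        ]
        buf.write("\t".join([str(var)] + cells) + "\n")
    return buf.getvalue()


def _method_from_json(obj: dict, where: str) -> MethodSpec:
    if not isinstance(obj, dict) or "method" not in obj:
        raise ValueError(f"{where}: expected an object with a 'method' key")
    method = obj["method"]
    if method not in METHODS:
        raise ValueError(f"{where}: unknown method {method!r}")
    threshold = obj.get("threshold")
    buckets = obj.get("buckets")
    if buckets is not None:
        buckets = int(buckets)
    return MethodSpec(method=method, threshold=threshold, buckets=buckets)


def read_discretisation_spec(text: str) -> DiscretisationSpec:
    """Parse the JSON discretisation spec.

    Schema::

        {"default": {"method": str, ...params},
         "variables": [{"name": str, "method": str,
                        "threshold": num?, "buckets": int?}]}
    """
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"discretisation spec is not valid JSON: {exc}") from None
    if not isinstance(obj, dict):
        raise ValueError("discretisation spec must be a JSON object")
    unknown = set(obj) - {"default", "variables"}
    if unknown:
        raise ValueError(f"unknown top-level keys {sorted(unknown)}")
    default = None
    if "default" in obj:
        default = _method_from_json(obj["default"], "default")
    per_var: dict[str, MethodSpec] = {}
    for i, entry in enumerate(obj.get("variables", [])):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ValueError(f"variables[{i}]: expected an object with a 'name'")
        per_var[str(entry["name"])] = _method_from_json(entry, f"variables[{i}]")
    return DiscretisationSpec(default=default, variables=per_var)


def write_parameters(n: CausalNetwork) -> str:
    """Print every CPT as a text table, byte-stable for a fixed network.

    Each node gets a ``> node [| parents]`` header.  Root nodes list one
    ``state probability`` line per state; nodes with parents list one
    line per parent configuration (row-major over the parents' state
    spaces): the parent states, a ``:``, then the probability of each
    child state.  Probabilities use 6 decimal places.
    """
    out = _io.StringIO()
    for node in n.topology.nodes:
        cpt = n.cpt(node)
        if cpt.parents:
            out.write(f"> {node} | {' '.join(cpt.parents)}\n")
            rows = cpt.table.reshape(-1, cpt.table.shape[-1])
            parent_cards = cpt.table.shape[:-1]
            for r, row in enumerate(rows):
                config = np.unravel_index(r, parent_cards)
                cfg = " ".join(str(int(c)) for c in config)
                probs = " ".join(f"{p:.6f}" for p in row)
                out.write(f"{cfg} : {probs}\n")
        else:
            out.write(f"> {node}\n")
            for state, p in enumerate(cpt.table):
                out.write(f"{state} {p:.6f}\n")
        out.write("\n")
    return out.getvalue()


_HEADER_RE = re.compile(r"^> (\S+)(?: \| (.+))?$")


def parse_parameters(text: str) -> dict[str, CPT]:
    """Inverse of :func:`write_parameters` (up to print precision)."""
    cpts: dict[str, CPT] = {}
    node = None
    parents: tuple[str, ...] = ()
    rows: list[tuple[tuple[int, ...], list[float]]] = []

    def flush():
        if node is None:
            return
        if parents:
            cards = tuple(max(cfg[i] for cfg, _ in rows) + 1 for i in range(len(parents)))
            k = len(rows[0][1])
            table = np.zeros(cards + (k,))
            for cfg, probs in rows:
                table[cfg] = probs
        else:
            table = np.array([p[0] for _, p in sorted(rows)])
        cpts[node] = CPT(child=node, parents=parents, table=table)

    for line in text.splitlines():
        if not line.strip():
            continue
        m = _HEADER_RE.match(line)
        if m:
            flush()
            node = m.group(1)
            parents = tuple(m.group(2).split()) if m.group(2) else ()
            rows = []
        elif parents:
            left, right = line.split(":")
            cfg = tuple(int(t) for t in left.split())
            rows.append((cfg, [float(t) for t in right.split()]))
        else:
            state, prob = line.split()
            rows.append(((int(state),), [float(prob)]))
    flush()
    return cpts
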