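"""Fixture networks and synthetic data generation.

Everything needed to exercise the package without external downloads:
the classic rain/sprinkler/wet-grass teaching network with fixed CPTs,
seeded ancestral (forward) sampling, MCAR missingness injection, a
per-state Gaussian emitter that turns discrete samples into continuous
measurements (so the discretisation path can be tested end to end), and
random valid networks for oracle-equivalence property tests.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CPT, CausalNetwork, StateSpace, Topology, topological_order

__all__ = [
    "make_sprinkler",
    "forward_sample",
    "inject_missing",
    "sample_continuous",
    "make_random_network",
]


def make_sprinkler() -> CausalNetwork:
    """Rain (R) -> Sprinkler (S), both -> WetGrass (W); binary nodes.

    P(R=1)=0.2; P(S=1|R=0)=0.4, P(S=1|R=1)=0.01;
    P(W=1|R,S): (0,0)->0, (1,0)->0.8, (0,1)->0.9, (1,1)->0.99.
    """
    topology = Topology(["R", "S", "W"], [("R", "S"), ("R", "W"), ("S", "W")])
    states = StateSpace.from_cards({"R": 2, "S": 2, "W": 2})
    cpts = {
        "R": CPT("R", (), np.array([0.8, 0.2])),
        "S": CPT("S", ("R",), np.array([[0.6, 0.4], [0.99, 0.01]])),
        # axes: R, S, W
        "W": CPT(
            "W",
            ("R", "S"),
            np.array(
                [
                    [[1.0, 0.0], [0.1, 0.9]],
                    [[0.2, 0.8], [0.01, 0.99]],
                ]
            ),
        ),
    }
    return CausalNetwork(topology=topology, states=states, cpts=cpts)


def forward_sample(
    net: CausalNetwork, count: int, seed: int = 0
) -> pd.DataFrame:
    """Ancestral sampling: draw *count* joint samples in topological order.

    Returns a variables x samples integer DataFrame (columns ``s0..``),
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    order = topological_order(net.topology)
    columns = [f"s{i}" for i in range(count)]
    draws: dict[str, np.ndarray] = {}
    for node in order:
        parents = net.parents(node)
        table = net.cpt(node).table
        k = net.card(node)
        u = rng.random(count)
        if parents:
            rows = table[tuple(draws[p] for p in parents)]
        else:
            rows = np.broadcast_to(table, (count, k))
        cdf = np.cumsum(rows, axis=1)
        draws[node] = (u[:, None] > cdf).sum(axis=1).clip(0, k - 1)
    data = pd.DataFrame.from_dict(
        {n: draws[n] for n in net.topology.nodes}, orient="index", columns=columns
    )
    return data.astype(np.int64)


def inject_missing(
    data: pd.DataFrame, rate: float, seed: int = 0
) -> pd.DataFrame:
    """Set each cell to NaN independently with probability *rate* (MCAR)."""
    if not 0 <= rate < 1:
        raise ValueError(f"missingness rate must be in [0, 1), got {rate}")
    if rate == 0:
        return data.astype(float)
    rng = np.random.default_rng(seed)
    mask = rng.random(data.shape) < rate
    out = data.astype(float).to_numpy()
    out[mask] = np.nan
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def sample_continuous(
    net: CausalNetwork,
    count: int,
    seed: int = 0,
    state_means: Optional[Mapping[str, Sequence[float]]] = None,
    state_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discrete forward samples emitted through per-state Gaussians.

    Each variable's state s is emitted as N(state_means[var][s],
    state_sd).  Means must be strictly increasing per variable (default:
    the state indices themselves).  Returns (continuous matrix, the
    underlying discrete matrix) so round-trip tests can compare.
    """
    discrete = forward_sample(net, count, seed=seed)
    rng = np.random.default_rng(seed + 1)
    rows = {}
    for var in net.topology.nodes:
        means = np.asarray(
            (state_means or {}).get(var, np.arange(net.card(var), dtype=float)),
            dtype=float,
        )
        if len(means) != net.card(var):
            raise ValueError(f"need one mean per state for {var!r}")
        if np.any(np.diff(means) <= 0):
            raise ValueError(f"state means for {var!r} must be strictly increasing")
        states = discrete.loc[var].to_numpy()
        rows[var] = means[states] + rng.normal(0.0, state_sd, size=count)
    continuous = pd.DataFrame.from_dict(
        {n: rows[n] for n in net.topology.nodes},
        orient="index",
        columns=discrete.columns,
    )
    return continuous, discrete


def make_random_network(
    node_count: int,
    max_parents: int = 3,
    max_states: int = 3,
    seed: int = 0,
) -> CausalNetwork:
    """A random valid network for property tests.

    A random node order admits edges only from earlier to later nodes
    (so the graph is acyclic by construction); each node draws up to
    *max_parents* parents and a cardinality in ``2..max_states``; CPT
    rows come from a flat Dirichlet.
    """
    if node_count < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(node_count)]
    order = list(rng.permutation(names))
    cards = {n: int(rng.integers(2, max_states + 1)) for n in names}
    edges = []
    for i, node in enumerate(order):
        if i == 0 or max_parents == 0:
            continue
        k = int(rng.integers(0, min(max_parents, i) + 1))
        parents = rng.choice(order[:i], size=k, replace=False)
        edges.extend((str(p), node) for p in parents)
    topology = Topology(names, edges)
    cpts = {}
    for node in names:
        parents = topology.parents(node)
        shape = tuple(cards[p] for p in parents) + (cards[node],)
        rows = rng.dirichlet(np.ones(shape[-1]), size=int(np.prod(shape[:-1])))
        cpts[node] = CPT(node, parents, rows.reshape(shape))
    return CausalNetwork(
        topology=topology,
        states=StateSpace.from_cards(cards),
        cpts=cpts,
    )
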