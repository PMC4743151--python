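"""CPT estimation from discretised data, with EM over missing entries.

With complete data, maximum-likelihood CPTs are plain conditional
frequencies (:func:`ml_counts`).  With missing entries the
expectation-maximisation algorithm alternates between computing expected
family counts — for every sample, the posterior over that family's
unobserved members given the sample's observed entries, by exact
inference — and re-normalising those counts into CPTs.  EM only finds a
local optimum, so it is restarted from several initialisations and the
restart with the highest final log-likelihood wins.

Samples sharing the same observation pattern contribute identical
expected counts, so the data are collapsed to unique columns with
multiplicities before the E-step; this changes nothing but run time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import (
    InconsistentEvidenceError,
    evidence_probability,
    variable_elimination,
)
from .model import CPT, CausalNetwork

__all__ = ["EMConfig", "FitResult", "ml_counts", "log_likelihood", "em_fit", "init_cpts"]

NEG_INF = float("-inf")

INIT_SCHEMES = ("uniform", "random", "complete_case")


@dataclass(frozen=True)
class EMConfig:
    """EM settings.

    max_iter
        Iteration cap per restart.
    tol
        Convergence threshold on the absolute change of the total
        log-likelihood between iterations.
    restarts
        Number of restarts; restart *i* uses ``schemes[i % len(schemes)]``.
    schemes
        Ordered initialisation schemes, each in
        ``{uniform, random, complete_case}``.
    seed
        Base seed for the ``random`` scheme (offset per restart).
    pseudo_count
        Optional Laplace smoothing added to every count cell in the
        M-step; 0 keeps pure frequency estimates.
    """

    max_iter: int = 100
    tol: float = 1e-6
    restarts: int = 3
    schemes: tuple[str, ...] = ("uniform", "complete_case", "random")
    seed: int = 0
    pseudo_count: float = 0.0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.restarts < 1:
            raise ValueError("at least one restart is required")
        for s in self.schemes:
            if s not in INIT_SCHEMES:
                raise ValueError(f"unknown initialisation scheme {s!r}")


@dataclass
class FitResult:
    """Outcome of :func:`em_fit`."""

    network: CausalNetwork
    log_likelihood: float
    iterations: list[int]
    winner: int
    ll_history: list[list[float]] = field(default_factory=list)


def _check_data(net: CausalNetwork, data: pd.DataFrame) -> None:
    missing_vars = set(net.topology.nodes) - set(data.index)
    if missing_vars:
        raise ValueError(f"variables absent from data: {sorted(missing_vars)}")
    if data.shape[1] == 0:
        raise ValueError("empty data: no samples")


def _normalise_counts(
    counts: dict[str, np.ndarray], net: CausalNetwork, pseudo: float
) -> dict[str, CPT]:
    cpts = {}
    for node, table in counts.items():
        table = table + pseudo
        totals = table.sum(axis=-1, keepdims=True)
        k = table.shape[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(totals > 0, table / np.where(totals > 0, totals, 1), 1.0 / k)
        cpts[node] = CPT(child=node, parents=net.parents(node), table=probs)
    return cpts


def ml_counts(net: CausalNetwork, data: pd.DataFrame) -> CausalNetwork:
    """Maximum-likelihood CPTs from complete data.

    Each cell is the conditional frequency
    ``#(child=v, parents=cfg) / #(parents=cfg)``; parent configurations
    never observed get the uniform distribution over child states.
    """
    _check_data(net, data)
    if data.loc[list(net.topology.nodes)].isna().any().any():
        raise ValueError("ml_counts requires complete data (no missing entries)")
    counts: dict[str, np.ndarray] = {}
    for node in net.topology.nodes:
        parents = net.parents(node)
        shape = tuple(net.card(p) for p in parents) + (net.card(node),)
        table = np.zeros(shape)
        idx = tuple(
            data.loc[v].to_numpy(float).astype(int) for v in parents + (node,)
        )
        np.add.at(table, idx, 1.0)
        counts[node] = table
    return net.with_cpts(_normalise_counts(counts, net, 0.0)).with_training_data(data)


def _unique_patterns(
    net: CausalNetwork, data: pd.DataFrame
) -> list[tuple[dict[str, int], int]]:
    """Collapse samples to unique observed-entry patterns with counts."""
    nodes = list(net.topology.nodes)
    arr = data.loc[nodes].to_numpy(float)
    patterns: Counter[tuple] = Counter()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        key = tuple(None if np.isnan(v) else int(v) for v in col)
        patterns[key] += 1
    return [
        ({n: s for n, s in zip(nodes, key) if s is not None}, count)
        for key, count in patterns.items()
    ]


def log_likelihood(net: CausalNetwork, data: pd.DataFrame) -> float:
    """Sum over samples of log P(observed entries), missing entries
    marginalised out exactly; ``-inf`` if any sample has probability 0."""
    _check_data(net, data)
    total = 0.0
    for evidence, count in _unique_patterns(net, data):
        p = evidence_probability(net, evidence)
        if p <= 0:
            return NEG_INF
        total += count * np.log(p)
    return float(total)


def init_cpts(
    net: CausalNetwork,
    scheme: str,
    seed: int = 0,
    data: Optional[pd.DataFrame] = None,
) -> CausalNetwork:
    """Initial CPTs for one EM restart.

    ``uniform`` sets every row uniform; ``random`` draws each row from a
    flat Dirichlet (reproducible via *seed*); ``complete_case`` applies
    :func:`ml_counts` to the samples without any missing entry (falling
    back to uniform when none exist).
    """
    if scheme not in INIT_SCHEMES:
        raise ValueError(f"unknown initialisation scheme {scheme!r}")
    if scheme == "complete_case":
        if data is None:
            raise ValueError("complete_case initialisation requires data")
        complete = data.loc[:, ~data.loc[list(net.topology.nodes)].isna().any(axis=0)]
        if complete.shape[1] == 0:
            return init_cpts(net, "uniform")
        return ml_counts(net, complete).with_training_data(data)
    rng = np.random.default_rng(seed)
    cpts = {}
    for node in net.topology.nodes:
        parents = net.parents(node)
        shape = tuple(net.card(p) for p in parents) + (net.card(node),)
        if scheme == "uniform":
            table = np.full(shape, 1.0 / shape[-1])
        else:
            flat = rng.dirichlet(np.ones(shape[-1]), size=int(np.prod(shape[:-1])))
            table = flat.reshape(shape)
        cpts[node] = CPT(child=node, parents=parents, table=table)
    return net.with_cpts(cpts)


def _family_posterior(
    net: CausalNetwork,
    family: tuple[str, ...],
    evidence: dict[str, int],
) -> Optional[np.ndarray]:
    """Posterior over the family's joint states given one sample's
    observed entries, as an array shaped like the family's CPT.

    Returns None if the evidence is inconsistent under the current
    parameters (the sample then contributes nothing this iteration).
    """
    observed = {v: evidence[v] for v in family if v in evidence}
    hidden = [v for v in family if v not in evidence]
    shape = tuple(net.card(v) for v in family)
    table = np.zeros(shape)
    if not hidden:
        table[tuple(observed[v] for v in family)] = 1.0
        return table
    try:
        post = variable_elimination(net, hidden, evidence)
    except InconsistentEvidenceError:
        return None
    index: list = [observed[v] if v in observed else slice(None) for v in family]
    table[tuple(index)] = post.values
    return table


def em_fit(
    net: CausalNetwork, data: pd.DataFrame, config: EMConfig = EMConfig()
) -> FitResult:
    """Fit CPTs by EM with restarts; the best final log-likelihood wins.

    Within each restart the log-likelihood is non-decreasing across
    iterations (the EM guarantee); convergence is declared when its
    absolute change drops below ``config.tol``.
    """
    _check_data(net, data)
    patterns = _unique_patterns(net, data)
    families = {
        node: net.parents(node) + (node,) for node in net.topology.nodes
    }
    shapes = {
        node: tuple(net.card(v) for v in fam) for node, fam in families.items()
    }

    best: Optional[tuple[float, CausalNetwork, int]] = None
    iterations: list[int] = []
    histories: list[list[float]] = []
    for restart in range(config.restarts):
        scheme = config.schemes[restart % len(config.schemes)]
        current = init_cpts(net, scheme, seed=config.seed + restart, data=data)
        history: list[float] = []
        ll_prev = NEG_INF
        iters = 0
        for iters in range(1, config.max_iter + 1):
            counts = {node: np.zeros(shape) for node, shape in shapes.items()}
            for evidence, count in patterns:
                for node, fam in families.items():
                    post = _family_posterior(current, fam, evidence)
                    if post is not None:
                        counts[node] += count * post
            current = current.with_cpts(
                _normalise_counts(counts, net, config.pseudo_count)
            )
            ll = log_likelihood(current, data)
            history.append(ll)
            if ll_prev != NEG_INF and abs(ll - ll_prev) < config.tol:
                break
            ll_prev = ll
        iterations.append(iters)
        histories.append(history)
        final_ll = history[-1] if history else NEG_INF
        if best is None or final_ll > best[0]:
            best = (final_ll, current, restart)
    assert best is not None
    final_ll, fitted, winner = best
    return FitResult(
        network=fitted.with_training_data(data),
        log_likelihood=final_ll,
        iterations=iterations,
        winner=winner,
        ll_history=histories,
    )
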