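"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's Factor/variable-elimination code
path: the full joint table is assembled axis by axis from the raw CPT
arrays and posteriors are obtained by slicing and summing, with no
elimination ordering involved.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def joint_table(net):
    """The full joint distribution as (node list, ndarray over their states)."""
    nodes = list(net.topology.nodes)
    cards = [net.card(n) for n in nodes]
    joint = np.ones(cards)
    for n in nodes:
        cpt = net.cpt(n)
        scope = list(cpt.parents) + [n]
        global_axes = [nodes.index(v) for v in scope]
        order = sorted(range(len(scope)), key=lambda i: global_axes[i])
        table = cpt.table.transpose(order)
        shape = [1] * len(nodes)
        for ax in sorted(global_axes):
            shape[ax] = cards[ax]
        joint = joint * table.reshape(shape)
    return nodes, joint


def enum_posterior(net, targets, evidence=None):
    """P(targets | evidence) by slicing the enumerated joint; None if P(e)=0."""
    evidence = dict(evidence or {})
    nodes, joint = joint_table(net)
    idx = tuple(evidence[n] if n in evidence else slice(None) for n in nodes)
    sub = joint[idx]
    keep = [n for n in nodes if n not in evidence]
    drop = tuple(i for i, n in enumerate(keep) if n not in targets)
    marg = sub.sum(axis=drop) if drop else sub
    total = marg.sum()
    if total <= 0:
        return None
    remaining = [n for n in keep if n in targets]
    perm = [remaining.index(t) for t in targets]
    return marg.transpose(perm) / total


def enum_probability(net, assignments, evidence=None):
    """Joint probability of the assignments given evidence, by enumeration."""
    targets = [n for n, _ in assignments]
    post = enum_posterior(net, targets, evidence)
    if post is None:
        return None
    return float(post[tuple(s for _, s in assignments)])


def loglik_by_enumeration(net, data):
    """Log-likelihood by summing joint cells compatible with each sample."""
    nodes, joint = joint_table(net)
    total = 0.0
    for col in data.columns:
        sample = data[col]
        idx = tuple(
            slice(None) if np.isnan(sample[n]) else int(sample[n]) for n in nodes
        )
        p = float(np.asarray(joint[idx]).sum())
        if p <= 0:
            return float("-inf")
        total += math.log(p)
    return total


def all_joint_states(net):
    """Iterate (assignment dict, probability) over every joint state."""
    nodes, joint = joint_table(net)
    for states in itertools.product(*(range(net.card(n)) for n in nodes)):
        yield dict(zip(nodes, states)), float(joint[states])
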