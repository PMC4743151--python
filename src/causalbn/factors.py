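"""Factor algebra for exact inference.

A factor is a nonnegative table over the joint states of an ordered list
of variables (its *scope*); CPTs are factors, and variable elimination is
nothing but repeated factor product and marginalisation.  Values are held
in a numpy array with one axis per scope variable, so the product is a
broadcast multiply.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import CPT, CausalNetwork

__all__ = ["Factor", "factor_product", "factor_marginalize", "factor_reduce"]


class Factor:
    """Nonnegative table over the joint states of ``scope``.

    ``values[s1, ..., sk]`` is the entry for the joint state in scope
    order; axis ``i`` has size ``cardinalities[i]``.
    """

    __slots__ = ("scope", "cards", "values")

    def __init__(
        self,
        scope: Sequence[str],
        cards: Sequence[int],
        values: np.ndarray,
    ):
        self.scope = list(scope)
        self.cards = list(int(c) for c in cards)
        if len(set(self.scope)) != len(self.scope):
            raise ValueError("factor scope contains duplicate variables")
        arr = np.asarray(values, dtype=float).reshape(tuple(self.cards))
        if np.any(arr < 0):
            raise ValueError("factor values must be nonnegative")
        self.values = arr

    @classmethod
    def from_cpt(cls, net: CausalNetwork, node: str) -> "Factor":
        """The CPT of *node* as a factor over (parents..., node)."""
        cpt = net.cpt(node)
        scope = list(cpt.parents) + [node]
        cards = [net.card(v) for v in scope]
        return cls(scope, cards, cpt.table)

    @classmethod
    def scalar(cls, value: float) -> "Factor":
        f = cls.__new__(cls)
        f.scope = []
        f.cards = []
        f.values = np.asarray(float(value))
        return f

    def card(self, var: str) -> int:
        return self.cards[self.scope.index(var)]

    def total(self) -> float:
        return float(self.values.sum())

    def _aligned(self, scope: list[str], cards: list[int]) -> np.ndarray:
        """values transposed/reshaped to broadcast against *scope*."""
        order = [v for v in scope if v in self.scope]
        perm = [self.scope.index(v) for v in order]
        vals = self.values.transpose(perm)
        shape = tuple(c if v in self.scope else 1 for v, c in zip(scope, cards))
        return vals.reshape(shape)

    def product(self, other: "Factor") -> "Factor":
        """Factor product; scope is self's order followed by other's new variables."""
        for v in other.scope:
            if v in self.scope and self.card(v) != other.card(v):
                raise ValueError(
                    f"cardinality mismatch on shared variable {v!r}: "
                    f"{self.card(v)} vs {other.card(v)}"
                )
        scope = self.scope + [v for v in other.scope if v not in self.scope]
        cards = [
            self.card(v) if v in self.scope else other.card(v) for v in scope
        ]
        vals = self._aligned(scope, cards) * other._aligned(scope, cards)
        return Factor(scope, cards, vals)

    def marginalize(self, var: str) -> "Factor":
        """Sum out *var*; total mass is conserved."""
        if var not in self.scope:
            raise ValueError(f"variable {var!r} not in factor scope {self.scope}")
        ax = self.scope.index(var)
        vals = self.values.sum(axis=ax)
        scope = [v for v in self.scope if v != var]
        cards = [c for i, c in enumerate(self.cards) if i != ax]
        out = Factor.__new__(Factor)
        out.scope = scope
        out.cards = cards
        out.values = vals
        return out

    def reduce(self, evidence: Mapping[str, int]) -> "Factor":
        """Zero out rows inconsistent with *evidence*; scope is retained.

        Evidence on variables outside the scope is ignored.  No
        renormalisation is performed.
        """
        vals = self.values
        touched = False
        for var, state in evidence.items():
            if var not in self.scope:
                continue
            ax = self.scope.index(var)
            state = int(state)
            if not 0 <= state < self.cards[ax]:
                raise ValueError(
                    f"evidence state {state} out of range for {var!r} "
                    f"(cardinality {self.cards[ax]})"
                )
            if not touched:
                vals = vals.copy()
                touched = True
            idx = [slice(None)] * vals.ndim
            mask = np.ones(self.cards[ax], dtype=bool)
            mask[state] = False
            idx[ax] = mask
            vals[tuple(idx)] = 0.0
        if not touched:
            return self
        out = Factor.__new__(Factor)
        out.scope = list(self.scope)
        out.cards = list(self.cards)
        out.values = vals
        return out

    def transpose(self, scope: Sequence[str]) -> "Factor":
        """Reorder axes to the given permutation of the current scope."""
        scope = list(scope)
        if sorted(scope) != sorted(self.scope):
            raise ValueError(f"{scope} is not a permutation of {self.scope}")
        perm = [self.scope.index(v) for v in scope]
        out = Factor.__new__(Factor)
        out.scope = scope
        out.cards = [self.cards[i] for i in perm]
        out.values = self.values.transpose(perm)
        return out

    def normalized(self) -> "Factor":
        total = self.values.sum()
        if total <= 0:
            raise ZeroDivisionError("cannot normalise a zero factor")
        out = Factor.__new__(Factor)
        out.scope = list(self.scope)
        out.cards = list(self.cards)
        out.values = self.values / total
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Factor(scope={self.scope}, total={self.total():.6g})"


def factor_product(f: Factor, g: Factor) -> Factor:
    return f.product(g)


def factor_marginalize(f: Factor, var: str) -> Factor:
    return f.marginalize(var)


def factor_reduce(f: Factor, evidence: Mapping[str, int]) -> Factor:
    return f.reduce(evidence)
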