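"""Discretisation of continuous observations into integer states.

The network model is purely discrete, so continuous measurements (e.g.
phosphorylation levels from flow cytometry) must be mapped to a small
number of ordered classes first.  Ten methods are provided:

* ``ceil`` / ``floor`` / ``round`` — nearest-integer maps, re-indexed to
  a dense ``0..k-1`` range (``round`` is round-half-to-even);
* ``arithmetic_mean`` / ``harmonic_mean`` / ``median`` / ``z_score`` /
  ``fixed_threshold`` — binary: state 1 iff the value exceeds the
  statistic (strictly; ties go to state 0);
* ``bracket_medians`` — k equal-probability classes cut at the ``i/k``
  empirical quantiles;
* ``pearson_tukey`` — three classes cut at the 0.185 and 0.815
  quantiles, the classical 0.185/0.63/0.185 three-point mass split;
* ``none`` — asserts the column already holds integer states.

All statistics are computed over the non-missing values only, and
missing entries (NaN) pass through unchanged.  Empirical quantiles use
the inverted-CDF (type-1) definition: q(p) is the smallest order
statistic whose CDF reaches p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "MethodSpec",
    "DiscretisationSpec",
    "discretise_column",
    "discretise_matrix",
]

METHODS = frozenset(
    {
        "ceil",
        "floor",
        "round",
        "arithmetic_mean",
        "harmonic_mean",
        "median",
        "z_score",
        "fixed_threshold",
        "bracket_medians",
        "pearson_tukey",
        "none",
    }
)


@dataclass(frozen=True)
class MethodSpec:
    """A discretisation method plus its parameters."""

    method: str
    threshold: Optional[float] = None
    buckets: Optional[int] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown discretisation method {self.method!r}")
        if self.method == "fixed_threshold" and self.threshold is None:
            raise ValueError("fixed_threshold requires a 'threshold' value")
        if self.method == "bracket_medians":
            if self.buckets is None:
                raise ValueError("bracket_medians requires a 'buckets' count")
            if int(self.buckets) < 2:
                raise ValueError("bracket_medians needs at least 2 buckets")


@dataclass(frozen=True)
class DiscretisationSpec:
    """Per-variable method assignment with an optional default."""

    default: Optional[MethodSpec] = None
    variables: Mapping[str, MethodSpec] = field(default_factory=dict)

    def for_variable(self, name: str) -> MethodSpec:
        spec = self.variables.get(name, self.default)
        if spec is None:
            raise ValueError(
                f"no discretisation method for variable {name!r} and no default"
            )
        return spec


def _quantile_type1(sorted_values: np.ndarray, p: float) -> float:
    """Inverted-CDF empirical quantile: smallest value with CDF >= p."""
    n = len(sorted_values)
    i = max(int(math.ceil(n * p)) - 1, 0)
    return float(sorted_values[min(i, n - 1)])


def _dense_reindex(ints: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, int]:
    uniq = np.unique(ints[mask])
    rank = {v: i for i, v in enumerate(uniq.tolist())}
    out = np.full(ints.shape, np.nan)
    out[mask] = [rank[v] for v in ints[mask].tolist()]
    return out, len(uniq)


def discretise_column(
    values, spec: MethodSpec
) -> tuple[np.ndarray, int]:
    """Discretise one variable's values.

    Parameters
    ----------
    values
        1-d array-like of floats; NaN marks a missing entry.
    spec
        The method and its parameters.

    Returns
    -------
    (states, k)
        ``states`` is a float array with integer states and NaN preserved
        in place; every non-missing state lies in ``0..k-1``.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if not mask.any():
        raise ValueError("cannot discretise a column with all values missing")
    obs = x[mask]
    method = spec.method

    if method == "none":
        if not np.allclose(obs, np.round(obs)) or obs.min() < 0:
            raise ValueError(
                "method 'none' requires nonnegative integer states already"
            )
        out = np.full(x.shape, np.nan)
        out[mask] = obs
        return out, max(int(obs.max()) + 1, 2)

    if method in ("ceil", "floor", "round"):
        fn = {"ceil": np.ceil, "floor": np.floor, "round": np.rint}[method]
        ints = np.zeros(x.shape)
        ints[mask] = fn(obs)
        return _dense_reindex(ints, mask)

    if method in ("arithmetic_mean", "harmonic_mean", "median", "z_score",
                  "fixed_threshold"):
        if method == "arithmetic_mean":
            cut = float(obs.mean())
        elif method == "harmonic_mean":
            if np.any(obs <= 0):
                raise ValueError("harmonic mean requires strictly positive values")
            cut = float(len(obs) / np.sum(1.0 / obs))
        elif method == "median":
            cut = float(np.median(obs))
        elif method == "z_score":
            sd = float(obs.std(ddof=0))
            if sd == 0:
                raise ValueError("z_score undefined: standard deviation is 0")
            cut = float(obs.mean())  # z > 0  <=>  value > mean
        else:
            cut = float(spec.threshold)
        out = np.full(x.shape, np.nan)
        out[mask] = (obs > cut).astype(float)
        return out, 2

    if method in ("bracket_medians", "pearson_tukey"):
        srt = np.sort(obs)
        if method == "bracket_medians":
            k = int(spec.buckets)
            cuts = [_quantile_type1(srt, i / k) for i in range(1, k)]
        else:
            k = 3
            cuts = [_quantile_type1(srt, 0.185), _quantile_type1(srt, 0.815)]
        out = np.full(x.shape, np.nan)
        # ties at a cut point fall into the lower bracket (strict >)
        out[mask] = np.sum(
            obs[:, None] > np.asarray(cuts)[None, :], axis=1
        ).astype(float)
        return out, k

    raise ValueError(f"unknown discretisation method {method!r}")  # pragma: no cover


def discretise_matrix(
    raw: pd.DataFrame, spec: DiscretisationSpec
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Discretise a variables x samples matrix column-variable-wise.

    Returns the discrete matrix (same shape and names, NaN preserved) and
    the per-variable state counts used to build the network's state
    spaces.  State counts are at least 2 even if a method produced a
    single class, so every variable has a well-formed state space.
    """
    out = {}
    cards: dict[str, int] = {}
    for var in raw.index:
        states, k = discretise_column(raw.loc[var].to_numpy(), spec.for_variable(var))
        out[var] = states
        cards[var] = max(k, 2)
    df = pd.DataFrame.from_dict(out, orient="index", columns=raw.columns)
    return df.loc[raw.index], cards
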