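# Methods

## Model

The package operates on causal Bayesian networks: a DAG over named
discrete variables, each with an ordered state space `0..k-1` (display
labels such as low/medium/high are cosmetic) and a conditional
probability table P(node | parents).  The joint distribution is the
product of the CPTs.  Treating the edges as causal licenses two
operations beyond ordinary conditioning: interventions (graph
mutilation) and counterfactuals (twin networks).  Continuous variables
are not modelled directly; observations are discretised first.

CPT arrays are stored with one axis per parent (parents in
lexicographic order — the canonical order used everywhere) and the
child axis last.  Rows must sum to 1 within 1e-9;
`validate_network` reports any violation, and every learning routine is
required to emit networks that pass it.

## Exact inference

`variable_elimination` computes P(targets | evidence) by factor algebra:
each CPT becomes a factor, evidence is asserted by zeroing inconsistent
rows (scope retained — simpler bookkeeping, identical results to
slicing), and all non-target variables are summed out.  The elimination
order is chosen by the min-fill heuristic over the factor interaction
graph; ties break lexicographically.  The order affects cost only, never
values — the suite checks this by reversing the tie-break.  Evidence
with zero probability raises `InconsistentEvidenceError` rather than
returning NaN: silently propagating 0/0 hides user errors.

Posterior factors are normalised to total 1 within 1e-9.  The test
oracle is full-joint enumeration (assembling the complete joint table by
broadcasting, no elimination involved), compared at 1e-9 over hundreds
of random networks.

## Interventions

`apply_do` removes every edge into an intervened node and replaces its
CPT by a point mass (graph mutilation); no other CPT is touched.
`apply_edge_intervention` adds or removes an arc and re-estimates the
child's CPT:

* with retained training data, by expected family counts with all other
  CPTs held fixed — a family-restricted EM that reduces to plain
  conditional frequencies when the family's columns are complete;
* without data, an added parent axis replicates the existing CPT
  (initial independence — the data needed to estimate a new parent's
  effect simply is not there), and a removed parent is averaged out
  weighted by its marginal.

## Counterfactuals

A query that both conditions and intervenes ("given that we observed e,
what if X had been x?") is evaluated on a twin network: nodes that are
not descendants of an intervened node in the post-intervention graph are
shared between the factual and counterfactual worlds; intervened nodes
and their descendants get counterfactual copies (suffix `*`) wired to
the counterfactual counterparts of their parents, with the
post-intervention CPTs; do-assignments apply only to the copies.
Factual evidence is asserted on the original names, targets are read off
the copies.

**Semantic caveat.** The model stores CPTs, not structural equations
with explicit exogenous noise, so a copied node's stochastic response is
redrawn independently given its parents; only the shared non-descendants
couple the worlds.  This is the strongest coupling derivable from CPTs
alone.  Response-function parameterisations, which would preserve each
unit's noise across worlds and can give sharper counterfactuals, are out
of scope.  Users who instead want single-world semantics
P(Y | e, do(X=x)) — evidence and intervention in one world — can pass
`worlds="single"` (CLI flag `--worlds single`).

## Parameter learning

`ml_counts` is the complete-data maximum-likelihood estimate:
conditional frequencies, with never-observed parent configurations set
uniform (an explicit convention; no silent NaNs).  No pseudo-count
smoothing is applied by default — frequency estimates are reported as
they are — but `EMConfig.pseudo_count` adds optional Laplace smoothing.

`em_fit` handles missing entries (assumed missing completely at random):

* **E-step** — for every sample and every family, the posterior over the
  family's unobserved members given the sample's observed entries, by
  variable elimination.  Samples with identical observation patterns
  contribute identical posteriors, so the data are collapsed to unique
  columns with multiplicities first; this is purely a run-time
  optimisation.
* **M-step** — normalise the expected counts per parent configuration
  (zero-mass configurations → uniform).
* **Convergence** — on the absolute change of the total log-likelihood
  (default tolerance 1e-6, cap 100 iterations).  Log-likelihood is used
  rather than parameter deltas because EM guarantees it never decreases,
  which doubles as a test oracle (checked at slack 1e-9 on every run).
* **Restarts** — default 3, cycling through uniform, complete-case and
  random-Dirichlet initialisation; the restart with the highest final
  log-likelihood wins.  The counts and schemes are this package's
  choices; they are cheap insurance against local optima, and with
  complete data every scheme converges to `ml_counts` immediately.

Note that an LL tolerance of `t` leaves parameters roughly `sqrt(t)`
from the optimum (the likelihood is locally quadratic); callers needing
parameter-level accuracy should tighten `tol` accordingly, as the
fixed-point tests do with `tol=1e-12`.

If a sample's evidence has probability zero under the current parameters
(possible after a complete-case initialisation with empirical zeros), it
is skipped for that E-step and the log-likelihood is reported as `-inf`;
such a restart never wins against one with finite likelihood.

## Discretisation

Ten methods (see the module docstring for the full list).  Conventions
that needed fixing:

* all thresholds are strict (`value > cut` → upper class); ties go to
  the lower class — this keeps the median method balanced on odd n;
* empirical quantiles use the inverted-CDF (type-1) definition, so cuts
  are order statistics and the bracket-medians classes are exactly
  equal-count on divisible n;
* `round` is round-half-to-even (numpy's `rint`);
* ceil/floor/round outputs are re-indexed to a dense `0..k-1` range,
  because CPTs need dense state indices;
* `z_score` thresholds at z > 0.  On a single column this coincides with
  the arithmetic-mean split (it still errors on zero variance); the
  alternative reading |z| > 1 would be three-class and is not used;
* `fixed_threshold` is per-variable, with the JSON spec's `default`
  entry providing a global fallback;
* statistics are computed over non-missing values only, and missing
  entries pass through untouched.

## File formats

* SIF: `source relation target [target ...]`; the relation token is
  ignored and direction is source→targets (common SIF usage).  A
  single-token line declares an isolated node.
* TGF: `id [label]` lines, `#`, `from to` lines; the label, if present,
  names the node.
* Observation matrix: whitespace-separated, variables as rows and
  samples as columns (header row of sample ids, with or without a corner
  cell); `NA`/`na`/`nan` mark missing entries.  The orientation is a
  convention of this package — network workflows key data by node name —
  and `--transpose` accepts the other one.
* Discretisation spec: JSON with a `default` method and per-variable
  overrides; validated by explicit checks (the schema is small enough
  that a schema engine would be overhead).
* `write_parameters` prints each CPT with 6-decimal probabilities,
  parent configurations enumerated row-major; output is byte-stable and
  `parse_parameters` inverts it to print precision.

## Query language

`? target... [| evidence...] [! intervention...]` with targets
`NODE = STATE` or `argmax(NODE)`, interventions `do N = v`, `+ N M`,
`- N M`.  Tokenisation is whitespace-insensitive (punctuation
self-delimits); `do` and `argmax` are reserved.  States may be integer
indices or display labels.  Dispatch: interventions only → mutilated or
edge-modified network; evidence only → plain inference; both →
counterfactual (twin network).  Multiple assignment targets return their
joint posterior (strictly more informative than per-node marginals);
argmax targets are evaluated per node with smallest-index tie-breaking.

## Synthetic data

The generator exists so every pipeline is testable without downloads.
`forward_sample` is seeded ancestral sampling; `inject_missing` is MCAR
with a fixed per-cell rate (MAR/MNAR mechanisms are not modelled — EM's
correctness under them is a different question that these tests do not
address); `sample_continuous` emits per-state Gaussians with strictly
increasing means, which exercises the discretisation path but is far
cleaner than real flow-cytometry intensities (no skew, no shared
technical noise).  Passing tests therefore demonstrate correctness of
the algorithms under the stated assumptions, not robustness to real-data
pathologies.

The sprinkler fixture's CPTs are fixed constants chosen so that every
expected number in the tests is reproducible by brute-force enumeration
of its 8 joint states.  The shipped `sachs_consensus.sif` encodes the
published 11-protein consensus signalling topology (17 arcs) as prepared
by the package authors; it carries no data.

## Problem sizes and determinism

The acceptance script uses 200 random networks (≤ 10 nodes, ≤ 3 states)
for the enumeration cross-check, n = 50 000 samples with 20% missing
cells for EM recovery, and 25 six-node networks for the
intervention-invariance sweep — sizes at which the binomial/enumeration
tolerances quoted in the tests are comfortably sharp while the whole
script stays fast.  Every random draw derives from the `--seed`
argument; reruns with the same seed are bit-identical.

## Known limitations

* Structure learning is out of scope by design: topologies come from
  external tools or the literature.
* No continuous conditional distributions; discretisation granularity is
  the user's modelling decision.
* Counterfactual semantics as caveated above (independent redraw).
* Exact inference only: treewidth-heavy networks (far beyond the
  signalling-pathway scale this targets) would need approximate methods.
* EM assumes MCAR/ignorable missingness.
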