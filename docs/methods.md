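# Methods

## Scope and objects

Everything operates on undirected simple graphs with integer nodes
`0..N-1` (networkx `Graph`) and binary attribute vectors `x` of length `N`
(`x_i = 1` marks an "active" node). Loaders remap arbitrary integer labels
to the canonical range, drop self-loops, collapse duplicate edges, and
record both the label map and the cleanup counts. Isolated nodes stay in
`N` and in `p(0)` but contribute nothing to `q(k)` or `e(k, k')`; they can
never experience the illusion.

## Statistics

* `e(k, k')` counts each undirected edge in both orientations with weight
  `1/(2|E|)`. This convention makes `sum_k' e(k,k') = q(k)` an exact
  identity rather than an approximation, which the rest of the model relies
  on.
* The assortativity `r_kk` is computed from `e(k,k')` as the Pearson
  correlation of edge-end degrees,
  `r_kk = (sum k k' e(k,k') - mu_q^2) / sigma_q^2`. For regular graphs
  (`sigma_q = 0`) it is undefined and reported as `nan` — never as 0, which
  would silently mean "uncorrelated". The same `nan` convention applies to
  `rho_kx` when the attribute or the degrees are constant. `nan` was chosen
  over raising because degenerate configurations legitimately arise in the
  middle of parameter sweeps and should produce a skippable cell, not a
  crash.
* `rho_kx` uses the closed form
  `P(x=1)(<k>_{x=1} - <k>)/(sigma_x sigma_k)` with population standard
  deviations; tests verify it equals the node-level Pearson correlation of
  `(k_i, x_i)` to 1e-9.

## The illusion measurement

A node is in the illusion at threshold `phi` iff it has degree at least 1
and strictly more than `phi k` active neighbors. The strict inequality is
used everywhere (measurement, binomial tails, cascade rule) so that the
empirical observable and the model tail `P(Bin(k, p) > phi k)` count
exactly the same event; for even `k` at `phi = 1/2` an exact tie is *not*
an illusion. Toy narrations phrased as "at least half" can be reproduced
with `observers="inactive"` and the per-node shares, but strict-majority is
the package-wide default. The denominator of the illusion fraction is all
`N` nodes (active and isolated included), matching the mixture over the
full `p(k)`.

## The statistical model

`P(x=1|k)` is measured per degree class from the concrete configuration
(empirical route) or linearized from `rho_kx` alone (Gaussian route). The
neighbor activation probability mixes it through `e(k,k')/q(k)`; the global
`P(x'=1)` is implemented as the `p(k)`-mixture of the conditional
probabilities, the unambiguous form of that identity. Binomial tails come
from `scipy.stats.binom.sf`, which is evaluated in log space internally and
is accurate for all degrees encountered; an independent direct-summation
oracle (exact `math.comb` arithmetic) pins it to 1e-12 in the tests for
`k <= 64`.

The Gaussian route can leave `[0, 1]` for heavy-tailed degree
distributions; the output is clamped. That clamped regime is precisely
where the approximation is known to fail (power-law exponents near 2), and
the tests assert the failure rather than hiding it: for Erdős–Rényi graphs
with `<k> = 5.2` near zero assortativity the two routes agree within 0.02,
while at exponent 2.1 they diverge by an order of magnitude more.

## Generators

The power-law generator draws degrees i.i.d. from the normalized discrete
law `p(k) ∝ k^-alpha` on `[k_min, k_max]`, with defaults `k_min = 1`,
`k_max = N-1` (no structural cutoff imposed — the natural disassortativity
that heavy tails force on simple graphs is part of the phenomenon under
study). An odd degree total is fixed by incrementing one uniformly chosen
node. Wiring is the configuration model (random half-edge matching,
delegated to networkx), after which self-loops and parallel edges are
removed. Simplification rather than rejection-resampling was chosen
because every downstream statistic recomputes the *realized* `p(k)`,
`q(k)`, `e(k,k')`, so the pruning biases only the generator, never the
model inputs. Erdős–Rényi graphs use `p = <k>/(N-1)`.

All generators are deterministic given a seed (bitwise-identical edge
sets), and the sweep harness derives per-cell sub-seeds from the master
seed with `numpy.random.SeedSequence`.

## Rewiring and attribute swapping

Assortativity steering uses double-edge swaps: two random edges `(a,b)`,
`(c,d)` on four distinct nodes; both rewirings `(a,c)(b,d)` and
`(a,d)(b,c)` are evaluated and the better one proposed; a proposal is
accepted iff it keeps the graph simple and strictly shrinks
`|r_kk - target|` (a swap leaving `r_kk` unchanged is rejected). Because
degrees are invariant, `r_kk` depends on the edge set only through
`T = sum_edges k_u k_v`, so each proposal is evaluated in O(1); the full
recomputation is the test oracle (agreement to 1e-8). When the target is
unreachable the best-so-far graph is returned with a `target_reached=False`
flag — driving toward ±1 is the supported way to reach the achievable
extreme of a given degree sequence. A second procedure accepts swaps that
change the degree-pair multiset (hence `e(k,k')`) while pinning `r_kk`
within a tolerance of its initial value, isolating higher-order structure
at fixed `p(k)` and `r_kk`.

Attribute steering activates exactly `round(f N)` nodes (exact-count rather
than i.i.d., so sweep cells share the same prevalence) and then swaps
attribute values: to raise `rho_kx`, a random active/inactive pair is
exchanged iff the inactive node has the larger degree; to lower it, the
mirrored rule. Each accepted swap moves `rho_kx` monotonically, so the
process is a stochastic exchange sort on degrees whose fixed point (for
target +1) is the top-`fN`-by-degree active set; a sorting construction of
that optimum is the test oracle. Termination: target within tolerance,
iteration cap, or `50 N` consecutive rejected proposals (the stall rule that
operationalizes "until it no longer changes"); the stall constant is
configurable.

## Cascade

The linear-threshold cascade is progressive (active nodes, including
seeds, never deactivate) with the same strict rule `n_active > phi k`,
updated synchronously. Monotonicity makes the fixed point unique and
order-independent; tests check synchronous and asynchronous updates agree.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `phi` | 0.5 | strict-majority threshold |
| active fraction | 0.05 | global prevalence in the standard experiment |
| `N` | 10,000 | network size of the standard experiment |
| `alpha` | 2.1 / 2.4 / 3.1 | heavy / intermediate / mild tail exponents |
| ER `<k>` | 5.2 | Poisson-regime mean degree |
| swap `tol` | 0.005 | stop window around the `rho_kx` target |
| rewire `tol` | 0.005 | stop window around the `r_kk` target |
| stall factor | 50 | consecutive rejects per node before declaring a fixed point |

## What the synthetic generators do and do not emulate

The generators reproduce the degree heterogeneity, assortativity range and
degree–attribute correlation structure that drive the illusion. They do
not produce clustering, community structure, or degree-correlated attribute
noise beyond the binary swap mechanism — all of which real social and
biological networks have. Passing tests therefore establish that the
measurement and the model agree *given* the structural summaries
(`p`, `e`, `P(x|k)`); on real networks those summaries must be measured
from data, and the model's neighbor-independence assumption (step 2) can
be strained by clustering.

## Problem sizes and tolerances in the test suite

End-to-end checks run at the standard `N = 10,000` (they complete in
seconds); multi-seed statistical property tests use 2,000–3,000-node
networks as replicate-friendly study sizes. Model-vs-measurement agreement
is asserted as a mean absolute deviation below 0.05 across a `rho_kx` grid
and 10 seeds at exponent 3.1; the exact-oracle identity for independent
activation is asserted at 1e-9; distribution identities (`sum e = 1`,
marginal = `q`, `q = k p/<k>`) at 1e-9.

## Known limitations

* The binomial step treats neighbor states as independent given degree;
  clustering and attribute homophily beyond `P(x|k)` violate this.
* Greedy rewiring explores the achievable `r_kk` range of one degree
  sequence, not the full graph space with fixed `(p(k), r_kk)`; it can stop
  at a greedy extreme short of the global one.
* Directed and weighted graphs are out of scope; directed inputs read from
  GraphML are symmetrized generically (an edge in either direction becomes
  one undirected edge) and this is logged, since published analyses of
  directed sources have used dataset-specific reductions.
* The attribute model is binary by design.
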