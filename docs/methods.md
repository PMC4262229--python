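# Methods

## Problem and model

Given an undirected PPI network G = (V, E) — cleaned so that
self-interactions and duplicate pairs are removed — and optionally a
protein → GO-term annotation map, the detector searches for a partition of
V into functional modules that maximizes Newman modularity,

    Energy(A) = Σ_{c=1..K} [ e_c/|E| − (d_c / 2|E|)² ],

where e_c is the number of interactions inside module c and d_c the sum of
its members' degrees. This quantity lies in [-0.5, 1] for any partition of
any graph; the singleton partition of a single edge attains −0.5 and any
one-module partition attains 0.

The search is a cellular (lattice) evolutionary algorithm. A candidate
partition is encoded as a connection vector a over a fixed node ordering
(sorted protein identifiers, for determinism) with the locus-based
feasibility constraint a_i ∈ Γ(i) ∪ {i}; decoding is connected components
of the chosen links. The encoding can express exactly the partitions whose
modules are connected subgraphs — no restriction in practice, since
splitting a disconnected module into its components never lowers
modularity, so some optimal partition is always representable.

## Similarity channels and solution construction

Edges carry a combined strength s_ij + f_ij ∈ [0, 2]:

* structural: cosine similarity of closed neighborhoods,
  s_ij = |Γ⁺(i) ∩ Γ⁺(j)| / √(|Γ⁺(i)|·|Γ⁺(j)|). The closed form is used so
  that adjacent nodes with identical neighborhoods score exactly 1.
* functional: squared term-set overlap f_ij = |g^i ∩ g^j|²/(|g^i|·|g^j|),
  the same functional form as the NA matching score. Proteins without
  annotations contribute f = 0 rather than an error, because real
  annotation files are incomplete.

Initial agents are built by random walks: a traversal starts at a uniform
unassigned node and repeatedly steps to a neighbor not yet visited in the
current traversal whose strength reaches the gate ε, with probability
proportional to strength. Stepping onto a node assigned by an earlier
traversal terminates the traversal (chains merge, which lets walks
assemble modules larger than a single traversal); having no feasible step
writes a breakpoint. Cross-component moves are impossible, so connected
components are never merged spuriously.

## Evolutionary operators

* **Competition** — against the highest-energy lattice neighbor (4-cell
  von-Neumann torus; ties broken by lowest (row, col)). A winner survives
  unchanged. A loser's cell is re-occupied by a clone of the winner into
  which the loser's stronger links are injected: with probability p_o only
  at the winner's weakest link (ties at the minimum go to the lowest node
  index, for determinism), otherwise at every position where the loser is
  stronger. Breakpoints carry link strength 0, so competition tends to
  repair module boundaries first.
* **Crossover** — with probability p_c, both the alternating-link rule
  (child links taken from alternating parents while following the chain;
  on a would-be cycle the chain restarts at a random unassigned node) and
  the alternating-chunk rule (alternating parents supply chunks of length
  uniform on 1..remaining) are applied against one uniformly chosen
  lattice neighbor; the better child replaces the agent only on strict
  energy improvement. Every child link comes from one of the parents, so
  feasibility is inherited, never repaired.
* **Mutation** — with probability p_m, n = min(N, max(1,
  ceil((l/R)·log₂(N+1)))) distinct positions are re-pointed uniformly
  within their feasible sets, where l is the agent's stagnation count and
  R the stagnation horizon; the mutant replaces the agent only on strict
  improvement. The count grows with both network size and stagnation, so
  stuck agents explore progressively larger perturbations.

Replacement on *strict* improvement everywhere (plus winner-survives
competition) makes the best-ever energy trace monotone non-decreasing,
which the tests assert on every run. Cells are swept in fixed row-major
order with immediate replacement; a single root seed spawns separate
streams for construction, lattice placement and operator decisions, making
runs bit-reproducible.

Termination: the run stops when the global best energy has not improved
for R consecutive iterations, or at max_iter (default 1000 — convergence
on all tested problems occurs far earlier; the cap only guards runaway
loops).

## Post-processing

Modules are first merged greedily: the pair with the highest symmetric
best-match functional similarity

    S(M_S, M_T) = (1/|M_S|) Σ_{i∈M_S} max_{j∈M_T} f_ij
                + (1/|M_T|) Σ_{j∈M_T} max_{i∈M_S} f_ij   ∈ [0, 2]

is merged while S > λ (ties by earliest index pair). The [0, 2] range is
deliberate: useful merging thresholds for noisy data lie above 1, which a
[0, 1]-bounded average could never exceed. Then modules with fewer than
two proteins or induced density 2e_s/(n_s(n_s−1)) < δ are removed — a
singleton has no defined density, so size and density are alternative
removal causes, not a conjunction.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| M | population size (perfect square) | 100 | 225 for noisier screens |
| ε | walk strength gate | 0.27 | medium values balance search space vs. convergence |
| R | stagnation horizon (iterations) | 60 | termination and mutation scaling |
| p_o | Strategy-1 probability in competition | 0.5 | balances the two occupation strategies |
| p_c | crossover probability | 0.5 | |
| p_m | mutation probability | 0.8 | high rate helps convergence |
| λ | merging threshold on S ∈ [0,2] | 0.21 | 1.8 for noisy data (`gavin` preset) |
| δ | density filter | 0.04 | 0.12 for noisy data |
| ω | NA match threshold | 0.2 | the field's customary value |

Presets (`dip`, `gavin`, `mips`, `dip-scere2014`, `dip-hsapi2014`) bundle
these per source database; the default is the curated-network (`dip`)
preset.

## Synthetic study case

The generator plants K modules in n proteins (blocks as even as possible),
connecting within-block pairs with probability p_in and cross-block pairs
with p_out, and gives every protein its block's private term set, plus —
with probability equal to the noise rate — one term from another block.
The default study case is n=60, K=6, p_in=0.9, p_out=0.05, 3 terms per
module and noise 0.1: the smallest configuration that exercises both
similarity channels, non-trivial modularity structure and the
post-processing thresholds. What it does *not* emulate: scale-free degree
distributions, assay-specific false-positive structure, hub proteins
shared between complexes, or overlapping modules — perfect recovery here
therefore demonstrates correctness of the machinery, not expected
performance on experimental screens.

Problem sizes used by the validation suite and the acceptance script —
exhaustive optima on graphs of ≤ 7 nodes (Bell-number enumeration),
25 evolve runs for the hit-rate estimate, and 5–10 seeds of the 60-protein
study case — were chosen to keep full from-scratch reproduction fast on a
single core while still estimating every rate from multiple independent
runs.

## Numerical and design choices

* Modularity is evaluated via vectorized component labeling
  (scipy.sparse.csgraph) and per-label edge/degree counts; agents cache
  their energy and invalidate it on any link change.
* The hypergeometric tail P(X ≥ k) uses scipy's survival function; tests
  cross-check it against exhaustive enumeration of all draws for small
  universes.
* Reference complexes may contain proteins absent from the network; they
  are kept by default (matching a curated benchmark against a specific
  screen should not silently shrink the reference), with an option to
  restrict references to network nodes.
* Energy ties in competition favor the incumbent (≥), which prevents
  drift cycles between equal-energy encodings of the same partition.
* Per-module p-values are reported raw, one per (module, term) pair
  minimized over terms; no multiple-testing correction is applied, since
  the values are used comparatively, not inferentially.

## Known limitations

* Modules are disjoint by construction; moonlighting proteins that belong
  to several complexes cannot be expressed.
* The functional channel treats GO terms as opaque labels — no DAG
  propagation or information-content weighting.
* Runtime grows with M·N per iteration; for networks of 10⁴+ proteins the
  per-iteration Python loop over cells dominates and parallel lattice
  updates (deliberately out of scope) would be the next step.
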