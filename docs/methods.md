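# Methods

## Model

A weighted undirected network with `N ≥ 2` nodes is represented by a
symmetric nonnegative weight matrix `W` with zero diagonal; node strengths
are `K_i = Σ_j W_ij`. Continuous-time diffusion `∂τ φ = −L φ` with the
combinatorial Laplacian `L = diag(K) − W` defines the propagator
`U(τ) = e^{−τL}`, which is symmetric, nonnegative and doubly stochastic
because `L` has zero row sums. Everything the package computes is a
functional of the pair `(L, τ)`:

- the **emergent functional state** `W̃(τ) = φ₀ Π U(τ)` with zeroed
  diagonal, where `Π = diag(φ_i/φ₀)` encodes the initial distribution of
  the field (identity, i.e. one full unit per source node, unless supplied);
- the **Gibbs state** `ρ(τ) = U(τ)/Tr U(τ)` with eigenvalues
  `p_ℓ = e^{−τλ_ℓ}/Z` over Laplacian modes, and its Von Neumann entropy
  `S(τ) = −Σ p_ℓ log p_ℓ` (natural log);
- **functional modules**: Louvain modularity maximization on the dense
  functional state;
- the **RWCM null**: same edge set, weights redrawn iid Uniform(0,1) and
  rescaled once by (original total weight)/(drawn total weight).

Assumptions: the network is static on the time scale of signal propagation;
flow is conservative first-order diffusion (no sources/sinks, no nonlinear
transport); weights are exchange conductances. Directed networks,
multigraphs and temporal edge lists are out of scope.

## Numerical choices

- **One eigendecomposition per network.** `L` is symmetric, so `U(τ)` for a
  whole τ grid is `V diag(e^{−τλ}) Vᵀ` from a single `scipy.linalg.eigh`
  call — O(N³) once, O(N²) per scale. This targets N ≤ ~500 (the default
  `max_nodes` cap); Krylov/sparse exponentials for much larger N are
  deliberately not implemented.
- **Zero modes.** Eigenvalues below `10⁻¹⁰ · max(λ_max, 1)` are snapped to
  exactly 0. This is simultaneously the connectivity test (number of zero
  modes = number of components) and what keeps extreme-τ limits exact:
  without the snap, `e^{−τ·ε}` with residual `ε ≈ 10⁻¹⁵` visibly corrupts
  `U(τ)` and `S(τ)` for τ ≳ 10⁶.
- **Nonnegativity guard.** Propagator entries in `[−10⁻¹², 0)` are clipped
  to 0 (floating-point noise); anything more negative raises, since
  `e^{−τL}` is provably nonnegative and a larger violation means a bug.
- **Entropy from eigenvalues only**, log-sum-exp stabilized — never by
  exponentiating and re-diagonalizing `ρ`. An independent dense-matrix
  oracle (`expm` + second diagonalization) confirms agreement to 10⁻⁸ in
  the tests. Entropy is evaluated on the *structural* Laplacian, not on the
  functional state. `entropy_curve` additionally clamps the (provably
  monotone) column with a running minimum to remove ~10⁻¹⁵ jitter on flat
  stretches, and emits both `S` and `S/log N`, the latter for averaging
  across networks of different sizes.
- **Diffusion-time rescaling.** `τ_d = 1/λ₂`; grids are log-spaced in
  `τ/τ_d ∈ [10⁻¹⁰, 10]` (100 points by default). Cross-network averages and
  null comparisons match *ratios*, not absolute τ — each network (and each
  null realization) is evaluated at its own `τ = r·τ_d`, no interpolation.
- **φ₀ is a pure scale** (default 1): strengths are reported both raw and
  divided by φ₀; partitions are invariant to it.
- **Non-uniform initial conditions** produce an asymmetric state; community
  detection receives the symmetrization `(W̃ + W̃ᵀ)/2`.

## Louvain

Implemented in-package (two phases: greedy local moves, then aggregation of
communities into super-nodes with self-loops carrying the internal weight,
repeated until no move improves Q). Design points:

- weighted Newman–Girvan modularity at resolution 1 — multiscale behaviour
  comes from τ, not from a resolution knob;
- the functional state is used fully dense; an optional `min_weight`
  threshold exists on export only;
- per restart the node sweep order is reshuffled from a generator seeded by
  `(seed, restart)`; 10 restarts by default; the best-Q partition wins,
  first restart on ties. A move requires a gain strictly above 10⁻¹² —
  equal-gain candidates (scanned in ascending community id) keep the
  incumbent, so results are deterministic given the seed;
- module ids are renumbered by first appearance in node order.

Tests pin the implementation to two independent oracles: exhaustive
enumeration of all set partitions on N ≤ 8 graphs (agreement to 10⁻¹²) and
igraph's multilevel algorithm on structured graphs.

## Synthetic generators

Topologies: random geometric (connection radius supplied per call),
Barabási–Albert, Watts–Strogatz, stochastic block model (defaults:
4 blocks, intra 10⁻³, inter 0.5 — both probabilities are free parameters,
and assortative settings intra 0.5 / inter 10⁻³ are used for the planted
recovery tests), two bridged cliques, path, complete. Draws that come out
disconnected are resampled with a shifted seed up to 200 times. Weights are
unit unless a distribution is requested: `uniform`, `loguniform`, or
`degree_product` (weight `(d_i d_j)^γ`), the last emulating organized
transport networks where trunk cords between hubs are thick and peripheral
tips thin.

What the generators do *not* emulate about real fungal/slime-mold data:
spatial embedding with physical cord lengths, growth dynamics, measurement
noise in conductance estimates, or species-level covariates. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
multiscale phenomenology (module merging, entropy decay, null gaps), not
quantitative claims about any particular organism.

## Fixture choices that were genuinely open

- **Planted-block recovery scale.** The slow inter-block modes have decayed
  to 1/e already at `τ = τ_d`, so block recovery degrades there (measured
  mean adjusted Rand index ≈ 0.49). Recovery is perfect across
  `τ ∈ [10⁻⁴, 10⁻¹]·τ_d`; the tests use `0.05·τ_d` as the intermediate
  scale.
- **Null-comparison fixture.** An iid heterogeneous weighting (log-uniform
  over three decades on a small-world backbone) *loses* entropy to its RWCM
  at mid scales — unsurprising, since iid disorder is exactly what the null
  draws. The phenomenon of interest is that *organized* sparse weighted
  networks beat their nulls, so the fixture is a preferential-attachment
  tree with degree-product weights: its gap is ≈ 0 at both extreme rescaled
  scales, peaks above +1 at mid scales, and is never materially negative.

## Known limitations

- Dense O(N³)/O(N²) algebra caps practical sizes near the 500-node default.
- Louvain is a greedy heuristic; optimality is only guaranteed where the
  brute-force oracle checks it (N ≤ 8) and empirically matched to igraph on
  structured graphs.
- The module-count curve is seed-dependent where the modularity landscape
  is degenerate (very small or very large τ plateaus are stable; the
  transition region can shift by one module between seeds).
- `corpus_summary` averages at matched ratios only; it does not weight by
  network size, and emits both `S` and `S/log N` so the caller can choose.
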