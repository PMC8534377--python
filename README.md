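# funcstate

Multiscale **emergent functional states** of weighted undirected networks:
diffusion propagators, spectral (Von Neumann) entropy, functional modules,
and randomized-weight nulls — for anyone studying how structure shapes flow
in sparse weighted networks such as fungal and slime-mold transport systems.

## The problem and the method

A weight matrix `W` only shows direct links. To see how a network actually
*communicates* across scales, couple it to a diffusion process: a field
`φ(τ)` evolves as `∂τ φ = −L φ` with the combinatorial Laplacian
`L = diag(K) − W`, `K_i = Σ_j W_ij`. The solution is carried by the
heat-kernel propagator

```
U(τ) = e^{−τL}            (symmetric, doubly stochastic)
```

From it the package computes, per propagation scale τ:

- **Emergent functional state** `W̃_ij(τ) = φ₀ U_ij(τ) (1 − δ_ij)` — a
  network whose links encode the flow exchanged between every node pair
  within time τ. For τ → 0 it reduces to `φ₀ τ W` (pure structure); for
  large τ it becomes fully connected. Its mean strength
  `k̄ = (1/N) Σ_ij W̃_ij` rises from 0 toward `φ₀ (N−1)/N`.
- **Functional modules** — Louvain modularity maximization on the dense
  `W̃(τ)`: many small, structure-like modules at small τ; few large ones at
  large τ (implemented in-package with seeded restarts and deterministic
  tie-breaking).
- **Spectral entropy** — the Gibbs state `ρ(τ) = U(τ)/Tr U(τ)` has
  eigenvalues `p_ℓ = e^{−τλ_ℓ}/Z`; its Von Neumann entropy
  `S(τ) = −Tr[ρ log ρ]` (natural log) measures the diversity of active flow
  pathways. `S(0) = log N`, S is non-increasing in τ, and for a network
  with C components `S → log C`.
- **Rescaled scales** — scales are compared across networks via the
  diffusion time `τ_d = 1/λ₂` (at `τ = τ_d` the slowest nontrivial mode has
  decayed to exactly 1/e); curves are reported against `τ/τ_d ∈ [10⁻¹⁰, 10]`.
- **RWCM nulls** — the randomized-weight configuration model keeps every
  edge in place (preserving connectivity and degrees, crucial for sparse
  networks), redraws weights Uniform(0,1) and rescales them to conserve the
  total weight exactly. Comparing `S(τ/τ_d)` of a network against its RWCM
  mean quantifies what the *organization* of its weights contributes.

## Worked example

```python
import funcstate as fs

net = fs.generate(fs.GeneratorSpec("watts_strogatz", 60, 11, {"k": 4, "p": 0.05}))
dec = fs.decompose(net)
print(f"N = {net.n_nodes}, edges = {net.n_edges}, diffusion time tau_d = {dec.diffusion_time:.3f}")

result = fs.sweep(net, fs.SweepConfig(n_points=9, seed=1))
table = result.entropy_curve.merge(result.module_count_curve, on=["tau_over_taud", "tau"])
table = table.merge(result.mean_strength_curve, on=["tau_over_taud", "tau"])
print(table[["tau_over_taud", "entropy", "n_modules", "mean_strength"]].round(4).to_string(index=False))
```

prints

```
N = 60, edges = 120, diffusion time tau_d = 6.718
 tau_over_taud  entropy  n_modules  mean_strength
        0.0000   4.0943          7         0.0000
        0.0000   4.0943          7         0.0000
        0.0000   4.0943          7         0.0000
        0.0000   4.0943          7         0.0000
        0.0000   4.0943          7         0.0008
        0.0007   4.0943          7         0.0199
        0.0178   4.0626          7         0.3604
        0.4217   1.9586          4         0.9435
       10.0000   0.0005          1         0.9833
```

Reading it: at tiny `τ/τ_d` the entropy sits at `log 60 = 4.094`, seven
structure-like modules exist and almost no flow has been exchanged; around
`τ ≈ τ_d` the entropy collapses and modules merge; by `τ/τ_d = 10` the state
is fully mixed — one module, `k̄ → 59/60 = 0.983`.

## Command line

```bash
funcstate generate --topology barabasi_albert --n-nodes 60 --param m=1 --seed 5 --out tree.tsv
funcstate sweep tree.tsv --n-points 50 --seed 1 --outdir out/          # curves + manifest
funcstate rwcm tree.tsv --n-realizations 20 --outdir nulls/            # null edge lists
funcstate compare tree.tsv --n-null 20 --out gap.csv                   # S_real vs S_null
funcstate corpus *.tsv --outdir summary/                               # cross-network means
funcstate plot out/entropy_curve.csv --y entropy --out entropy.png
```

Networks are tab-separated edge lists (`node node weight`, `#` comments) or
dense adjacency CSVs with a label header. Every sweep writes a
`manifest.json` (config, seed, table checksums) from which the run is
byte-for-byte reproducible.

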