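# Methods

## Model

`rewirenet` simulates activity-dependent structural plasticity as adaptive
rewiring driven by diffusion on a graph. Neural activity is abstracted as heat
flow: on a simple undirected graph with nonnegative weighted adjacency matrix
`A`, strengths `s_i = Σ_j A_ij` and strength matrix `D = diag(s)`, diffusion is
governed by the normalized graph Laplacian

    L = D^{-1/2} (D − A) D^{-1/2},   dh/dt = −L h,   h(0) = I,

whose solution is the heat kernel `h(t) = exp(−tL) = Σ_i e^{−λ_i t} v_i v_iᵀ`.
`h(t)_ij` is the amount of heat transferred from node i to node j by time t.
The eigenvalues of `L` lie in `[0, 2]`; the zero eigenvalue's multiplicity
counts connected components, and its eigenvector is proportional to
`(√s_1, …, √s_n)`, so the large-t kernel converges to the strength projector.

The rewiring iteration starts from an Erdős–Rényi graph with a fixed edge
count and repeatedly moves one edge:

1. choose a pivot node k uniformly among nodes with `0 < d_k < n−1`;
2. with probability `p_random` pick a non-neighbor j₁ and a neighbor j₂ of k
   uniformly; otherwise compute `h(τ)` on the **current** graph and let j₁ be
   the non-neighbor with the highest heat transfer with k and j₂ the neighbor
   with the lowest;
3. delete (k, j₂), add (k, j₁), carrying the deleted edge's weight.

Diffusion restarts from the identity on the current graph before every
diffusion-based decision, so each decision uses `h(τ) = exp(−τ L_current)`.
Random rewirings are treated as instantaneous (they consume no diffusion
time). Edge count and the multiset of edge weights are conserved for the
whole run; only the wiring changes.

The rewiring rate τ is the single control parameter of interest: small τ
confines heat to the pivot's neighborhood (local decisions → modular
networks), large τ integrates heat globally (→ centralized, hub-dominated
networks). `p_random` models adaptation to neural noise.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `node_count` n | 100 | network size |
| `edge_count` m | `round(2·ln(n)·(n−1))` = 912 at n=100 | twice the ER connectivity-critical density; mean degree 18.24 |
| `weight_regime` | `normal` | `binary` (all 1), `normal` N(μ=1, σ=0.25), `lognormal` ln-N(μ=0, σ=1) |
| `tau` | 3.0 | diffusion time per adaptive decision (dimensionless graph-diffusion time) |
| `p_random` | 0.2 | probability a rewiring is uniform-random |
| `total_rewirings` | 4000 | enough for networks to diverge from the random initial condition |

Weights are drawn i.i.d. at initialization and divided by the network maximum,
so they lie in (0, 1]. Negative draws from the normal regime are set to zero
as drawn; a zero weight is indistinguishable from a non-edge in an adjacency
matrix, so such pairs (probability ≈ 3×10⁻⁵ per edge) drop out of the edge
set and the realized m can very occasionally be one below the configured
value. Weights are never renormalized after initialization.

The edge-count rule is evaluated with nearest-integer rounding, which yields
912 at n = 100 (a literal floor yields 911); m is independently overridable.

Sentinel rates ε = 10⁻¹⁵ and δ = 10¹⁵ probe the asymptotic regimes. At δ the
exponentials of all nonzero eigenvalues underflow to exactly zero and the
kernel becomes the within-component strength projector — the intended limit.
At ε the analytic kernel is `I − τL + O(τ²)`, and the heat transferred to
*non-neighbors* is zero to first order; in double precision the surviving
differences (~10⁻¹⁶) are eigendecomposition round-off, not resolvable
diffusion signal, so shortcut selection at ε is effectively arbitrary among
non-neighbors. Tie-breaking among *exactly* equal heat values is uniform
random from the run's generator; near-ties from round-off are not detected or
randomized.

## Metrics

* **Clustering C** — binary: mean local triangle density. Weighted: Onnela
  geometric-mean clustering on weights normalized by the network maximum
  (coincides with the binary formula when all weights are equal).
* **Efficiency E** — global efficiency, the mean over ordered pairs of
  `1/d_ij` with shortest paths under edge length `1/w` (heavier edges carry
  flow better); disconnected pairs contribute 0.
* **Small-worldness S** = `(C/⟨C_rand⟩)·(E/⟨E_rand⟩)`, with the baseline an
  ensemble (default 100) of ER graphs with the same n, m and the same weight
  multiset placed at random. A random graph scores S ≈ 1 by construction.
  Absolute S values depend on this normalization choice; both factors are
  null-normalized here.
* **Modularity Q** — Newman leading-eigenvector bisection of the modularity
  matrix `B_ij = A_ij − s_i s_j / 2W` (`2W = Σ_ij A_ij`; strengths replace
  degrees in the weighted case), with Kernighan–Lin-style single-node moves
  refining each split, stopping when no split has positive gain. Q of the
  returned partition is ≥ 0 because the trivial partition is the fallback.
* **Degree-outlier proportion** — fraction of nodes with degree outside
  `⟨k⟩ ± 3√⟨k⟩` (Poisson dispersion, `⟨k⟩ = 2m/n`); indexes centralization.
  Degrees, not strengths, are used in every regime.
* **Assortativity r** — Pearson correlation of degrees across edge endpoints
  (both orientations); NaN when endpoint degrees have no variance.
* **Rich clubs** — club at threshold k: nodes with degree strictly > k.
  Topological Φ(k) is the club's internal edge density, normalized by
  degree-preserving Maslov–Sneppen rewired controls (default 10·m attempted
  double-edge swaps, weights carried with edges, 100 nulls). Weighted Φ_w(k)
  is the club's internal total weight, normalized by topology-preserving
  uniform weight shuffles. Curves are truncated where clubs have < 2 nodes.
* **Heavy tails** — Clauset-style fit of `P(x) ~ x^{−α}`: continuous-
  approximation MLE for α with x_min minimizing the KS distance (discrete MLE
  available as an option), plus Vuong loglikelihood-ratio comparisons of the
  power law against lognormal and exponential alternatives fitted to the same
  tail. Note that the KS-selected x_min materially determines α on degree
  samples whose body is not power-law: on centralized networks produced here,
  x_min lands near the distribution mode's upper edge (x_min ≈ 10) and
  α ≈ 2.2–2.4, while forcing small x_min (≈ 4) yields α ≈ 1.7. We report the
  KS-selected fit and expose `x_min` as an explicit argument.

## Sweeps and derived quantities

Sweeps replicate runs per (regime, τ, p_random) cell with per-run seeds
derived from the base seed by a counter scheme (`SeedSequence([base, cell,
run])`), aggregate means and standard errors, and cache per-cell tables so
interrupted sweeps resume. The modular→centralized transition rate
τ_transition is the midpoint of a four-parameter logistic
`lo + (hi−lo)/(1+e^{−slope(τ−mid)})` least-squares-fitted to the outlier
proportion versus τ (sentinel rates are excluded from the fit's τ axis).

**Correlation convention.** The correlation between small-worldness and its
two factors is computed from per-τ cell means at a fixed p_random (0.2 by
default in the analysis front end), matching how the per-τ curves are drawn;
`metric_correlation` pools whatever cells it is given and accepts explicit
`regime=`/`p_random=` restrictions. The S–C correlation along τ is robust to
this convention (≈ +0.97 to +0.99 under every pooling we examined). The S–E
correlation is not: per-τ means at one noise level are dominated by the joint
rise of S and fall of E between τ = 1 and 2 and give a strong negative value
(≈ −0.8 to −0.9), while pooling cells across several p_random levels
down-weights that segment toward a moderate negative value — but at a few
runs per cell that pooled estimate is too unstable to report (half-sample
estimates disagree by > 0.2). We therefore keep the fixed-p_random
convention and flag that the *magnitude* of ρ(S, E) is
convention-dependent; its sign and the contrast with the strongly positive
ρ(S, C) are not.

## What the generator does and does not emulate

Synthetic networks here are the model's own study conditions: fixed-size
(n = 100) dense-ish (⟨k⟩ = 18.24) undirected graphs with conserved weight
multisets. They emulate the statistical structure the model predicts —
modular, transition and centralized small-world topologies with topological
but not weighted rich clubs. They do not emulate real connectomes' spatial
embedding, directionality, leak (non-conservative dynamics), developmental
growth, or measurement noise in tract reconstruction; passing tests show
internal consistency of the model and metrics, not anatomical fidelity.

## Numerical choices

* Symmetry/PSD tolerances at 1e−8 absolute; eigenvalues clamped at 0 before
  exponentiation; eigenvector signs fixed so each vector's largest-magnitude
  entry is positive (Fiedler orderings are equivalence-class-valued under
  global sign flip).
* Isolated nodes get all-zero Laplacian rows/columns (the matrix-product
  definition), so they retain their heat: `h(t)_ii = 1`. Eligible pivots
  always have positive degree, so the choice only affects reporting.
* The heat kernel is recomputed from the current adjacency by dense
  eigendecomposition at every diffusion step (~1 ms at n = 100); a 4000-step
  run takes a few seconds.
* The logistic fit bounds the midpoint to the observed τ range and starts at
  the half-rise point; flat or short curves raise instead of returning
  garbage.
* Degenerate metric inputs signal NaN (assortativity without degree variance,
  rich-club thresholds with clubs < 2) or raise (empty-graph modularity,
  binary weighted rich club), as documented per function.

## Problem sizes used by tests and the acceptance analysis

Unit and property tests run on graphs of 2–60 nodes with closed-form or
brute-force oracles (series-expansion heat kernels, exhaustive partition
search, exact permutation averages). Reproduction-scale checks use the full
n = 100, m = 912, 4000-rewirings setting with 5–12 replicate seeds per
condition and 15–50-graph null ensembles; these sizes give stable means
(s.e.m. of Q ≈ 0.01–0.03 at 10 runs) while keeping a full suite run in
minutes.

## Known limitations

* Only symmetric, conservative diffusion is modeled (no directed flow or
  leak), matching the model's stated scope.
* The ε-sentinel regime's selection is round-off-driven (see above); results
  at ε should be read as "no resolvable diffusion signal", not as a
  well-defined fast-diffusion limit.
* Exact modularity maximization is NP-hard; the spectral bisection family
  with node-move refinement can return locally optimal partitions below the
  global optimum on adversarial graphs (verified exact on the small fixtures
  tested).
* The weighted clustering and small-world normalization follow one standard
  convention each (Onnela; both-factors null-normalized); absolute S values
  are convention-dependent even though qualitative conclusions are not.
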