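# rewirenet

Adaptive rewiring of weighted networks by graph heat diffusion.

Brain anatomical networks — from synapses to white-matter tracts — share three
structural signatures: small-worldness, modularity, and rich-club
organization. `rewirenet` implements a parsimonious generative model for all
three: starting from a random Erdős–Rényi network, edges carrying little
diffusive traffic are pruned while shortcuts are added where diffusion is
intense. Neural activity is abstracted as heat flow governed by the normalized
graph Laplacian `L = D^{-1/2}(D − A)D^{-1/2}`, whose kernel
`h(τ) = exp(−τL)` measures the heat transferred between every node pair after
diffusion time τ. Each adaptive step picks a pivot node k, connects it to the
non-neighbor with the *highest* heat transfer `h(τ)_kj`, and cuts the edge to
the neighbor with the *lowest*, carrying the cut edge's weight; with
probability `p_random` the step is uniform-random instead (neural noise).

The rewiring rate τ steers the outcome: fast rewiring (small τ) yields
modular networks, slow rewiring (large τ) centralized hub-dominated ones,
with a transition zone in between. The package supports binary,
normally-distributed (μ=1, σ=0.25) and lognormally-distributed (μ=0, σ=1)
edge weights, and ships the full metric suite used to characterize the
outcomes: clustering C, global efficiency E, null-normalized small-worldness
S = (C/⟨C_r⟩)(E/⟨E_r⟩), Newman spectral modularity Q (strength-based),
degree-outlier proportion, assortativity, topological and weighted rich-club
curves against degree-preserving and weight-shuffling null models, and
Clauset-style power-law tail fits.

Intended users: computational/systems neuroscientists and network scientists
studying self-organization of connectivity, or anyone needing a clean
reference implementation of diffusion-based adaptive rewiring with matched
null models.

## Worked example

```python
import rewirenet as rw

# modular regime: normal weights, tau = 3, 20% random rewirings
cfg = rw.RewiringConfig(weight_regime="normal", tau=3.0, p_random=0.2, seed=1)
g, trace = rw.run_rewiring(cfg)

q, communities = rw.modularity_spectral(g)
s = rw.small_worldness(g, rw.NullEnsembleConfig(n_nulls=100, seed=1))
print(f"n={g.node_count} m={g.edge_count}")
print(f"Q={q:.2f}  S={s:.2f}  outliers={rw.outlier_proportion(g):.2f}")
```

prints

```
n=100 m=912
Q=0.73  S=3.31  outliers=0.07
```

A modularity of 0.73 means the rewired network is strongly modular (a random
graph at this density scores ≈ 0.2); S ≈ 3.3 says its clustering is ~3×
higher than matched random controls at comparable efficiency; only 7% of
nodes have degrees outside the Poisson band ⟨k⟩ ± 3√⟨k⟩, so the network is
not centralized. Rerunning with `tau=5.0` instead collapses Q to ≈ 0.2 and
raises the outlier share to ≈ 0.4 — a centralized network with the *same*
small-worldness.

The same simulation from a shell:

```sh
rewire run --n 100 --m 912 --weights normal --tau 3.0 --p-random 0.2 \
           --steps 4000 --seed 1 --snapshot-every 1000 --out run1/
rewire metrics --in run1/final_adjacency.txt --weighted --nulls 100 \
               --seed 7 --out report.json
rewire sweep --config sweep.yaml --out cells/
rewire analyze cells/ --report summary.json
```

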