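# burstnet

Cascades on burstiness-controlled temporal networks: renewal-process edge
dynamics with finite memory, threshold and epidemic contagion models, an
approximate master equation on the edge-state configuration space, an
event-driven Monte Carlo simulator, and the analytic temporal-percolation
phase boundary.

## The problem

Real interaction sequences — emails, messages, neural spikes — are *bursty*:
events cluster in short active periods separated by long silences.  burstnet
models each edge of a static skeleton as an independent stationary renewal
process with interevent-time law ψ(τ) (exponential, Weibull, gamma,
lognormal, or generalized gamma, matched by mean ⟨τ⟩, standard deviation
σ_τ, and optionally skewness γ_τ).  A memory kernel determines how long an
event contributes to the interaction strength of its edge: a step kernel
(constant for a window η) or an exponential kernel (forgotten at rate 1/η).
The *state* j of an edge is the number of events in active memory, and the
interaction strength is w_j = j.

On top of this temporal network a binary-state, non-recovering contagion
runs with background noise p and transmission rate F determined by the
node's influence vectors **k**, **m** (counts of edges and infected
neighbours per edge state):

| model | F |
|---|---|
| RT (relative threshold) | 1 if **m**·**w** ≥ φ **k**·**w**, else p |
| AT (absolute threshold) | 1 if **m**·**w** ≥ M_φ, else p |
| SI (epidemic) | max(p, λ **m**·**w**) |

Two engines produce ρ(t), the infected density, and the diffusion measures
ρ_f (fraction of infections due to noise) and t_f (spreading time normalised
by the noise-only time −ln(1−ρ_c)/p):

* **Monte Carlo** (`burstnet.simulate`): event-driven simulation merging the
  renewal event/expiry queue with exact Gillespie node dynamics, started
  from the stationary edge-state law.
* **Master equation** (`burstnet.master_eq`): densities s_{k,m} of
  uninfected nodes per configuration class evolve under ego (−F), neighbour
  (β_j) and edge (μ_j, ν_j) transitions, ds/dt = (W_ego + W_neigh + W_edge)s.

The edge rates come from Laplace-domain convolution identities,
E_j ∝ (Ψ∗ψ^{∗(j−1)}∗Ψ)(η), inverted by the Gaver–Stehfest algorithm in
extended precision (`burstnet.edge_state`), with a direct grid-convolution
oracle as an independent cross-check.  For exponential ψ the chain is the
Poisson closed form E_j = Poisson(η/⟨τ⟩), μ_j = 1/⟨τ⟩, ν_j = j/η.

The stationary fraction of inactive edges, the *effective sparsification*

    ξ_E = (1/⟨τ⟩) ∫_η^∞ Ψ(τ) dτ,

controls a percolation transition: the expected sub-graph of active edges
loses its giant component when (1 − ξ_E)⟨k(k−1)⟩/⟨k⟩ ≤ 1 (Molloy–Reed).
`burstnet.percolation` solves ξ_E(σ_c; η) = 1 − ⟨k⟩/⟨k(k−1)⟩ for the
critical burstiness σ_c per interevent-time family.

## Worked example

Critical burstiness of the giant temporal component for a lognormal degree
distribution (⟨k⟩ = 7, σ_k = 0.5) at memory η = 10:

```
$ burstnet percolation --eta 10
gamma        eta=10  sigma_c = 14.45
weibull      eta=10  sigma_c = 79.1
lognormal    eta=10  sigma_c = 1186
```

At the same mean and standard deviation, the three families produce
order-of-magnitude different temporal connectivity: the gamma law anneals
the network (pushes edges into state 0) far faster than the Weibull, which
in turn is far faster than the lognormal.  Mean and variance alone do not
determine the dynamics; the next moment (skewness) does, which is why the
generalized gamma family interpolates these boundaries smoothly.

The stationary edge-state chain for a Poisson (exponential-ψ) edge process:

```
$ burstnet spectrum --family exponential --sd 1 --eta 1 --n 5
 j        E  mu  nu
 0 0.367879 1.0 0.0
 1 0.367879 1.0 1.0
 2 0.183940 1.0 2.0
 3 0.061313 1.0 3.0
 4 0.015328 1.0 4.0
xi_E=0.367879 xi_mu=1 tail_mass=0.00366
```

E is the stationary occupancy (here Poisson(1)), mu/nu the upward and
downward transition rates of the induced birth–death chain; detailed
balance μ_j E_j = ν_{j+1} E_{j+1} holds for every ψ.

Cascade experiments are described by a flat YAML run configuration and run
with either engine:

```
$ burstnet simulate run.yaml     # Monte Carlo, per-realization rho_f / t_f
$ burstnet solve run.yaml        # master equation on the same system
$ burstnet ingest events.tsv     # interevent stats of an empirical edge list
```

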