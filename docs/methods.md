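# Methods

This note documents the models, numerical choices and known limitations of
burstnet, in the package's own terms.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Temporal network model

A static configuration-model skeleton carries independent stationary
renewal processes on its edges.  The interevent-time law ψ is chosen from a
parametric family and fixed by its moments; all experiments use ⟨τ⟩ = 1 so
that time is measured in mean interevent times (general means are supported
and normalised internally).  Stationarity means the time from a random
observation instant to the next event follows the residual law Ψ(t)/⟨τ⟩,
which is how every simulation is initialised: the clock is wound to −η, one
residual draw is made per edge, and subsequent gaps are i.i.d. ψ draws, so
that the edge-state distribution at t = 0 is exactly stationary in the
large-network limit.

The memory kernel defines the edge state j:

* **step**: j counts events in the trailing window (t − η, t];
* **exponential**: each event is remembered for an independent Exp(η)
  lifetime, modelling content whose visibility decays at rate 1/η.

Interaction strength is additive in remembered events, w_j = j, so the mean
edge state is η/⟨τ⟩ regardless of ψ — burstiness redistributes strength in
time without changing its average.

## Edge-state spectrum

For the step kernel the stationary occupancies and transition rates of the
induced birth–death chain are convolution identities evaluated at the
window width:

    E_j   = (Ψ ∗ ψ^{∗(j−1)} ∗ Ψ)(η) / ⟨τ⟩            (j ≥ 1)
    μ_j   = (Ψ ∗ ψ^{∗j})(η)   / (Ψ ∗ ψ^{∗(j−1)} ∗ Ψ)(η)
    ν_j   = (Ψ ∗ ψ^{∗(j−1)})(η) / (Ψ ∗ ψ^{∗(j−1)} ∗ Ψ)(η)

with the j = 0 members given by the effective sparsification
ξ_E = E_0 = (1/⟨τ⟩)∫_η^∞ Ψ and its escape rate ξ_μ = Ψ(η)/∫_η^∞ Ψ.  The
convolutions are evaluated in the Laplace domain and inverted at η; this
normalisation reproduces the Poisson closed form (E_j = Poisson(η/⟨τ⟩),
μ_j = 1/⟨τ⟩, ν_j = j/η) exactly for exponential ψ at any mean, and makes
detailed balance μ_j E_j = ν_{j+1} E_{j+1} an algebraic identity (both
sides equal (Ψ∗ψ^{∗j})(η)/⟨τ⟩).

Numerics.  The Gaver–Stehfest inversion is catastrophically ill-conditioned
in doubles, so transform values and weights are computed with mpmath at 60
significant digits, 16 terms.  Transforms use closed forms where available
(exponential, gamma) and otherwise quadrature after substitutions that
remove the density singularity (u = (t/λ)^c for Weibull/generalized gamma;
x = log τ for the lognormal) over analytically capped finite windows.  The
method's absolute accuracy is ~1e−6; occupancies below that floor can
surface as small negatives and are clipped.  Sub-Poissonian laws
(σ_τ < ⟨τ⟩) concentrate the convolutions sharply and degrade Stehfest
convergence; when the inversion produces negatives beyond 1e−5 the package
falls back automatically to the direct route below, which is authoritative
whenever the two disagree.

The independent cross-check, `spectrum_by_convolution`, discretizes ψ into
cell masses Ψ(x_i) − Ψ(x_{i+1}) with atoms at cell midpoints — exact in
total mass even for densities with an integrable singularity at zero — and
evaluates the identities by discrete convolution.  Occupancies converge at
second order in the grid step, the rate ratios at first order.

For the exponential kernel no transform route is derived; the state-0
fraction is estimated by Monte Carlo over stationary renewal histories,
taking the expectation over the independent memory coin-flips analytically
within each history (mean of Π_i (1 − e^{−a_i/η}) over past-event ages
a_i).  Ages beyond η·ln(1e12) and histories whose log-probability falls
below −45 are abandoned, bounding the work per history.

## Contagion models and observables

All three models are non-recovering with background noise p > 0.  A node
with k·w = 0 (no active influence) infects only at rate p under RT — the
relative threshold compares influences, and with nothing to compare the
social channel is closed; this convention is required for the annealed
limit η → 0 to reduce to pure noise growth ρ = 1 − e^{−pt}.  Threshold
comparisons carry a 1e−9 slack because φ·(k·w) may round one ulp above an
exactly attained integer threshold.

Observables follow the noise-accounting identities: ρ̃(t) = p∫_0^t(1−ρ),
ρ_f = ρ̃(t_c)/ρ(t_c) at the first crossing of the cutoff density ρ_c, and
t_f = t_c/(−ln(1−ρ_c)/p).  The simulator additionally counts the firing
channel of every infection (noise iff F = p at the instant of firing),
reported as `rho_f_counted`; the analytic ρ̃-based ρ_f is the headline
value and the two agree closely in practice.

## Monte Carlo engine

A single binary heap orders edge events and memory expiries, deterministic
ties broken by (time, edge id, kind).  Between structural events every
transmission rate is constant, so node infections are scheduled exactly
with one aggregate exponential clock at the total rate R, resampled
whenever R changes (memorylessness makes resampling exact); the firing node
is then drawn proportionally to its rate — membership pools with O(1)
swap-removal for the two-level RT/AT rate structure, a linear scan for SI.
This is an exact reformulation of per-node next-reaction clocks with
invalidation, chosen because it makes the per-event cost O(1).  Interevent
draws beyond the horizon are discarded unrealised, keeping heavy-tailed
streams bounded.

Sampling heavy-tailed ψ uses inverse-transform on a logarithmic survival
grid: levels log-spaced from 1 down to 1e−12, node times found by
bisection on log τ to relative tolerance 1e−10, a third-order spline in
(log Ψ, log τ) between nodes, analytic tail inversion below the grid floor,
and vectorized bisection above the highest node.  The compiled kernel uses
a denser linearly-interpolated version of the same table.  One genuine
double-precision limit: gamma-family laws with σ_τ ≳ 15⟨τ⟩ place
substantial true mass below 1e−300; those draws return the float floor,
which is the correct representable value (such events are instantaneous
bursts for every purpose in this model).

## Master equation

Classes (k, m) are enumerated exhaustively in lexicographic tuple order for
every degree in a truncated support; |C_k| = C(k+2n−1, 2n−1), so the space
over a support up to k grows as Θ(k^{2n}).  The uninfected densities
s_{k,m}, normalised per underlying degree, evolve under the ego, neighbour
and edge transition table; infected densities evolve under the same
neighbour and edge flows without the ego term, which makes per-degree
conservation Σ(s + i) = 1 an auditable invariant (integrator-level defect
≤ 1e−8 in the tests).  β_j is the ensemble rate of uninfected-neighbour
infection behind a state-j edge, recomputed from the current s at every
right-hand-side evaluation; an empty ensemble yields β_j = 0, whose flows
carry zero weight.  Applying the network-wide rates μ_j, ν_j and β_j at
class level is a mean-field approximation; it is exact for the network as
a whole but deviates slightly per class.

Finite representation.  The edge chain is truncated to n states with the
spectrum's tail mass folded into the top state; μ_{n−1} = 0 and ν_{n−1} is
rebalanced so the folded chain keeps E stationary exactly.  The initial
condition places all nodes uninfected with k-vectors multinomial in the
folded E_j.  A strict tail target (1e−6) would require n ≈ 10 at η = ⟨τ⟩,
which the Θ(k^{2n}) growth makes prohibitive; production solves use n = 4–5
(tail ≲ 2%) and a degree cutoff at cumulative probability 0.99
(renormalised pmf, k_max = 13 for lognormal(7, 2)) — chosen so the solve
completes in tens of seconds to minutes; the simulator uses the same
truncated pmf whenever the two engines are compared, so cross-validation is
unaffected by the truncation itself.

Integration is explicit adaptive Runge–Kutta (relative tolerance 1e−6,
absolute 1e−10), stepped manually so the trajectory is recorded at the
solver's own resolution without retaining the full state history; the
ρ_c crossing is refined by bisection on the local dense interpolant.

## Percolation boundary

The expected instantaneous active-edge graph is the skeleton under
binomial edge thinning with removal probability ξ_E, so the giant
component criterion is (1 − ξ_E)⟨k(k−1)⟩/⟨k⟩ > 1 with moments of the
*discretized* degree pmf actually sampled (lognormal rounded to the nearest
integer, k ≥ 1; the induced moment shift at σ_k ≤ 2 is below 2%).  σ_c
solves ξ_E(σ) = 1 − ⟨k⟩/⟨k(k−1)⟩ by bisection on log σ (relative tolerance
1%), with geometric bracket expansion.  For a fixed generalized-gamma
skewness target the family exists only on an interval of σ; outside it the
solver classifies the endpoint by comparing the target against the
lognormal skewness limit (σ²+3)σ.  A simulation oracle deletes state-0
edges from one stationary snapshot and measures the largest component.

## Synthetic data and what the tests show

All networks and event streams are generated by the package itself: the
configuration model (erased variant; erased-stub counts reported) with
discretized lognormal degrees emulates the heavy-but-not-fat degree spread
of communication networks, and the renewal streams emulate per-edge
burstiness with uncorrelated gaps.  Real temporal networks additionally
exhibit inter-edge correlations, circadian and weekly rhythms
(nonstationarity), and degree–activity correlations — none of which the
generator produces, so passing tests demonstrate correctness of the model's
mathematics, not fidelity of these simplifications to any particular data
set.  Empirical edge lists can be ingested (`burstnet ingest`) for the
pooled interevent statistics over edges with more than one event, but no
data ship with the package.

Problem sizes in the test suite are the package's own scaling choices:
Monte Carlo ensembles of 2 000–10 000 nodes with 3–100 realizations,
master-equation spaces up to ~2×10^5 classes, 10^5-edge percolation
snapshots, and 4×10^4–10^5 renewal histories for the exponential-kernel
estimator.  One cross-engine fact documented by the suite: at N = 10^4 the
ensemble-mean Monte-Carlo ρ(t) lags the master-equation curve by up to
~0.1 near the cascade takeoff because discrete noise seeding delays finite
systems (takeoff-time jitter is of order the takeoff width itself); the gap
shrinks monotonically with N and is ≲ 0.02 at N = 10^5.  ρ_f and t_f are
insensitive to this jitter and agree to three decimals already at N = 10^4.

## Known limitations

* Step-kernel master-equation rates only; the exponential kernel is
  simulation-only (plus the Monte-Carlo state-0 estimator feeding the
  percolation criterion).
* No recovery dynamics, adaptive rewiring, correlated interevent times, or
  nonstationary (aging) renewal processes.
* The lognormal law is represented natively; the generalized-gamma
  skewness solver refuses targets at or beyond the lognormal limit rather
  than chasing the numerically degenerate c → 0 corner.
* Gamma-family sampling below 1e−300 saturates at the float floor (see
  above); all double-precision samplers share this bound.
* Large memory η entails a large mean edge state and a configuration space
  growing as k^{2n}; master-equation solves at η ≫ ⟨τ⟩ are impractical and
  the simulator is the intended tool there.
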