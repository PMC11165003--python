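# Methods

## The model

`syncpath` addresses networks of `N` identical `m`-dimensional dynamical
units coupled diffusively through a graph:

    dx_i/dt = f(x_i) - d * sum_j L_ij g(x_j) ,

where `f` is the local flow, `g` a linear output function through which the
units interact, `d >= 0` the coupling strength, and `L = D - A` the
combinatorial Laplacian of a connected, undirected, nonnegatively weighted
graph. Zero row sums of `L` make the fully synchronized state
`x_1 = ... = x_N = x_s(t)` invariant for every `d`.

As `d` grows from zero the network does not jump to full synchrony: it passes
through a sequence of intermediate states in which specific groups of nodes
evolve in unison while the rest stay incoherent. The package predicts that
whole sequence — the node membership of every cluster, the order of events,
and the critical coupling of each — from the eigendecomposition of `L` alone,
then verifies it by direct simulation.

## Spectral prediction

Let `0 = λ_1 < λ_2 ≤ ... ≤ λ_N` be the Laplacian eigenvalues with
orthonormal eigenvectors `v_1 ... v_N` (columns of `V`). Linear stability of
the synchronized state decouples into independent modes governed by the
parametric variational equation (next section) evaluated at `ν = d λ_i`;
mode `i` is damped once `d λ_i` exceeds the critical intercept `ν*`. As `d`
increases, modes therefore stabilize in decreasing order of `λ_i`.

Clusters appear when eigenvectors are *localized*. For each eigenvector index
define the squared component-difference matrices and their cumulative sums

    E_{λ_i}[j,k] = (v_i[j] - v_i[k])^2 ,     S_n = Σ_{k≥n} E_{λ_k} .

Because the rows of `V` are orthonormal, every off-diagonal entry of `S_n` is
at most 2, with equality exactly when nodes `j` and `k` have identical
components on *all* eigenvectors below index `n`. Scanning the degenerate
eigenvalue blocks in decreasing order and collecting the node pairs whose
`S` entry equals 2 at each block boundary yields the events: each group of
pairs (closed transitively) synchronizes at `d = ν* / λ_block`. The final
boundary is `λ_2`, where all off-diagonals of `S_2` equal 2 — complete
synchronization at `d_c = ν* / λ_2`.

Detection happens **only at block boundaries**: inside a degenerate block the
partial sums depend on the arbitrary choice of basis within the eigenspace,
while the boundary sum is determined by the block's spectral projector and is
therefore basis-invariant (property-tested by rotating each degenerate block
with a random orthogonal matrix).

Equivalently (and this is the combinatorial anchor of the whole scheme), a
set of `k` nodes supports a spectral block of `k - 1` localized eigenvectors
if and only if it is an **external equitable cell**: every member has
identical connections, with identical weights, to every node outside the set.
`equitable_cells` computes these directly from the Laplacian rows
(pair relation + signature refinement to a fixed point), and `verify_plan`
cross-checks every predicted cluster against the cell condition.

### Numerical tolerances of detection

Two tolerances matter:

* **Degeneracy grouping** (`grouping_tol`, default `1e-8` relative):
  consecutive eigenvalues are chained into one block when their gap is below
  `tol * max(1, λ)`. Double-precision symmetric eigensolvers resolve
  well-separated spectra far better than this.
* **Entry-equals-2** (`entry_tol`, default `1e-11`): for a genuine cell pair
  the deviation of the `S` entry from 2 is pure solver noise (measured at or
  below ~3e-14 up to N = 1000), while the nearest "impostor" pair — two bulk
  nodes on which every eigenvector below the inspected block happens to be
  nearly constant — can come as close as ~1e-10 on graphs whose low modes
  localize strongly. The default sits between the two with two to three
  decades of margin on either side.

A hard limitation follows from the same mechanism: when the Fiedler vector
itself is strongly localized (e.g. a large random core carrying small planted
structures), some non-cell pairs differ on the excluded modes by *less than
solver noise*, and no tolerance can separate them. On such graphs raw
detection necessarily emits extra candidate clusters. These candidates are
exactly what `verify_plan` exists for: the combinatorial cell condition is
evaluated in exact weight arithmetic and flags every impostor. The CLI marks
unverified events, and `cluster_census` (used for whole-network cluster
counts) excludes them. On the package's 1000-node planted benchmark the
filtered output equals the planted ground truth exactly.

The transitive-closure step checks that the "entry ≈ 2" relation is
numerically an equivalence relation: since `|S - 2|` is a squared distance
between truncated eigenvector rows, a chain of `L` pairs within `tol` bounds
every same-cluster pair by `(L-1)^2 tol`; a violation beyond `4 L^2 tol`
aborts with a diagnostic instead of emitting a corrupt cluster.

## Master Stability Function

The variational equation of the synchronized state, mode by mode, is

    dη/dt = [Jf(x_s) - ν Jg] η ,    ν = d λ ,

driven by the isolated trajectory `x_s(t)`. Its largest Lyapunov exponent
`Λ(ν)` is the Master Stability Function. The sign pattern over `ν ≥ 0`
classifies every flow/output pair: Class I (never negative — the system
cannot synchronize), Class II (single crossing `ν*` — threshold
`d_c = ν*/λ_2`), Class III (negative only on `(ν1*, ν2*)` — both
`d λ_2 > ν1*` and `d λ_N < ν2*` required, giving an upper bound
`d_max = ν2*/λ_N` beyond which events are flagged unreachable).

`Λ(0)` equals the isolated unit's largest Lyapunov exponent, which is why the
machinery targets chaotic units: a periodic unit has `Λ(0) = 0`, hence
`ν* = 0` and no intermediate clusters.

Exponents are estimated with the single-vector Benettin method: the base
trajectory is integrated past a transient (default 200 time units), then base
and one tangent vector are co-integrated with the tangent renormalized every
1 time unit, averaging the logarithmic growth over the window (default 2000
units). Integration uses an adaptive eighth-order Runge–Kutta scheme at
`rtol = atol = 1e-9`. Initial states default to the system's reference point
plus a seed-controlled 1e-3 jitter (the attractor is reached during the
transient); the same seed gives bitwise-identical estimates, and `Λ(ν)` is a
smooth function of `ν` for a fixed seed, which keeps bisection well-behaved.

Intercepts are located in two stages (`find_nu_star`): a coarse grid scan
with a short 400-unit window brackets the sign changes, then bisection on
fresh full-window estimates refines each root. For systems whose exponent
converges slowly near the crossing, the refinement window can be raised; the
shipped benchmark protocol uses 5000 units for the Rössler system and 2000
for the Lorenz system.

Built-in systems (per-component output selectors, analytic Jacobians checked
against finite differences):

| system  | flow                                           | defaults                    | output (default) |
|---------|------------------------------------------------|-----------------------------|------------------|
| rossler | `(-y-z, x+ay, b+z(x-c))`                       | `a=b=0.1, c=18`             | `(0, y, 0)`      |
| lorenz  | `(σ(y-x), x(ρ-z)-y, xy-βz)`                    | `σ=10, ρ=28, β=2`           | `(x, 0, 0)`      |
| linear  | `x' = rate·x` (1-d)                            | `rate=1`                    | `x`              |

The linear system's MSF is exactly `Λ(ν) = rate − ν`, which serves as a
closed-form validation of the whole Benettin pipeline (agreement to 1e-6 is
asserted in the tests; in practice it is ~1e-10). Its Jacobian is
state-independent, so no base trajectory is integrated — the flow itself
diverges exponentially and would overflow any long window.

**A reproducibility note on the Rössler intercept.** With the parameters and
output above, our converged estimate of the y-coupled intercept is
`ν* ≈ 0.164–0.165` (windows of 2000 → 20000 units give 0.153 → 0.1645, with a
saturating trend), while a commonly quoted value for this setup is 0.179. The
same machinery reproduces the Lorenz intercept 7.322 to 0.6% and the linear
closed form to 1e-10, and the discrepancy survives alternative coupling
components, nearby parameter sets, loose integrator tolerances, and distant
initial conditions; coupling through `x` instead crosses near 0.195 (and is
Class III). Empirical thresholds read off finite-time network simulations are
biased slightly above the true MSF intercept, which is consistent with the
larger quoted value. The package reports what it computes.

## Network simulation and synchronization error

`simulate_network` integrates the full `N·m`-dimensional coupled system
(adaptive RK45, `rtol = 1e-6`, `atol = 1e-9`), with per-node uniform
initial-condition jitter of amplitude 1 around the system's reference state.
Trajectories are stored downsampled (every 0.1 time units) to bound memory;
all error computation uses the stored samples. Defaults follow the study
conditions: 1500 time units per trial, errors averaged over the final
`ΔT = 100` units.

Cluster synchronization is quantified by

    E_cl = ⟨ ( (1/N_cl) Σ_i |x_i − x̄_cl|² )^{1/2} ⟩_{ΔT} ,

the time-average over the final window of the RMS deviation of the cluster
members from their instantaneous cluster mean. Only the coupled state
components are tracked by default (the error vanishes on a synchronized
cluster in either mode; this matches how the coupling acts). Sweep curves are
ensemble-averaged over seed-varied runs and normalized by the per-curve
maximum over the coupling grid, so each curve runs from 1 down to 0; the
normalization convention is recorded in the output metadata.

`empirical_thresholds` reports the smallest grid coupling at which a
normalized curve falls below `eps_sync` (default 0.01) *and stays below* for
all larger grid values — a transient dip does not count. The default band
sits well below desynchronized plateaus and above ensemble noise at
10-member ensembles.

Heterogeneity: `HeterogeneitySpec(parameter, ε)` gives node `i` a parameter
value drawn uniformly from `[p−ε, p+ε]`. With heterogeneous units the exact
synchronous solution no longer exists and errors fluctuate around zero
rather than vanishing; the *ordering* of cluster emergence is preserved for
small ε, and that ordering (not a numeric band) is what the tests assert.

## Synthetic generators

`planted_cluster_graph` builds networks with analytically known cluster
structure: a random Erdős–Rényi core (`p = 2 ln n / n` by default, connected
with high probability, regenerated on disconnection up to 20 retries) plus
ensembles of `k` nodes each attached with unit weight to the *same* `m`
randomly chosen core nodes. Every ensemble is an external equitable cell by
construction and contributes `k−1` degenerate eigenvalues equal to `m`
(internally empty ensembles; an internal clique of weight `w` shifts the
localized eigenvalue to `m + k w`), with eigenvectors supported on the
ensemble — verified constructively via `L(e_p − e_q) = m (e_p − e_q)`.
Generation validates that the combinatorial cells of the result equal the
planted cells plus singletons and aborts otherwise (an accidental twin pair
in the random core would silently change the ground truth).

`count_localized_eigenvalues` counts localized modes robustly under
degenerate mixing: solvers may return an eigenbasis that mixes localized and
delocalized directions of one eigenspace, so the count is the nullity of the
eigenvector rows outside the cluster (via SVD), not a per-vector support
test.

`orbit_weighted_graph` builds graphs whose nodes split into fully
interchangeable symmetry orbits (equal intra-orbit weights, equal weights to
every node of each other orbit). `three_orbit_demo_graph` is a worked
10-node, all-to-all instance with orbits {1,2,3}, {4,5,6}, {7,8,9,10} whose
rational weights (solved exactly from the localized-eigenvalue and quotient
conditions, with the quotient eigenvector constraint that makes orbit 2 join
the existing cluster rather than form its own) give the Laplacian spectrum
exactly `{0, 1,1,1, 4,4,4, 6,6,6}` and the three-event accretion transition:
formation of {7,8,9,10} at relative coupling 1/6, growth by {4,5,6} at 1/4,
complete synchronization at 1. It is a synthetic stand-in fixture
constructed to this spectrum, not a published adjacency.

## Scale choices in the shipped tests

The acceptance-style tests run at desk scale, chosen as the package's own
reduced protocol: MSF intercepts from 11-point scans plus ~10 bisection
steps; the planted-degeneracy benchmark at N = 1000 (dense eigendecomposition
in ~1 s); simulation sweeps on the 4-node worked fixture (10 couplings,
600-unit runs) and a 50-node planted fixture (11 couplings, 500-unit runs),
both with 10-member ensembles. Larger ensembles and longer runs sharpen the
curves but do not move the thresholds at the tolerances asserted.

## Known limitations

* The critical couplings for *cluster* states are approximations: they reuse
  the MSF of the fully synchronized trajectory, whereas a cluster's true
  synchronous trajectory feels a coupling-dependent perturbation from the
  rest of the network. The approximation is good in the small-`d` transition
  regime, which is where the predictions are used; stability analysis on the
  quotient trajectory is out of scope.
* Raw S-matrix detection can emit impostor candidates on graphs with strongly
  localized low modes (see the tolerance discussion above); downstream
  consumers should use the verified/filtered views.
* Directed graphs, negative weights and normalized Laplacians are out of
  scope; dense eigendecomposition is refused above N = 20000 because the
  method needs the complete spectrum.
* Periodic units (`ν* = 0`) are rejected at plan-scaling time; the relative
  (topology-only) plan remains well-defined.
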