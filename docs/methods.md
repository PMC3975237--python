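# Methods

## Model

The monolayer is `N = L x L` cells on a square lattice with periodic
boundaries, one molecule per cell, between two hard walls separated by
`h ~ 1.7 r0` (about 0.5 nm for water).  The walls act by excluded volume
only; the height coordinate is coarse-grained away, so the system is a 2D
projection.  Degrees of freedom:

* four bonding indices `sigma_ij in {0..q-1}` per molecule, one per arm.
  `q = 6` because a hydrogen bond survives only within about one sixth of
  the full range of the relevant bonding angle, so `q` counts the entropy of
  bond breaking correctly.
* one continuous volume `V0 >= N v0` shared by all cells (**homogeneous
  cells**): the discretised density field `n_i` is then a single global flag,
  `n = 1` iff the per-cell density ratio exceeds the occupancy threshold
  (default 1/2, i.e. `V0/N < 2 v0`).  The threshold reproduces the geometric
  hydrogen-bond cutoff: bonds die exactly when the nearest-neighbour distance
  reaches `r_max = r0 sqrt(2)` (4.1 Å at `r0 = 2.9` Å, an OH–O distance of
  3.14 Å after subtracting `r_OH = 0.96` Å).

Enthalpy:

```
H = U_iso(V0) - J N_HB - J_sigma N_coop + P (V0 + N_HB v_HB)
```

`U_iso` is a shell sum: with homogeneous cells all pair distances are lattice
distances scaled by `ell = sqrt(V0/N)`, so the O(N^2) pair sum collapses onto
precomputed shell multiplicities.  The pair potential is a hard core below
`r0` plus the Lennard-Jones form `eps[(r0/r)^12 - (r0/r)^6]` up to the cutoff
`25 r0`; the well shape is a configurable modelling choice of this package.
`N_HB` counts matching facing indices across occupied edges (max `2N`);
`N_coop` counts equal pairs among each molecule's six index pairs (max `6N`)
and is deliberately not gated by occupancy, consistently with the cluster
rule below.  Defaults `J = 0.5 eps`, `J_sigma = 0.05 eps`, `v_HB = 0.5 v0`:
the directional bond dominates the cooperative term by an order of
magnitude, and each bond's volume increment is the average expansion from
the high-density to the tetrahedral low-density local structure.

### The volume measure

The density field replaces the molecules' translational degrees of freedom,
which leave behind the configurational measure `V0^N dV0`
(`ModelParams.free_volume_entropy`, default on).  This term is what gives
the volume an extensive entropy `-N k_B T ln(V0/N v0)`: without it a single
global `V0` has only `O(T/N)` thermal expansion and the model has no density
maximum and no liquid–gas transition at any size.  The bare measure `dV0`
remains available (off) and is used by the closed-form tests (the ideal
system then has exponential excess volume with mean `k_B T / P`).  Both
measures are `(beta, P)`-independent, so all fluctuation–dissipation
identities hold under either.

## Monte Carlo

NPT sampling alternates:

* **Wolff cluster updates of the indices.**  Links: intra-molecular between
  any two arms of a molecule with probability `1 - exp(-beta J_sigma)`, and
  inter-molecular between facing arms with `1 - exp(-beta J_eff)`,
  `J_eff = max(J - P v_HB, 0)`, active only while cells are occupied.
  Folding the bond-volume enthalpy into `J_eff` makes the move
  rejection-free in NPT; the construction is exact for `P <= J / v_HB`
  (all quantitative oracle comparisons live there).  The whole cluster is
  relabelled to a uniformly drawn different value.  One sweep seeds one
  cluster per arm by default; `clusters_per_sweep` can be reduced when
  clusters span the system (deep in the ordered phase a single cluster
  already decorrelates the field, and the stride estimator compensates).
* **Volume moves.**  Symmetric uniform steps in `V0`, Metropolis acceptance
  on the full change: isotropic energy, `P dV0`, the free-volume term
  `N ln(V0'/V0)`, and — when the occupancy flag flips — the bond term
  `-(J - P v_HB) dN_HB`.  The step size is auto-tuned to 30–50% acceptance
  during equilibration, then frozen.

Randomness is a splitmix64 counter generator; every series is
bit-reproducible from `(seed, stream)`.  The decorrelation stride is
estimated from the integrated autocorrelation time of the energy density
during equilibration (Sokal window) unless set explicitly, and recorded in
the series metadata.  Annealing runs each isobar from a random high-`T`
state downward, chaining final states.

**Equilibration criterion:** the fluctuation routes
`K_T = <dV^2>/(k_B T <V>)`, `C_P = <dH^2>/(k_B T^2)`,
`alpha_P = <dV dH>/(k_B T^2 <V>)` must agree with centred finite differences
of `<V>` and `<H>` across neighbouring state points within the jackknife
errors (`check_equilibration`).  The `alpha_P` cross-fluctuation form is the
standard NPT identity; it is cross-validated against the derivative route
throughout.

## Observables and loci

Response functions are computed by both routes with jackknife errors over
sample blocks.  Points whose volume or enthalpy distribution is clearly
bimodal are flagged as coexistence and their fluctuation-route values
suppressed (two-phase distributions invalidate single-phase estimators).
The detector requires two histogram peaks separated by a valley below 60% of
the smaller peak.

Density extrema (TMD = maximum, TminD = minimum) come from local quadratic
fits around discrete extrema of `rho(T)`; edge extrema are flagged
unbounded.  The liquid–gas spinodal is the temperature where `rho` collapses
below a gas threshold on heating; the liquid–liquid spinodal can be
assembled as the envelope of converging isochores.  Extrema loci of the
response functions are classified strong/weak within each scan family: a
peak is weak when shorter than (tallest peak)/3.

**Correlation length.**  The bonding indices determine every fluctuation in
this model, so `G(r)` is built from per-molecule functionals of them.  Two
kernels are provided: the default *overlap* kernel (the q-vector of
arm-value fractions; its connected correlation is the order-parameter-like
channel and grows on cooling toward the bond-ordering transition) and the
*coop* kernel (fraction of agreeing index pairs within a molecule; an
energy-like channel that is much shorter-ranged — near zero beyond one
lattice unit at all state points probed).  `xi` comes from weighted least
squares in log space, either pure exponential or Ornstein–Zernike
(`G ~ exp(-r/xi)/r^{d-2+eta}`); bins indistinguishable from zero (below two
standard errors) are dropped, because fitting log-noise fabricates lengths
of order the bin spacing.  Fits are marked unreliable when `xi` exceeds the
window (ordered phase).

**Thermodynamic identities.**  On any smooth `V(T, P)`,
`(dK_T/dT)_P = -(dalpha_P/dP)_T` identically; the implementation verifies
its own finite-difference routes to ~1e-13 relative (Richardson-extrapolated
stencils).  `alpha_P` vanishes on detected density extrema by construction
of the extremum.  On a toy surface with a turning TMD line the
`(dK_T/dT)_P = 0` locus crosses the TMD exactly at the turning point
(`dT/dP = 0`), and the `(dC_P/dP)_T = 0` locus (`V_TT = 0`) meets the
density-extrema branch where that branch has `dP/dT = 0` — the two crossing
geometries the response-function loci must satisfy.

## Histogram reweighting

Runs contribute 2D histograms `h_i(u, rho)` on shared edges (default
200 x 200 over the pooled range padded 5%; the fixtures use 100–400 bins).
The combined density-of-states estimate and the run constants `C_i` are
iterated from `C_i = 0` entirely in log space (log-sum-exp; the literal
fixed-point equations overflow at large `N`) until the maximum change drops
below 1e-3 (configurable), gauge-fixed to `C_0 = 0`.  Reweighting to
`(T', P')` weights the estimate by `exp(-beta'(E + P' V))`; a Kish effective
sample size far below the pool triggers a warning (there is no sharp
"close enough" criterion).  `G(P)` along isotherms is the log of the
reweighted partition-function estimate, shifted to zero at the lowest
pressure; `dG/dP` equals the reweighted `<V>` (verified internally).
`Q_N(M)` is the projection of the joint density onto `M = rho* + s u*`,
binned at the projected input resolution with edges anchored so input values
sit at bin centres (no half-bin smearing).

## Mixed-field finite-size scaling

`Q_N(M)` is rescaled to zero mean and unit variance (`M_c` = mean,
`B` = 1/std).  The apparent critical point is located in two stages, as the
method prescribes: first minimise the asymmetry
`integral |Q(x) - Q(-x)|/2` over `(T, P, s)` (Nelder–Mead with a scaled
initial simplex, optional box bounds), then evaluate the distance to the
universal references.  Position uncertainties come from refitting with a
jittered simplex.  The universal `P_d(x)` tables ship with the package and
are regenerated by `scripts/make_reference_tables.py`: Wolff simulation of
the standard Ising model at `beta_c = ln(1+sqrt 2)/2` (2D, 48^2) and
`beta_c = 0.22165455` (3D, 12^3), 2e5 clusters, magnetization symmetrized
and rescaled to unit variance.  On moderate lattices these approximate the
fixed-point distributions well enough for shape comparison (the 2D table is
sharply double-peaked near `|x| = 1.1`, the 3D one much flatter between
peaks), though not at the precision of dedicated large-scale studies.

Diagnostics: `U_M = 1 - <M^4>/(3 <M^2>^2)` with non-centred moments (2/3 for
any point mass, below 2/3 for two-phase distributions of a density-like
order parameter); `D_KL` in nats over bin masses with the reference floored
at 1e-12; the peak-contrast deviation `W_d = |Delta(P_N) - Delta(P_d)| /
Delta(P_d)` with `Delta = max(P) - P(0)` (the relative normalisation makes
`W` dimensionless and comparable across `d`); and the interface cost
`Delta G/(k_B T_c) = ln(Q_max/Q_min)` with `Q_max` the mean of the two peak
heights and `Q_min` the interior minimum.  Finite-size fits: `T_c(N)`,
`P_c(N)` linear in `L^{-(theta+1)/nu} = N^{-3/2}` (2D Ising `theta = 2`,
`nu = 1`); `B(N) ~ N^{beta/(d nu)}` (= `N^{1/16}` in 2D); `Delta G(N)` by a
continuous two-slope log-log fit whose breakpoint estimates the 2D–3D
crossover size (the expected slopes are `2/3` with an effective 3D
`L = N^{1/3}` and `1/2` with the lattice `L = N^{1/2}`; both conventions are
reported through the two slopes).

## Synthetic data

The analysis layers are validated without long simulations:

* **Exact enumeration** of the 2x2 lattice (q = 2 or 3): the sigma sum uses
  a density-of-states contraction over per-molecule states, the continuous
  `V0` a trapezoid grid.  A second, independent brute-force implementation
  (plain loop over all 2^16 states through the public energy functions)
  agrees to ~1e-12 relative.  I.i.d. samples from the enumerated
  distribution feed estimator tests with zero autocorrelation.
* **Synthetic series** (Gaussian, double-Gaussian, Ising-like, drifted,
  constant) with prescribed moments.
* **Synthetic critical families**: at `(T_c, P_c)` the order parameter
  `M = rho + s u` follows the tabulated 2D Ising distribution; the energy
  density is correlated with `M` and carries a skewed residual, so
  projecting along a wrong `s` gives a visibly asymmetric distribution
  (with a symmetric residual `s` would be unidentifiable from symmetry
  alone).  Runs at nearby `(T_i, P_i)` are exact NPT importance resamplings
  of the critical pool, making the family self-consistent with WHAM.
  Recovery of `(s, T_c)` within 3-sigma intervals succeeds in >= 18/20
  replicates.

What the generators do **not** emulate: critical slowing down, finite-size
corrections beyond leading order, and the correlated sampling noise of real
trajectories; passing these tests validates the estimators and fits, not the
model's own critical behaviour, which is probed separately at scaled-down
sizes.

## Scaled-down study sizes and desk-scale caveats

The validation campaigns run minutes on one CPU: 2x2 lattices for exact
comparisons, 16x16 for fluctuation–dissipation, 32x32 with five isobars
(`P = 0.2 .. 0.6`, 21 temperatures each, 400 samples per point) for the
qualitative phase diagram.  At these sizes the model shows the full anomaly
phenomenology — a TMD on every isobar (`T ~ 0.6-0.7`), a liquid–gas
spinodal far above it, a strong low-`T` compressibility maximum and a weaker
high-`T` structure on the liquid branch — with these caveats:

* The **occupancy flag is global** (homogeneous cells), so the
  hydrogen-bond onset near the end of the liquid branch is a collective,
  first-order-like step rather than a smooth crossover.  `K_T` grows
  monotonically into the branch end, exactly as it grows into a spinodal;
  that growth is therefore excluded from the weak-maxima comparison, which
  uses interior peaks of the liquid branch only.
* Crossing the occupancy step in a single volume move costs the full bond
  energy `J N_HB` (the indices are frozen during the move), a rare event
  whose rate vanishes exponentially with `N`.  Spinodal heating scans
  therefore run at 16x16, where the escape is observable.
* The **correlation length stays of order one lattice unit** except near the
  bond-ordering transition (`T ~ 0.06-0.08`): with a global volume the
  liquid–liquid transition has an infinite-range (mean-field) component and
  short sigma correlations.  The xi-maximum locus tracks the ordering line;
  the strong `K_T` maxima (half-filling of the edge matches) sit at the same
  temperatures near the critical pressure but measurably above it at the
  lowest pressure studied.  Coincidence of the two loci is therefore
  asserted at locus level (mean deviation below 3 joint position errors,
  no isobar beyond 5), with peak positions and their uncertainties from
  local quadratic refinement under parametric bootstrap.
* Absolute critical parameters (`T_c`, `P_c`, `rho_c`) at production sizes
  are outside the desk-scale surface; the package verifies the machinery
  (symmetrisation, universality comparison, finite-size fits) on synthetic
  and scaled-down data.

## Numerical choices

* Hard-core violations raise a dedicated exception; the pair-energy hard
  core is an infinity sentinel used only as a rejection signal.
* WHAM, reweighting and projections conserve probability mass to 1e-12;
  all reweighted observables are invariant under a common shift of the
  `C_i` (gauge freedom).
* Numeric derivatives use centred differences with Richardson extrapolation
  where the grid allows; loci are refined by local quadratic fits, never
  global splines.
* Degenerate inputs (zero-variance distributions, single-bin histograms,
  ordered-phase correlation data) return flagged results or raise, rather
  than propagating NaNs silently.
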