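# Methods

`smolsim` simulates individual point molecules diffusing in continuous 1-, 2-
or 3-dimensional space over fixed time steps dt, interacting with
infinitely-thin panel-based surfaces and reacting with zeroth-, first- and
second-order kinetics.  The governing idealization is Smoluchowski dynamics:
ideal Brownian motion plus reaction upon encounter at a critical pair
separation.  All discrete-time parameters (binding radii, per-step
probabilities, sticking probabilities) are calibrated so the simulated
dynamics converge to that idealization as dt shrinks; at finite dt the
dynamics are approximate in ways quantified below.

Units are conventions, not enforced: lengths in um, times in s, diffusion
coefficients in um^2/s, adsorption/permeability coefficients in um/s,
second-order rate constants in um^3/s (1 M^-1 s^-1 = 1e15 / N_A um^3/s,
N_A = 6.02214076e23; the conversion happens when a config uses
`reaction_molar`).

## The time step

Within one step the substeps run in a fixed order:

1. diffusion of every molecule (solution, surface-bound, drift, anisotropy),
2. surface/boundary interaction for every segment crossing,
3. desorption and surface-state conversion of bound molecules,
4. zeroth-order reactions,
5. first-order reactions,
6. bimolecular and conformational-spread reactions,
7. spatial-partition reassignment,
8. scheduled commands that fall due.

Only the category order is physically motivated; the fine ordering (e.g.
surface interactions before first-order reactions) is a convention of this
package, held stable because results at finite dt depend on it.  A molecule
takes part in at most one reaction or adsorption event per step (`used`
flag); products created during a step are likewise inert until the next
step.  This single-event rule is one of the finite-dt approximations: rate
errors it introduces scale with (events per molecule per step), which is why
dt should be chosen well below reaction and transport timescales.

## Diffusion

Solution molecules receive independent Gaussian increments per axis with
standard deviation sqrt(2 D dt), plus an optional deterministic drift
offset v dt; anisotropic diffusers draw from a multivariate normal with
covariance 2 T dt via the eigendecomposition of the tensor T (valid for
semi-definite tensors, so one- or two-axis motion is expressible).
Surface-bound molecules take the same full-dimensional Gaussian step and
are re-deposited onto their panel by closest-point projection.  On planar
panels this is exact (orthogonal projections of Gaussians are Gaussian); on
curved panels it requires the curvature radius to be much larger than the
rms step, which the test suite checks on a sphere with R/s = 220.  A bound
molecule whose projection leaves its finite panel is clamped; if it is
clamped to a panel edge the package moves it to the nearest point among all
panels of the same surface, which is this package's convention for
traversing panel junctions.

## Surfaces and boundaries

Crossing detection runs on the straight segment from the pre-diffusion to
the post-diffusion position: the earliest crossing among all panels *and the
system boundary walls* is processed first, and the residual displacement is
recursed on (up to 50 events per molecule per step, after which the
molecule is clamped at the last hit, offset by tolerance toward its incoming
side).  Treating the boundary walls as competing crossing events inside the
same resolver matters: folding boundaries after panel processing would let a
segment exit through a side wall and bypass a panel's finite extent.
Tangent grazes (discriminant at machine scale) count as no-hit; they are
measure-zero and processing them would risk double-counting.

Per (species, side) a surface prescribes reflect / transmit / absorb /
adsorb / jump / port; undeclared pairs reflect.  `port` absorbs into a
per-surface tally (this package has no external consumer to hand molecules
to).  Jump panels teleport the hit point by the translation between the
panel reference points and continue the residual displacement -- sufficient
for the toroidal-boundary and hole constructions jump surfaces exist for;
rotational jump pairs are not supported.

### Adsorption and permeation

The per-collision sticking probability realizing an adsorption coefficient
kappa (Robin boundary flux kappa * c_surface) is

    P = kappa * sqrt(pi dt / D)                (reduced kappa' small)

with kappa' = kappa sqrt(dt / 2D).  Beyond the baseline regime (P > 0.01)
the mapping is calibrated once per process: for each P on a fixed grid the
1-D discrete-time integral equation for the concentration profile beside a
sticking plane is propagated (reflected-image kernel, deterministic), the
cumulative adsorption record is fitted against the Robin closed form

    Gamma(t) = (c0 D / kappa) [e^(h^2 D t) erfc(h sqrt(D t)) - 1
               + 2 h sqrt(D t / pi)],   h = kappa / D,

and the resulting monotone (kappa', P) table is interpolated linearly.
When even P = 1 cannot realize the requested flux the package warns and
clamps.  Permeability uses the same mapping per side (each side transmits
independently against its own collision flux), giving net flux
kappa_perm * (c1 - c2).  The validation keeps kappa' below ~0.1 where this
per-side symmetry is accurate.  Note the contract is the *boundary
condition*: in a two-chamber relaxation the observable rate includes a real
diffusion resistance 2 l / 3 D in series with the membrane, which is
physics, not error.

### Desorption placement

A molecule desorbing at rate k_d leaves with probability 1 - exp(-k_d dt)
per step (competing with state conversions through the multi-channel
first-order formula).  Its placement offset along the local normal accounts
for the diffusion between the (uniformly distributed) desorption instant and
the step's end.  The package samples the defining micro-process directly
with 100 substeps rather than closed-form densities: for irreversible
desorption the walk reflects off the surface (the Gaussian-plus-error-
function family); for reversible desorption a walk that touches the surface
would re-adsorb, so the placement law is the walk conditioned on staying
positive (the error-function family), sampled by rejection.  Every
desorbing molecule is placed -- within-step recapture bookkeeping belongs
to the adsorption algorithm of subsequent steps.  The 100-substep
discretization is the definitional resolution; tests compare it against
independent oracle implementations (exact folded-Gaussian mixture;
path-positivity by cumulative sums) at Kolmogorov-Smirnov distance < 0.01.

### Unbounded-emitter boundaries

To emulate an infinite medium, an absorbing bounding surface with declared
point emitters (positions r_i, strengths q_i) absorbs partially: on each
panel the free-space superposition c(r) = sum q_i / (4 pi D |r - r_i|) and
its normal flux density are evaluated at the panel centroid, the matched
Robin coefficient kappa_p = D (grad c . n) / c is rescaled so total
kappa-weighted flux balances total emission, and kappa_p is converted to an
absorption probability through the adsorption mapping.  The centroid
evaluation makes this approximate; the documented contract (checked on an
80-triangle sphere with a central source) is interior concentration within
10% of the free-space field over r in [0.2 R, 0.8 R], and the measured
profile is within ~3%.

## Reactions

*Zeroth order*: a Poisson(k V dt) count of products appears uniformly in the
volume (rejection-sampled inside a compartment, whose volume is estimated
once by 40,000-point Monte Carlo).

*First order*: with total rate k_tot over all channels of one reactant
signature, a molecule reacts with probability 1 - exp(-k_tot dt) and the
channel is drawn proportionally to its rate.

*Second order*: a pair reacts when it ends a step within the binding radius
sigma_b.  The map from sigma_b to the macroscopic steady-state rate is
computed in reduced units (lengths in units of the rms per-axis relative
step s = sqrt(2 (D_A + D_B) dt)) by finding the steady state of the
alternating absorb/propagate operation on the radial pair density.  Because
that operation is linear, the steady state is solved directly: interior
node densities satisfy (I - A) c = B t(a) where the far field is pinned to
the harmonic form 1 - a/r (invariant under the diffusion kernel) and the
scalar a = flux / 2 pi closes the system -- one dense solve per radius, no
iteration, stable from the well-mixed limit k -> (4/3) pi sigma_b^3 / dt
through the Smoluchowski limit k -> 4 pi D sigma_b.  The radial grid is
cell-centered with a cell edge aligned exactly at sigma_b (otherwise the
absorbed-mass quadrature mis-weights the cutoff cell), fine spacing
min(sigma_b, s)/30 near the absorber, geometric coarsening capped at 0.12 s
outward to sigma_b + 14 s, and automatic refinement until the flux moves
less than 1e-4 relatively.  `binding_radius_from_rate` inverts the map by
Brent's method between the two analytic limits, which bracket the root.
1-D and 2-D use the same machinery with the matching radial propagator and
a clamped far field (no true steady rate exists there; supported but less
validated -- the quantitative anchor is 3-D).

Candidate pairs come from a KD-tree range query (minimum image on periodic
axes via a per-axis boxsize), which is exactly equivalent to an all-pairs
search; pairs are processed nearest-first and each molecule reacts at most
once.  A uniform box grid indexes molecules with half-open cells whose edge
is at least the largest binding radius (construction fails otherwise) and
at least 1/20 of the box per axis.

*Product placement*: products appear at the reaction point -- for
bimolecular events the diffusion-weighted encounter point
r_C = (D_B r_A + D_A r_B) / (D_A + D_B), this package's convention for the
encounter location of unequal diffusers.  Dissociation products that can
re-react are separated by the unbinding radius sigma_u along a uniform
random direction; since a pair released at sigma_u is ever recaptured with
probability sigma_b / sigma_u (3-D first passage), the default
sigma_u = sigma_b / p_gem with p_gem = 0.2 caps geminate recombination at
20%.  That residual recombination biases reversible equilibria by roughly
p_gem; users needing tighter equilibrium fidelity should set a smaller
`pgemmax` (the test suite uses 0.05 for its 3% equilibrium check).
Excluded-volume "bounce" reactions place the products on the line that
connected the reactants at separation 1.01 sigma_b (default factor).
Conformational spread converts reactant A at a first-order rate whenever a
B lies within the interaction distance r_c, positions untouched; pairs are
non-exclusive (an A with m in-range partners gets m independent chances per
step), a documented convention.

Reaction orders above two are rejected at parse time (decompose into
bimolecular steps); a fixed-reaction-probability variant with enlarged
binding radii is deliberately not implemented.

## Statistical validation

Trajectory points from a single run are time-correlated, so Pearson
chi-squared on raw trajectories has no exact null distribution.  The test
suite therefore tests *conditionally independent* quantities wherever
possible: decay increments are exactly binomial given the current count;
bimolecular and enzymatic turnover over short windows is compared against
the mass-action expectation integrated from the *observed* state at the
window start with Poisson event-count variances; adsorbed counts at a
single time are exactly binomial because molecules are independent.
`chi2_report` implements the Pearson machinery with analytic variances and
standard low-expectation bin merging (threshold 5); its own calibration
(uniform p-values under the null, decisive rejection of a 20% rate error at
n = 1e4) is part of the suite.

Problem sizes used by the validation suite: the enzyme benchmark runs the
full 10,000 molecules for 10 s in 1 ms steps in a 100 um^3 box with
k_on = 0.01 um^3/s (6e6 M^-1 s^-1) and k_off = k_cat = 1/s -- rates chosen
once so roughly a third of substrate turns over in 10 s while ES stays
far from saturation; the leak-proof confinement check runs 1e4 molecules
for 1e4 steps (1e8 molecule-steps) in an 80-triangle sphere with rms step
0.05 R; free-diffusion slopes use 1e4 molecules per population for 100
steps; adsorption uses kappa in {1, 5, 20} um/s at D = 1 um^2/s and
dt = 2e-4 s, spanning the baseline and table-calibrated sticking regimes;
the pair-survival Monte Carlo uses 5e5 particles in a ball of radius 12 s.
Wall-time linearity in molecule count is asserted for an affine fit over
1e3..1e5 molecules: array-based stepping has a fixed per-step overhead, so
affine (not proportional-through-zero) is the meaningful statement of
linear scaling.

## What the generated fixtures do and do not show

The fixtures are idealized: uniform initial conditions, ideal Brownian
motion, dilute reactants, perfectly smooth panels.  Passing tests shows the
discrete-time algorithms converge to Smoluchowski dynamics with correctly
calibrated rates and boundary conditions.  They say nothing about
phenomena outside the model class: crowding-induced anomalous diffusion
(crowder fields are provided for such studies, but no claim is validated),
hydrodynamic interactions, moving or deforming membranes, inter-reactant
forces, or position-dependent diffusivity.  At finite dt the known biases
are: single-event-per-step saturation when event probabilities per step are
not small, transient (non-steady-state) inaccuracy of the adsorption
mapping at early times of order a few steps, geminate-recombination bias of
order p_gem in reversible equilibria, and curvature error of
surface-bound diffusion of order (s / R)^2.

## Numerical conventions

Box-grid cells are half-open [low, high); periodic wrap maps the high edge
to low.  A surface-bound molecule is considered on-panel within 1e-6 of the
system diagonal and is re-projected otherwise.  One RNG stream
(numpy PCG64) per simulation drives every stochastic draw in a fixed
substep order, so a (config, seed) pair reproduces output files
byte-for-byte.  Output tables print observables with 6 significant digits
and times with 12.  Degenerate inputs: zero-length segments never cross
panels; zero rates disable their channels; a bimolecular reaction between
two immobile species is a configuration error (no encounter process
exists), as is a binding radius exceeding the box size.
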