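# Methods

## Model and rate law

A model is an ordered list of species (id, compartment, reference
concentration `x0` in molar, `fixed` flag) and reactions (integer
reactant/product stoichiometries, forward rate constant `kf`,
equilibrium constant `Keq`, reversibility). Units are molar and hours
throughout; `kf` consequently carries `M^(1-order)/h` where *order* is
the sum of reactant coefficients, and the order is recoverable from the
stored stoichiometry. The default rate law is net mass action,

    v = kf (∏ x_s^a − Keq⁻¹ ∏ x_p^b),

which is zero exactly when the mass-action ratio Γ = ∏x_p^b / ∏x_s^a
equals Keq, and whose sign always matches the thermodynamic driving
force `ln Keq − ln Γ`. Irreversibility is encoded as `Keq = +inf`; the
reverse term is dropped symbolically and never evaluated, so no
overflow path exists. Species occurring on both sides of a reaction
are net-cancelled at construction so rate-law exponents are well
defined; non-integer stoichiometries are rejected. Custom symbolic
rate laws (sympy expressions over species symbols) may replace mass
action per reaction; they are validated for symbol closure at model
build and are excluded from Γ/PERC machinery, which is only meaningful
for the mass-action form.

Fixed (boundary) species keep their row in the stoichiometric matrix S
but contribute a zero ODE. Conserved pools are computed as the
rational left nullspace of S restricted to dynamic species (sympy exact
arithmetic, minimal integer scaling), so moiety totals like
ATP+ADP+AMP or free+bound enzyme are identified exactly rather than to
floating-point rank tolerance.

## PERC parameterization

Given a steady-state flux vector and concentration state, each
mass-action reaction's forward constant is back-calculated as
`kf = v_ss / D` with `D = ∏x_ss^a − Keq⁻¹∏x_ss^b`. `sign(D) ≠
sign(v_ss)` (flux against the driving force) and `D = 0` with nonzero
flux are hard errors naming the reaction; zero flux yields `kf = 0`
with a warning, a deliberate choice because samplers can emit exact
zeros and a dead reaction is more useful than an aborted workflow.
The flux state is checked for balance (`‖S·v_ss‖∞ ≤ 10⁻⁶·max|v|`,
configurable) before inversion. By construction the parameterized
model reproduces `v_ss` exactly at `x_ss`, which the tests verify to
`10⁻¹⁰·max|v|`.

Gibbs energies use `ΔG = R·T·ln(Γ/Keq)` with `R = 8.314×10⁻³`
kJ/(mol·K) and a default physiological temperature of 310.15 K;
irreversible reactions report `−inf` as the sentinel for an unbounded
forward driving force. Fluxes measured per dry weight convert to
volumetric units as `v_molar = v_gDW · density / 1000` with density in
gDW per litre of cell volume.

## Simulation and steady states

Integration uses LSODA (stiff-capable, adaptive) with the analytic
Jacobian `J = S·G`, `G[j,i] = ∂v_j/∂x_i`, assembled exactly from the
stoichiometric exponents; defaults `rtol = 10⁻⁹`, `atol = 10⁻¹⁵`
(absolute tolerance well below the ~10⁻⁶–10⁻³ M concentration range).
Negative excursions below `10·atol` are clipped to zero, and rate
evaluation clips negative inputs, preserving mass-action positivity
without perturbing the solution at tolerance scale. Trajectory fluxes
are recomputed from stored states rather than interpolated.

The steady-state criterion is `‖dx/dt‖∞ < max(atol_ss, rtol_ss·‖v‖∞)`
with defaults `10⁻⁹ / 10⁻⁶`. Three strategies: `integrate` simulates
over geometrically growing horizons (10 h × 10 per round, up to 10⁶ h);
`newton` runs a damped Newton iteration with Armijo backtracking on the
conserved-pool-reduced system (variables confined to the affine space
`x0 + null(L)` where L stacks the pool vectors, so pool totals are
preserved exactly and the reduced Jacobian is nonsingular at hyperbolic
steady states); `hybrid` (default) integrates toward the attractor and
polishes with Newton. Stability is decided either by the eigenvalues
of the pool-reduced Jacobian (`Re λ < 10⁻⁹`; reduction, not
thresholding, removes the structural zero modes) or by simulation: a 5%
multiplicative kick to all dynamic species followed by re-convergence
within a 10⁴ h horizon. Timescales are `−1/Re λ` over the strictly
stable spectrum, ascending. Interpolation onto new grids is monotone
cubic (PCHIP), with extrapolation rejected.

Perturbations are single-instant parameter changes (`kf`, `Keq`, or a
fixed species' boundary value), multiplicative or absolute. The
integrator splits the time span at the perturbation instant and carries
the state across continuously — only parameters jump. Dynamic species
cannot be targeted, which keeps trajectories continuous by
construction.

## State sampling

Concentration sampling works in log space `y = ln x` over dynamic
species; fixed species are folded into the constraint constants. Each
reaction with an imposed direction `s` contributes
`s·((b−a)ᵀy) ≤ s·ln Keq − ε_thermo` with margin `ε_thermo = 10⁻⁶`, so
every sampled state has strictly nonzero driving force and PERC
denominators cannot vanish. Box bounds come in two modes:
`deviation` (`(1−d)x_ref ≤ x ≤ (1+d)x_ref`, interpreting the deviation
fraction multiplicatively in linear space; `d = 0.8` by default) and
`magnitude` (`x_ref/10^d ≤ x ≤ x_ref·10^d`). The linear-space reading
of the deviation bound is a deliberate choice isolated behind
`bound_mode`, so the order-of-magnitude variant is a parameter change,
not a code change.

Sampling is a single hit-and-run core: from the Chebyshev center
(interior-point LP via HiGHS), draw isotropic Gaussian directions,
compute the feasible chord against all inequalities and box bounds, and
step uniformly along it. Chords shorter than 10⁻¹² trigger direction
resampling with bounded retries. Thinning defaults to 100 iterations
per emitted sample. Every emitted sample is asserted feasible (slack
≥ −10⁻⁹), and determinism is guaranteed by a single PCG64 generator
per call. One core with configurable thinning replaces the
low-memory/multiprocessing sampler pair sometimes seen elsewhere; the
algorithmic contract is identical.

Flux sampling restricts hit-and-run to nullspace coordinates of the
equality system (`S v = 0` over dynamic species, plus any pinned
coordinates with `lb = ub`), so every sample satisfies the balance to
10⁻⁹ by construction; box bounds on v become inequalities on the
nullspace coordinates, and numerically zero inequality rows (residue of
pinned coordinates) are dropped.

Minimal thermodynamic repair solves `argmin ‖y − ln x_init‖₂` subject
to the feasibility polytope (SLSQP with analytic gradient; feasible
inputs are returned unchanged, exactly). Flux fitting to measurements
solves `argmin Σ(v_j − measured_j)²` subject to `S v = 0` and bounds;
the unconstrained stationary point in nullspace coordinates is linear
least squares and is returned exactly when it respects the bounds,
otherwise SLSQP handles the active set. Futile-cycle inflation adds
`frac·|net|` to both legs of an opposing irreversible pair; because the
same increment is added to both, the net flux is preserved exactly,
including for rational inputs.

## Enzyme modules

Templates: 2- or 3-step uni-uni (E+S⇌ES(⇌EP)⇌E+P), ordered bi-bi, and
an MWC-style R/T template whose inactive branch is a dead end (the only
thermodynamic cycle constraint is then the Haldane relation on the
catalytic path). Because every elementary step converts exactly one
enzyme form into another with unit stoichiometry, the module's internal
steady state at fixed ligand concentrations is linear in the form
concentrations; it is solved directly with the conservation row
`Σ forms = e_total`, and the net flux is read off the
product-releasing steps. `e_total` defaults to 10⁻⁶ M when
unspecified and the default is flagged in the module's provenance.

Fitting optimizes log-transformed rate constants (positivity by
construction) with a trust-region least-squares method; all but one
path-step `Keq` are free, and the last is eliminated through the
Haldane product, so the constraint holds to machine precision rather
than to a penalty weight. Targets whose sign opposes the net driving
force at the fitting state are rejected before optimization. A few
randomized restarts guard against poor basins; achievable targets are
met to ~10⁻¹⁴ relative in practice. Optional Km/kcat residuals are
supported for the 2-step uni-uni template (`kcat = k₂`,
`Km = (k₋₁+k₂)/k₁`).

Merging replaces the host reaction with the module's steps and forms
(initialized at the fitted internal distribution), after checking that
the module's net flux matches the host reaction's flux at the reference
state to 10⁻⁶ relative; the enzyme conservation pool then appears in
the model's conserved pools, and removal restores the original
reaction.

## Ensemble workflow

Assembly takes the Cartesian product of flux and concentration sample
sets; each pair is checked for direction consistency and parameterized
by PERCs. Infeasible pairs are kept with status `infeasible` and a
diagnostic rather than dropped, so
`|stable| + |unstable| + |infeasible| = n_flux × n_conc` always holds.
The stability filter defaults to the simulation criterion — reach a
steady state, apply the perturbation, reach a steady state again — with
the eigenvalue test available as a fast pre-screen. Survivors are
integrated with the shared perturbation and interpolated onto a common
log-spaced grid whose endpoints equal the requested span. Aggregation
is per time point across candidates: mean, normal-theory 95% CI
(`mean ± 1.96·sd/√n`), median and IQR by linear-interpolation
percentiles. Per-time-point aggregation (rather than pooling time
courses) is a deliberate choice. The energy charge uses the standard
Atkinson definition `(ATP + ADP/2)/(ATP + ADP + AMP)`.

## Fixture generators

Both fixtures construct a balanced flux state first, draw positive
concentrations, then set each reversible `Keq` to the reference
mass-action ratio times `exp(margin)` with a positive random margin, so
the reference state is thermodynamically feasible by construction;
PERCs then make it an exact steady state. The linear chain is
src→X₁→…→Xₙ→sink with unit flux. The toy glycolysis network lumps
upper/lower glycolysis around G6P, FDP and pyruvate, carries an
irreversible PFK/FBPase futile pair (legs 1.1/0.1 around a net of 1.0,
i.e. each leg inflated by 10% of the net), an irreversible
ATP-utilization reaction, adenylate kinase, and a small adenylate
source/drain (0.05 M/h) so AK carries nonzero net flux at steady state.
Reference concentrations are physiological in scale (ATP 1.6 mM, ADP
0.4 mM, AMP 0.1 mM, hexose phosphates 0.2–0.5 mM) and jittered ±10% by
the seed.

What the fixtures do not emulate: measurement noise, missing data,
genome-scale network size, compartmentation, osmotic/charge balance,
and enzyme saturation in the host rate laws. Passing tests therefore
demonstrate correctness of the algorithms under clean, feasible inputs,
not robustness to the pathologies of real datasets.

## Problem sizes and numerical choices

The default test and acceptance runs use the desk-scale sizes the
package is designed around: 15 × 15 = 225 candidate ensembles on the
9-reaction toy glycolysis, 10⁴-sample chains with thinning 10 for
sampler-correctness statistics, and 10×10 concentration grids for the
enzyme-module equivalence check. Hit-and-run KS checks compare against
exact marginals (uniform on boxes, Beta(1, d) on simplices) and a
rejection-sampling oracle at α = 0.01; hit-and-run output is weakly
autocorrelated at thinning 10, so p-values are meaningful but
conservative interpretation is advised at much larger n.

Known limitations: no metabolic control analysis or parameter
sensitivities; no stochastic simulation; no event handling beyond
single-instant perturbations; SBML import is limited to documents this
package wrote; random-order enzyme mechanisms and genome-scale
performance tuning are out of scope.
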