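# Methods

This note documents the models, numerical procedures and design
choices behind `kinlearn`, in the order a user meets them.

## Model representation

A model is four registries — parameters, variables, derived quantities,
reactions — sharing one flat namespace, compiling to
dS/dt = N·v(t, S, k).  Rate laws and derived quantities are pure
positional functions whose dependencies are declared explicitly at
registration.  This makes the static/dynamic classification of derived
quantities a pure graph property: a derived quantity is *dynamic* iff
its transitive dependency closure contains simulation time, a variable,
or another dynamic derived quantity, and *static* otherwise.  Static
derived quantities may appear as stoichiometric coefficients; they are
resolved when the stoichiometric matrix is compiled, keeping N constant
as the model equation requires.  Dynamic stoichiometries are rejected
with an explicit error rather than silently reinterpreted — a
time-varying N has no well-defined meaning under this model class.

Stoichiometric coefficients are stored as exact rationals
(`fractions.Fraction`) so that downstream conservation analysis is not
subject to float drift.

Units are vectors of rational exponents over four base dimensions
(concentration, time, volume, mass).  Only multiplicative units exist;
affine units (°C) are out of scope because rate laws never need them.
Unit checking is opt-in per component: every (reaction, variable) pair
with both sides annotated is checked against
unit(v) = unit(S)/unit(time); a pair with a missing annotation yields
an "unchecked" note rather than a failure, so partially annotated
models remain usable.  The time scale (seconds vs minutes) is not
tracked numerically — checking is dimensional, not magnitude-aware.

Registered rate laws (mass action, Michaelis–Menten, constant,
first-order relaxation) carry a serialization identifier and a LaTeX
template, so models built from them round-trip bit-exactly through JSON
and render symbolically.  Arbitrary in-code rate functions are fully
supported for simulation but serialize structure-only and render as
opaque named terms.

## Simulation

The default integrator is LSODA (stiff-capable, adaptive) with
rtol = 1e-8, atol = 1e-10; an explicit RK45 variant is selectable.
Protocol-driven simulation applies a piecewise-constant parameter
schedule: the switch is instantaneous, the boundary time point belongs
to the later segment (its fluxes are computed with the later segment's
parameters), and the final state of each segment seeds the next, so
trajectories are continuous by construction.  Fluxes and dynamic
derived quantities in a returned time course are always recomputed from
the stored states, never interpolated.

Steady states use *integrate-then-refine*: integrate in geometrically
growing windows (×4) until ‖dS/dt‖∞ < 1e-6 or t_max = 1e5, then damped
Newton on N·v(S) = 0 with a central-difference Jacobian, declaring
convergence at ‖N·v‖ < 1e-10.  The Jacobian is classified before
convergence is declared: a singular or ill-conditioned Jacobian
(condition number > 1e12) is the signature of a conservation relation,
and the result is returned non-converged with the integrated fixed
point and a "possible conservation relation" diagnostic.  Oscillatory
or divergent systems return non-converged results rather than raising
or averaging.  The integrate-then-refine scheme is this package's
choice; nothing in the problem class forces it, but it is robust for
the dissipative networks the package targets.

## Metabolic control analysis

Elasticities use central differences on the rate laws with relative
step 1e-6·max(|Sᵢ|, 1e-8).  Control coefficients perturb a dedicated
multiplicative activity factor per reaction (reference value 1,
relative step 1e-4, central differences) and recompute the steady state
for each perturbation, warm-started from the reference state.
Perturbing an activity factor rather than a named kinetic constant
keeps the definition meaningful for arbitrary (including code-defined
and surrogate) rate laws.  Finite differences were chosen over implicit
differentiation deliberately: they work for any callable rate law and
are directly checkable against the summation theorems, which the test
suite enforces to 1e-3 on randomized mass-action pathways.  Normalized
quantities are undefined at zero flux or concentration; such entries
are explicit NaN-with-mask markers, never silently propagated.

## Uncertainty propagation

Priors are uniform, normal, lognormal or constant, optionally
truncated (truncation is implemented by restricting the inverse-CDF
input range, so stratified schemes stay stratified).  Sampling is
reproducible bit-for-bit from (specs, n, seed, scheme); schemes are
independent pseudo-random draws (default) and Latin hypercube.

Monte Carlo ensembles bind sample row i to ensemble member i
regardless of execution order, isolate member failures (logged, never
aborting the ensemble) and summarise over survivors only, reporting
attempted and successful counts.  The ensemble mean is the plain
arithmetic per-time average; quantiles interpolate linearly.

Sobol sensitivity uses the radial design (A, B, AB_i; n_base·(p+2)
model evaluations) with the Saltelli-2010 first-order estimator
S1ᵢ = mean(f_B·(f_{AB_i} − f_A))/V̂ and the Jansen total-order
estimator STᵢ = mean((f_A − f_{AB_i})²)/(2V̂), V̂ being the pooled
sample variance of (f_A, f_B).  Estimates are reported raw — small
negatives are estimation noise and clipping them would bias averages.
Zero-variance outputs (e.g. a conductance pinned at zero during a
dark-adaptation lead-in) carry explicit undefined markers.  Base
points come from seeded pseudo-random draws by default or a scrambled
Sobol low-discrepancy sequence (`scheme="sobol"`); the case-study
pipeline uses the low-discrepancy scheme, which at n_base = 128 gives
stable window-averaged orderings across seeds.  Optional bootstrap
half-widths quantify estimator noise.

## Surrogates and hybrid models

Surrogate families: least-squares polynomials of bounded total degree
(rank deficiency is reported with the degenerate feature names, via
pivoted QR), interpolating cubic splines (restricted to one input — 
multi-input splines are a different algorithm class and out of scope),
and a reference multi-layer perceptron.

The MLP is trained with Adam on mean-squared error, full-batch by
default or mini-batch, deterministic given its seed.  Inputs and
outputs are standardized by affine scalers fitted on the training data
and stored inside the surrogate, so a trained surrogate is a pure
function of its serialized state (JSON round-trips are bit-exact).
Non-finite losses abort training with the epoch named.  Predictions
outside the training input hull are allowed but flagged on the
surrogate, surfacing silent extrapolation.

Two embedding semantics, selected explicitly: *additive*
(dS/dt = N·v + coefficient-weighted surrogate outputs; the zero
surrogate is an exact identity) and *replacement* (named reactions are
removed once and the surrogate's identically named outputs enter
through the removed reactions' stoichiometric columns; an exact
surrogate of a rate law leaves the right-hand side invariant to
< 1e-8).  Hybrid models are ordinary models: simulation, ensembles,
MCA and fitting apply unchanged.

## Neural posterior estimation

The NPE workflow draws parameters from the prior, simulates each draw
into a feature vector (time courses at a grid, steady states, flux
control coefficients, or summary statistics), and trains the reference
MLP on (features → parameters).  Failed simulations are dropped with
their parameter rows (no imputation); more than 50% failures aborts
with a prior diagnostic, since that indicates the prior covers a
regime the model cannot simulate.  The default estimator is honestly a
point estimator: it amortizes the posterior mode/mean, and
"perturbation mode" reports the spread of estimates over
multiplicative-noise replicates of the observation as a crude
uncertainty surface — it is not a density.  Conditional-density
estimators can be plugged in through the same training-function
interface.  Predictions are clamped to the prior support and flagged
when clamping occurs.

## Multi-experiment fitting

The objective is weighted least squares; residuals are
weight·(observed − predicted) with the model evaluated exactly at the
observed times (no data interpolation) or at steady state.  A
shared-parameter map defines one global vector and per-experiment
bindings (plus fixed parameters); packing/unpacking is validated as a
bijection.  The default minimizer is SciPy's bounded trust-region
least squares; any minimizer honouring the contract
`(residual_fn, x0, bounds) → (optimum, trace, converged)` can be
injected, as can per-experiment residual methods and integrator
options.  Simulation failures during the search yield penalty
residuals (1e6 × weight) so local search can retreat; strict mode
raises instead.  A seeded multi-start helper covers mildly non-convex
problems; global optimization is out of scope.

## Database parametrization

Enzyme-kinetics entries are read from a documented JSON dialect
(`{"ec": ..., "entries": [{kind, value, unit, organism, substrate?,
comment?}]}`); real database exports are adapted to it via a
user-supplied adapter callable, keeping the table logic
schema-agnostic.  Values are normalized to canonical units (Km, Ki →
mM; kcat, specific activity → 1/s) with a fixed conversion table;
unknown units skip the row with a warning.  Distribution fitting:
lognormal via mean/sd of log values (sample sd, n−1 divisor), normal
analogously, uniform-range as [min, max]; single values degrade to
constant specs with a warning.  Aggregating across organisms versus
within one organism is a scientific choice the package does not make
for you: filter first, then fit.

## Packaged fixtures

**Stomatal conductance model** — three first-order relaxations in
series (time unit minutes): a biochemical signal tracks the normalized
light input L/500 with time constant τi while rising and τd while
falling; the guard-cell osmotic potential tracks the signal with τπ;
the leaf water potential tracks the osmotic potential with τw; the
conductance gs is proportional to the water potential.  Defaults
τi = 1, τd = 3, τπ = 2, τw = 4 minutes are round plausible values, and
the linear light→signal mapping is this package's documented choice —
the fixture reproduces the *structure* of the classic stomatal model
(three ODEs, asymmetric signal kinetics, delayed conductance), not any
published parameterization, so quantitative claims about it are claims
about the fixture only.  The default light protocol is a 15-minute
dark lead-in, then two 5-minute pulses at intensity 500 separated by
10-minute dark phases.  Gaussian priors on the four time constants use
σ = 0.2μ/3, i.e. 99.7% of draws within ±20% of the default.

**Toy photosynthesis pair** — an upstream light-driven pool P
(charging ∝ L·(1−P), relaxation k_t = 10) produces ATP-like and
NADPH-like carriers; a downstream carboxylation flux
Vc·(A/(A+Km))·(N/(N+Km)) consumes them 3:2, with small linear leaks
(0.1) making the steady state unique.  The upstream pool relaxes about
two orders of magnitude faster than the downstream module — the
physical premise under which replacing the upstream module by its
steady-state response (the surrogate) is valid.  The hybrid's
steady-state carboxylation flux matches the full model to well under
2% across the light grid; under dynamic light protocols the
quasi-steady-state approximation admits a transient mismatch at light
steps, bounded in practice by 10% of the peak flux.  The model is
deliberately tiny (3 state variables); it demonstrates the embedding
machinery, not photosynthesis.

## What the synthetic fixtures do and do not show

All tests run on synthetic models with known closed forms or
self-consistency properties.  Passing them demonstrates that the
numerics are correct (integration error tracks tolerances, estimators
converge to analytic variance decompositions, control coefficients
satisfy the summation theorems, parameter recovery works when the
problem is identifiable and the noise model is known).  It does not
demonstrate robustness to the pathologies of real experimental data —
model misspecification, correlated or heteroscedastic noise,
non-identifiability — which the fixtures deliberately exclude.

## Problem sizes

Default analysis sizes were chosen so every pipeline runs comfortably
on a single CPU: Monte Carlo ensembles of a few hundred members, Sobol
designs at n_base = 4096 for algebraic test functions and 128 for the
ODE-driven stomatal study, NPE training sets of 2048 simulations with
a (32, 32) network for 400 epochs, surrogate training on 25-point
grids for 5000 epochs.  All are plain function arguments; nothing in
the implementation assumes these values.

## Known limitations

No SBML import/export; no symbolic transformation or structural
identifiability analysis (rate-law expression trees for registered
laws are exported as a hook); no event detection, delay or stochastic
simulation; no MCMC, Morris or FAST sensitivity methods; no sequential
SBI or density-estimating posteriors; no profile-likelihood
uncertainty for fits; single-backend (NumPy) neural networks without
GPU support.
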