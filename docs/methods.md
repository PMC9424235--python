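# Methods

## Kinetic model

All three activation schemes are derived under the rapid-equilibrium
assumption: substrate and activator binding steps equilibrate fast
relative to turnover, so K_m, K_a and αK_a act as dissociation-style
constants and the catalytic step carries all the time dependence.  This
matches a system whose binding constants are reported as K_d-like
quantities and whose activation is dominated by the chemical step.  The
ternary complex turns over at β·k꜀ₐₜ; the substrate–activator coupling
coefficient α multiplies both cross-binding constants (binding of A to ES
with αK_a, of S to EA with αK_m), so α = 1 means independent sites.
α and β are dimensionless by definition; concentrations are carried in
molar and time in seconds throughout the library, with the CSV layer
converting from the bench conventions (substrate nM, activator μM,
rates nM/s).

Properties used as internal cross-checks: the random law reduces to
Michaelis–Menten at A = 0 and to βV·S/(αK_m + S) at saturating A; with
α = β = 1 it is exactly independent of A; at fixed αK_a = K′ it collapses
onto the substrate-first law as K_a → ∞ (the nesting used for the
F-test).  One subtlety worth stating because it is often mis-remembered:
in the substrate-first scheme β = 1 does *not* make the activator inert —
binding of A to ES still pulls the substrate-binding equilibrium and
raises the subsaturating rate; only the saturating-substrate rate is
unchanged.  In the random scheme neutrality requires α = β = 1.

The activator-first scheme exists to be rejected: it has no basal
activity, so any enzyme measurably active at A = 0 excludes it.  Its law
is fit with the lumped constants βV and αK_m (only those products are
identifiable), reported as V and K_m with α = β = 1.

## Beacon simulation

The molecular-beacon assay is modeled as substrate depletion
dP/dt = v(S₀ − P, A) with P(0) = 0, integrated with an adaptive solver
(LSODA, rtol 1e-8, absolute tolerance 1e-12·S₀) and sampled at the
requested times.  The observation model is F = F_b + m·φ·P plus additive
Gaussian read noise (a multiplicative option exists but is off by
default, since read noise dominates plate readers).  φ, the equilibrium
release fraction of the cleaved fluorophore arm, produces the
sub-stoichiometric plateau F_b + m·φ·S₀ seen with long-stemmed designs; a
two-state duplex helper φ = 1/(1 + exp(−n_bp·ΔG_bp/RT)) supplies a
physically motivated default (stabilizing ΔG_bp < 0 makes φ fall with
stem length, the rationale for trimming the stem from five to three base
pairs), but φ is always a direct design parameter, never fitted.  Enzyme
is not consumed and product inhibition is not modeled; curvature in the
progress curves comes only from substrate exhaustion and φ.
`simulate_progress(None, ...)` produces an enzyme-free control well,
since a zero maximal rate is outside the parameter space.

With the 8-bromoguanine preset at saturating activator, the simulated
curves exhaust 100 nM substrate within minutes; conditions for the
linear-phase demonstrations therefore use modest activator doses, where
turnover stays slow.  The preset k꜀ₐₜ and the bench observation of a
~40-minute linear phase at saturating activator cannot both hold in this
simple depletion model; the simulator takes the rate-law side, and tests
choose windows by turnover fraction rather than wall-clock minutes.

## Initial-rate extraction

Fluorescence slopes are converted to molar rates with an
ordinary-least-squares FAM standard curve (slope in fluorescence per
molar).  The linear phase is the longest window anchored at t = 0 whose
straight-line fit reaches r² ≥ 0.995 and whose quadratic term is
statistically insignificant (OLS t-test, p > 0.05; windows with
numerically perfect residuals pass by construction).  This reproduces
manual "linear portion" selection deterministically.  If no window
qualifies, the earliest five-point window is used and the measurement is
flagged rather than silently passed.  The windowed intercept absorbs the
background, so no blank subtraction is needed; negative slopes are
clipped to zero and flagged.  Replicate wells are extracted individually
and then averaged per condition, with the spread and well count reported.

## Mechanism fitting and selection

Fitting minimizes the unweighted sum of squared rate residuals
(proportional weighting is available).  Parameters are optimized on the
log scale, which enforces positivity without active bounds; residuals are
rescaled by the data's maximum so the optimizer's absolute tolerances are
meaningful for molar-scale rates (~1e-10 M/s).  Multi-start
initialization seeds V and K_m from an activator-free Michaelis–Menten
pre-fit, K_a from the half-effect of the rate-versus-A profile at the
highest substrate concentration, β from the maximal rate ratio and α = 1,
then jitters log-uniformly within a factor of three; starting stops once
the best SSE has been reproduced by a second start or the budget (16 by
default) is exhausted.  Standard errors are delta-method transforms of
the log-scale Jacobian covariance at the optimum, scaled by residual
variance, and are labeled asymptotic.  Designs with fewer than two
distinct substrate or activator concentrations, or a rank-deficient
Jacobian at the optimum, raise an identifiability error naming the
unresolvable parameters.

Model selection ranks candidates by AICc with the error variance counted
as a parameter; a best-to-runner-up gap below 2 units yields an explicit
"ambiguous" verdict instead of a forced winner, and the nested
substrate-first ⊂ random pair also gets an extra-sum-of-squares F-test.
A selection-consistency caveat: when the *simpler* nested model generates
the data, AICc still picks the larger model whenever the extra parameter
absorbs more than its ~2.3-unit penalty, which happens with probability
P(χ²₁ > 2.3) ≈ 0.13 regardless of sample size.  The simulation tests
assert selection rates consistent with that sampling distribution; for a
hard hypothesis test of the nested pair, use the reported F-test.

## Screening and dose-response

Plate aggregates are medians of the basal and positive-control wells
(robust to single-well failures); percent activation maps basal to 0 %
and the positive control to 100 %, and a plate whose positive-control
median does not exceed basal is rejected outright.  The hit threshold is
a strict "greater than 20 %"; exactly 20 % is not a hit.  The Hill model
is fit with E_max parameterized as B + span (span > 0 on the log scale)
so E_max > B holds by construction, EC₅₀ and n on the log scale, and the
Hill coefficient bounded to [0.3, 4]; fits whose EC₅₀ falls outside the
dosed range or whose n sits at a bound are flagged low-confidence.  The
midpoint identity ν(EC₅₀) = (E_max + B)/2 is exact in this
parameterization for any estimates.

## Synthetic data

Generators are pure functions of their arguments including the seed.
Rate-grid noise is proportional (5 % in the replicate studies) or
additive; duplicates are the default replicate structure.  Screening
plates place basal, positive-control (reference activator at 500 μM) and
compound wells (20 μM) at 100 nM substrate and 10 nM enzyme, with planted
actives drawn from a configurable parameter sampler (default: β
log-uniform 10–60, K_a log-uniform 1–30 μM, α = 1) and ground-truth
labels written to a separate sidecar table.  The 9-deazaguanine preset
takes α = 1, an assumption (its coupling coefficient was not separately
reported) that can be overridden.  The K_m presets assign the reported
12–15 nM range endpoints to the two activators (15 to 8-bromoguanine,
12 to 9-deazaguanine).

What the generators emulate is the statistical structure the analysis
assumes — exact rate laws plus uncorrelated Gaussian noise, exchangeable
wells, stable gain.  They do not emulate plate-position effects, drift,
photobleaching, compound fluorescence interference or pipetting error,
so passing tests demonstrate correctness of the estimators under the
stated model, not robustness to those real-world artifacts.

## Problem sizes and numerical choices

The simulation studies run at desk scale: 100 seeded replicates per
design for model discrimination, 42–112-point rate grids, 10⁴ replicate
draws for the noise-calibration check, and screening plates of a few
hundred to two thousand compounds.  Optimizer tolerances are 1e-15
(xtol/ftol/gtol) with a 5000-evaluation cap; the grid-search oracle for
the Hill fit uses a coarse-then-refined two-stage search.  AICc is
reported as −∞ when a model interpolates (SSE = 0) and +∞ when the
small-sample correction is undefined (n ≤ k + 2).

## Known limitations

Rates, not progress curves, are the fitting unit; no Bayesian
uncertainty; no plate-effect correction; the beacon model ignores
photophysics; asymptotic standard errors can understate uncertainty near
parameter bounds or with few dose levels.
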