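# Methods

This note records the models, statistical machinery, numerical choices and
known limitations behind `sloppykit`, in enough detail to reimplement it.

## Observation model and likelihood

Observations are independent Gaussians centred on the deterministic model
prediction.  Two error structures are supported, matching the two built-in
generators:

* **heteroscedastic**: SD proportional to the signal, `σ_k = ε · y_model,k(x, θ)`,
  with ε ∈ (0, 1).  The SD is evaluated at the *current* θ, not at the
  generating parameters, so the noise scale moves with the fit.  Synthetic
  draws are truncated below at zero by rejection (redraw); for ε ≤ 0.25 the
  truncation point lies ≥ 4 SDs below the mean, the acceptance rate is
  ≈ 1, and the mean of the truncated distribution exceeds `y_model` by a
  negligible amount (quantified in the generator tests rather than
  corrected).  A consequence of the `−Σ log σ_k` term worth knowing: on
  noiseless data the zero-residual point is *not* exactly the cost
  minimiser — predictions slightly below the data are preferred.  The exact
  zero-residual optimality statement holds for the homoscedastic case.
* **homoscedastic**: constant SD σ in output units.  The cardiac case study
  uses σ = 2 mV at 1 ms resolution (1 kHz), typical of a clean
  microelectrode recording.

The error magnitude (ε or σ) is itself inferable: if the parameter vector
carries a value under the error's name, the likelihood uses it.  For all
sensitivity analysis it is a *nuisance parameter*: rows and columns of every
sensitivity matrix for it are simply not computed, so the Michaelis–Menten
matrices are 3×3 and the Beeler–Reuter matrices 9×9.

## Priors

Components: uniform on a positive interval (in the natural scale),
log-normal, and multivariate log-normal blocks with full log-space
covariance.  Because all sampling and optimisation happen in log space, the
uniform density over log θ carries the exp Jacobian.  The prior log-space
covariance Ω — needed by the likelihood-informed subspace — is exact and
closed-form per component: `σ_log²` for log-normals, the declared covariance
for blocks, and for uniform(a, b)

    E[log U]   = (b log b − a log a)/(b − a) − 1
    Var[log U] = 1 − a b (log b − log a)² / (b − a)²

(Var[log U(1, e)] = 1 − e/(e−1)² ≈ 0.079326, cross-checked by Monte Carlo in
the tests).  Note Var[log U] → 1 as b/a → ∞: a natural-scale uniform can
never be more than one log-unit "wide" in this sense, because its mass
concentrates near the upper end on the log scale.

## Inference

**MLE.** Derivative-free Nelder–Mead simplex on log θ, with an optional
Powell polish; uniform prior components bound the search box, log-normal
components leave it unconstrained (maximum likelihood, not MAP).  The
returned cost never exceeds the start's.  In the full pipeline the start is
the posterior mean, which mirrors how the local matrices are meant to probe
the region the data actually support.  On ridge-shaped likelihoods the
simplex can lawfully wander far along the flat direction; the two-start
experiment in the tests shows the bare parameters disagreeing wildly while
the constrained combination `k_cat·E_T/K_M` agrees to < 1%.

**SMC.** Adaptive likelihood-annealing sequential Monte Carlo targeting
`π_t ∝ L^{γ_t} p`:

1. draw M particles from the prior (in log space);
2. choose the next inverse temperature by bisection so that the effective
   sample size of the incremental weights stays ≥ (1 − Δ)·M — the ESS may
   fall by at most the fraction Δ per step.  Δ ("ess_reduction") defaults
   to 0.001; the robustness check pairs a smaller population with a larger
   Δ.  The rule is exposed as configuration because several variants of
   "ESS reduction target" circulate; this one makes Δ directly the
   per-step information increment;
3. multinomial resampling back to equal weights at every step (the
   posterior-covariance estimator assumes equally weighted samples);
4. Gaussian random-walk Metropolis–Hastings diversification with proposal
   covariance `(2.38²/d) × ` the current population covariance.  After a
   pilot sweep with measured acceptance rate â, the number of sweeps is
   `ceil(log(1−C)/log(1−â))` (capped at 30) so each particle moves at least
   once with probability ≥ C = 0.95.

Models may expose a vectorised batch predictor; the Michaelis–Menten model
does, which keeps a 1000-particle run on a five-point dataset at ~1–2 s
despite ladders of a few hundred temperatures.

Defaults follow the study settings (M = 10 000, C = 0.95, Δ = 0.001); the
desk-scale analyses in the tests and the acceptance script use M = 1000,
which reproduces every qualitative result (and the stiffest eigenparameters
are verified identical between M = 2000/Δ = 0.001 and M = 1000/Δ = 0.005).

## Sensitivity matrices

All derivatives are taken with respect to log θ by central finite
differences with relative step δ ∈ [10⁻⁴, 10⁻²] (default 10⁻³).  The
log-space step is `h = log(1+δ)`, i.e. evaluation at `θ·e^{±h}`: this equals
the conventional `Δθ_i = δ·θ_i` to O(δ²) while keeping the stencil exactly
centred in log space, which makes every matrix exactly invariant to a change
of parameter units (checked in the tests) and keeps the FD Hessian
symmetric up to roundoff; it is then symmetrised as `(H+Hᵀ)/2` before any
eigenanalysis.  H may be indefinite away from a minimum; that is reported,
not hidden.  L is PSD by construction and equals H at a zero-residual
optimum (verified numerically at cosine ≥ 0.999).

`P = Σ̂⁻¹` uses the (M−1)-normalised log-sample covariance; if its condition
number exceeds 10¹², a diagonal jitter of `10⁻¹⁰·trace/N` is added with a
warning — near-flat directions make Σ̂ ill-conditioned *by design* in sloppy
problems.  `G` averages the prior-preconditioned Hessian `L_pᵀ H(θ_m) L_p`
over a seeded uniform subsample of the ensemble (default 500; the scenario
pipeline uses 200 of 1000) — doubling the subsample is the built-in
convergence diagnostic.  `K = L_pᵀ Σ̂⁻¹ L_p` is the likelihood-free stand-in
for G under a near-Gaussian posterior.

## Eigenparameters and diagnosis

Eigendecomposition uses the symmetric solver (`eigh`); eigenvalues are
sorted stiffest-first.  An eigenvector becomes an eigenparameter by (i)
dropping elements with |(v_n)_j| < 0.2 *before* rescaling, (ii) dividing
the survivors by the largest surviving magnitude (so the top exponent is
exactly ±1), and (iii) flipping the sign so the largest-magnitude exponent
is positive — an eigenparameter and its reciprocal are the same direction,
and a canonical orientation is needed for comparison.  Exponents are
displayed rounded to one decimal; full precision is kept internally.

The information-source diagnosis compares stiffest eigenparameters by the
absolute cosine of the full-length eigenvector directions, with ≥ 0.9
counting as "similar" (configurable): all similar → `data_dominated`; H/L ~
G but P different → `P_prior_influenced`; G different from H/L →
`prior_influences_fit`.

## Case-study conditions

**Michaelis–Menten** (k_cat = 100 min⁻¹, E_T = 5 µM, K_M = 146.7 µM;
ε = 0.25). Dataset A: S ∈ {2, 3, 4, 5, 6}·10⁴ µM, chosen so the *entire*
K_M prior support (≤ 10³ µM) satisfies K_M ≪ S — "saturating data" must
hold for every K_M the prior entertains, not just the true one, or the top
of the prior range genuinely informs K_M and contaminates the stiffest
eigenvector.  Dataset B: S ∈ {1, …, 5} µM ≪ K_M (first-order regime).
Scenario priors:

1. vague uniforms k_cat ~ U(1, 10⁴), E_T ~ U(0.01, 100), K_M ~ U(1, 10³),
   ε ~ U(0.01, 0.6);
2. independent log-normals with K_M *badly specified*: LN(log 10, 0.05) —
   informative, and centred 54 prior SDs away from the truth — against
   vague LN(log 100, 1) and LN(log 5, 1) for k_cat and E_T;
3. dataset B with k_cat ~ U(1, 10⁴), E_T badly specified LN(log 50, 0.15),
   K_M well specified LN(log 146.7, 0.04), ε ~ LN(log 0.25, 0.3).

The widths were set once from the qualitative description (which prior is
vague / well- / badly specified) so that "informative" priors genuinely
out-weigh a five-observation likelihood.  A caveat recorded here because it
is a property of the statistics, not of the implementation: on dataset B
the unconstrained MLE collapses to a small K̂_M for roughly 40% of noise
realisations (the noise's quadratic contrast mimics saturation curvature),
in which case the stiffest local eigenvector's K_M exponent flattens to
−0.6…−0.9 instead of −1.0.  The suite pins one realisation (seed 1) as
"the" dataset B.

**Beeler–Reuter.** The 1977 single-cell formulation: 8 ODE states (V_m,
[Ca]_i and six gates), four currents (I_Na, I_s, I_K1, I_x1).  The nine
fitted parameters are g_Na, g_NaC, E_Na, g_s, the amplitude scalers A_K1
and A_x1 on the two potassium currents, and three gate-kinetics rate
scalers (k_Na for m/h/j, k_x1 for x_1, k_si for d/f); reference values are
the published constants with all scalers at 1.  Stimulus: 30 µA/cm² for
2 ms at t = 10 ms, C_m = 1 µF/cm²; initial state = the quiescent
equilibrium, solved exactly by nested root finding (gates at α/(α+β),
calcium at its balance value, V at zero net current) so an unstimulated
simulation is stationary to solver tolerance.  Integration: LSODA with
rtol 10⁻⁶ and per-component atol (10⁻⁸, but 10⁻¹³ for [Ca]_i, which lives
at the 10⁻⁷ mol/l scale where a 10⁻⁸ floor would swamp the relative
tolerance), integrated piecewise across the stimulus discontinuities with
dense output sampled onto the 1 kHz grid.  Removable singularities in the
rate functions (α_m at V = −47 mV, the I_K1 term at V = −23 mV) are filled
with their analytic limits.  Priors: independent LN(log(reference), 0.2)
on the nine parameters, LN(log 2, 0.3) on σ.  The cardiac MLE uses a
600-evaluation simplex budget: the data come from the reference parameters,
so the optimum lies near the well-specified prior mean and a bounded local
refinement suffices; the fitted parameters land within ~10% of the
generating values and the convergence flag honestly reports the budget
termination.  In this parameterisation the stiffest eigenparameter carries,
besides the expected A_K1^{~0.9}·A_x1^{~0.4}/g_s balance, a k_si exponent
of ~0.6: the d/f gate speed trades off against the same plateau balance,
which a parameter set without kinetics scalers cannot express.

**Demo ecosystem.** A synthetic 4-species discrete-time consumer–resource
update (pasture, rabbits, native mammals, foxes; 12 rate parameters) with
an interior coexistence fixed point at (V, N, M, P) = (50, 12.2, 11.1, 4).
It is a fixture for exercising the machinery on a parameter-rich map and is
not calibrated to any real ecosystem.

## What the generators do and do not emulate

Synthetic data reproduce the error *structure* the likelihood assumes —
independent Gaussians of known form, the error magnitude correctly
specified up to inference.  Passing tests therefore demonstrate the
machinery (sampling, matrices, eigenanalysis, diagnosis) under a correctly
specified observation model; they do not probe model misspecification,
correlated noise, non-Gaussian errors, or real biological variability.

## Problem sizes

The default test run and the acceptance script use: five-point kinetic
datasets, 1000-particle SMC (2000 for the robustness pair), a 200-sample
Hessian subsample for G, one 500-ms action potential at 1 kHz, and a
600-evaluation cardiac simplex budget.  These sizes reproduce every
qualitative and quantitative claim above; the full-scale defaults
(M = 10 000, 500-sample subsample) remain the package defaults.

## Known limitations

* The heteroscedastic SD tied to the current θ makes the likelihood improper
  as predictions approach zero; generators and likelihood guard against
  non-positive predictions by raising rather than regularising.
* P assumes the posterior is adequately summarised by a log-space
  covariance; strongly curved (banana-shaped) posteriors will blur its
  eigenvectors.  G does not share this assumption but needs Hessians at
  posterior samples, which is the expensive path.
* MCMC, ABC, variational and Laplace posteriors are out of scope, as are
  active-subspace matrices and sparse inverse-covariance estimation.
* Uniform priors in the natural scale are at most one log-unit wide in the
  Var[log U] sense regardless of range (see above); for "many decades of
  ignorance" a log-normal with large σ_log is the honest vague prior.
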