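# sloppykit

Sloppiness analysis of deterministic models fitted to data: which
*combinations* of parameters does a model-data fit actually constrain, and
is each constrained combination informed by the data or merely by the prior?

Many mechanistic models in biology are **sloppy**: after a successful fit,
the eigenvalue spectrum of the fit's sensitivity to parameter changes spans
many orders of magnitude, so a handful of parameter combinations
("eigenparameters") are pinned down precisely while individual parameters
remain wildly uncertain.  `sloppykit` is for modellers — in biochemistry,
ecology, electrophysiology, or any field with positive-parameter
deterministic models and noisy observations — who want to find those
combinations and to know where the information behind them comes from.

## The method

Given a deterministic model `y_model = f(x, θ)` with strictly positive
parameters, a Gaussian observation model (heteroscedastic `σ_k = ε·y_model,k`
or homoscedastic `σ_k = σ`), and a prior `p(θ)`, the package builds four
square symmetric **sensitivity matrices over log-parameters** (the error
magnitude is treated as a nuisance parameter and excluded):

| matrix | definition | character |
|---|---|---|
| `H` | `H_ij = −∂² log L / ∂log θ_i ∂log θ_j` at the MLE (central finite differences) | local, likelihood only |
| `L` | `L_ij = Σ_k (∂r_k/∂log θ_i)(∂r_k/∂log θ_j)`, `r_k = (y_obs,k − y_model,k)/σ_k` | local Gauss–Newton; PSD; = H at zero residuals |
| `P` | `Σ̂⁻¹`, the inverse sample covariance of posterior log-parameter draws | global; data + prior |
| `G` | `mean_m  L_pᵀ H(θ_m) L_p` over posterior samples, `L_p L_pᵀ = Ω` (prior log-covariance) | global; data *beyond* the prior (likelihood-informed subspace) |

plus the likelihood-free approximation `K = L_pᵀ Σ̂⁻¹ L_p`, which shares
eigenvectors with `G` when the posterior is near-Gaussian in log space.
The posterior itself comes from an adaptive likelihood-annealing sequential
Monte Carlo sampler; the MLE from a simplex search in log space initialised
at the posterior mean.

Each eigenvector `v_n` (eigenvalues sorted stiffest-first) becomes an
eigenparameter `θ̂_n = Π_j θ_j^{(v_n)_j}`: elements with `|(v_n)_j| < 0.2`
are dropped, exponents are rescaled so the largest magnitude is exactly 1,
and the sign is canonicalised.  Comparing the stiffest eigenparameters
across matrix kinds yields a three-way diagnosis: `data_dominated` (all
agree), `P_prior_influenced` (only P disagrees: its stiff combination is
propped up by the prior), or `prior_influences_fit` (G disagrees with H/L:
the prior moves the plausible region itself).

Built-in case studies: the Michaelis–Menten rate law (`v = k_cat·E_T·S /
(K_M + S)`), the Beeler–Reuter (1977) ventricular action-potential model
(nine conductance/magnitude/kinetics parameters), and a synthetic
four-species consumer–resource demo ecosystem.  Seeded generators produce
the heteroscedastic truncated-normal and homoscedastic Gaussian synthetic
data the case studies use, so no external data are needed.

## Worked example

Saturating kinetic data only inform the maximum rate `v_max = k_cat·E_T`.
Five measurements at `S ≫ K_M` with 25% relative noise, vague uniform
priors, and the full pipeline:

```python
from sloppykit.scenarios import run_mm_scenario

res = run_mm_scenario(scenario=1, data_seed=1)   # ~2 s, M = 1000 particles
print(res.diagnosis)
for kind in ("H", "L", "P", "G"):
    print(kind, res.stiffest_string(kind))
```

prints

```
data_dominated
H k_cat^1.0·E_T^1.0
L k_cat^1.0·E_T^1.0
P k_cat^1.0·E_T^1.0
G k_cat^1.0·E_T^1.0
```

Every matrix finds the *product* `k_cat·E_T` as the stiffest
eigenparameter — the data constrain it ~16× more tightly (posterior SD of
its log) than either factor alone — while `K_M` is absent: these data say
nothing about it.  Because all four matrices agree, the diagnosis is
`data_dominated`: the priors are weakly informative.  Scenario 2 (a tight,
badly placed `K_M` prior) instead yields `P: K_M^1.0` with H/L/G unchanged
(`P_prior_influenced`), and scenario 3 (first-order-regime data with
informative priors) splits all three ways (`prior_influences_fit`); see
`examples/02_prior_vs_data_diagnosis.py`.

The cardiac example (`examples/03_cardiac_eigenparameter.py`) fits one
synthetic action potential (σ = 2 mV at 1 kHz) and finds the stiffest
eigenparameter of `L` to be the current balance
`A_K1^0.9 · A_x1^0.4 · k_si^0.6 / g_s` — the outward potassium amplitudes
against the slow inward conductance — whose eigenvalue exceeds the next by
two orders of magnitude.

A thin CLI wraps the same pipeline for shell use:

```bash
sloppykit analyze --config examples/configs/mm_scenario1.yaml
```

writes the dataset, posterior ensemble, matrices and a JSON report with the
eigenparameters and diagnosis into the configured output directory.

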