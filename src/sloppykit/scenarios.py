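"""Canonical study scenarios for the built-in case studies.

The Michaelis-Menten model is probed with two five-point datasets that each
see only one kinetic regime:

* dataset A - substrate concentrations far beyond saturation (S >> K_M),
  which inform only the maximum rate k_cat * E_T;
* dataset B - concentrations deep in the first-order regime (S << K_M),
  which inform only the ratio k_cat * E_T / K_M.

Both use heteroscedastic noise with relative error eps = 0.25.  Three prior
choices stress the prior-vs-data diagnosis:

1. vague uniform priors on everything (data dominate);
2. independent log-normals with the K_M prior badly specified - tightly
   centred at 10 uM while the true value is 146.7 uM (prior-data conflict
   invisible to the data, which carry no K_M information at saturation);
3. dataset B with a vague uniform k_cat, a badly specified E_T prior
   (centred at 50 uM, truth 5 uM) and a well-specified tight K_M prior.

The cardiac scenario fits the Beeler-Reuter model to a single synthetic
action potential sampled at 1 kHz with homoscedastic sigma = 2 mV, under
well-specified independent log-normal priors centred at the reference
values.

``run_mm_scenario`` executes the full pipeline (SMC -> posterior-mean-
initialised MLE -> H, L, P, G, K -> eigenparameters -> diagnosis) and is the
single entry point used by the command-line ``analyze`` and by the
acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .eigenanalysis import (
    Eigenparameter,
    diagnose_information_source,
    eigendecompose,
    to_eigenparameter,
)
from .inference import (
    MLEResult,
    PosteriorEnsemble,
    SMCSettings,
    fit_mle,
    posterior_log_moments,
    smc_sample,
)
from .models import BR_REFERENCE, MM_REFERENCE, BeelerReuterModel, MichaelisMentenModel
from .observation import Dataset, generate_heteroscedastic, generate_homoscedastic
from .parameters import ParameterSet
from .priors import LogNormalComponent, Prior, UniformComponent
from .sensitivity import FDConfig, SensitivityMatrix, hessian_H, levenberg_marquardt_L, lis_G, lis_K, pca_P

__all__ = [
    "DATASET_A_GRID",
    "DATASET_B_GRID",
    "MM_EPS",
    "mm_dataset",
    "mm_dataset_both_regimes",
    "mm_prior",
    "mm_theta_full",
    "br_dataset",
    "br_prior",
    "ScenarioResult",
    "run_mm_scenario",
]

#: Five substrate concentrations (uM) far beyond saturation (>99% of v_max
#: at the reference K_M, and >> the entire K_M prior support).
DATASET_A_GRID = np.array([20000.0, 30000.0, 40000.0, 50000.0, 60000.0])
#: Five concentrations (uM) deep in the first-order regime (S << K_M).
DATASET_B_GRID = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
#: Relative measurement error of the heteroscedastic generator.
MM_EPS = 0.25

_MM_NUISANCE = ("eps",)


def mm_theta_full(eps: float = MM_EPS) -> ParameterSet:
    """Reference MM parameters with the error magnitude appended."""
    d = MM_REFERENCE.as_dict()
    d["eps"] = eps
    return ParameterSet.from_dict(d)


def mm_dataset(which: str, seed: int) -> Dataset:
    """Synthetic dataset A (saturating) or B (first-order), eps = 0.25."""
    grid = {"A": DATASET_A_GRID, "B": DATASET_B_GRID}[which]
    return generate_heteroscedastic(
        MichaelisMentenModel(), grid[:, None], MM_REFERENCE, MM_EPS, seed
    )


def mm_dataset_both_regimes(seed: int, n: int = 10) -> Dataset:
    """A dataset whose S grid spans both kinetic regimes (identifiable)."""
    grid = np.geomspace(2.0, 6000.0, n)
    return generate_heteroscedastic(
        MichaelisMentenModel(), grid[:, None], MM_REFERENCE, MM_EPS, seed
    )


def mm_prior(scenario: int) -> Prior:
    """The three prior specifications for the MM scenarios."""
    if scenario == 1:
        return Prior(
            [
                UniformComponent("k_cat", 1.0, 1e4),
                UniformComponent("E_T", 0.01, 100.0),
                UniformComponent("K_M", 1.0, 1e3),
                UniformComponent("eps", 0.01, 0.6),
            ]
        )
    if scenario == 2:
        return Prior(
            [
                LogNormalComponent("k_cat", np.log(100.0), 1.0),
                LogNormalComponent("E_T", np.log(5.0), 1.0),
                # badly specified: tight, centred at 10 uM (truth 146.7 uM)
                LogNormalComponent("K_M", np.log(10.0), 0.05),
                LogNormalComponent("eps", np.log(0.25), 0.3),
            ]
        )
    if scenario == 3:
        return Prior(
            [
                UniformComponent("k_cat", 1.0, 1e4),
                # badly specified: tight, centred at 50 uM (truth 5 uM)
                LogNormalComponent("E_T", np.log(50.0), 0.15),
                # well specified: tight, centred at the true 146.7 uM
                LogNormalComponent("K_M", np.log(146.7), 0.04),
                LogNormalComponent("eps", np.log(0.25), 0.3),
            ]
        )
    raise ValueError(f"unknown scenario {scenario}; expected 1, 2 or 3")


def br_dataset(seed: int, t_end: float = 500.0, sigma: float = 2.0) -> tuple[BeelerReuterModel, Dataset]:
    """One synthetic action potential at 1 kHz with sigma = 2 mV noise."""
    model = BeelerReuterModel()
    t = np.arange(0.0, t_end, 1.0)
    data = generate_homoscedastic(model, t[:, None], BR_REFERENCE, sigma, seed)
    return model, data


def br_prior(sigma_log: float = 0.2) -> Prior:
    """Well-specified independent log-normals centred at the 1977 values."""
    comps = [
        LogNormalComponent(n, float(np.log(v)), sigma_log)
        for n, v in zip(BR_REFERENCE.names, BR_REFERENCE.values)
    ]
    comps.append(LogNormalComponent("sigma", np.log(2.0), 0.3))
    return Prior(comps)


@dataclass
class ScenarioResult:
    """Everything the full pipeline produces for one scenario."""

    scenario: int
    dataset: Dataset
    prior: Prior
    ensemble: PosteriorEnsemble
    mle: MLEResult
    matrices: dict[str, SensitivityMatrix]
    stiffest: dict[str, Eigenparameter]
    diagnosis: str
    similarities: dict[str, float] = field(default_factory=dict)

    def stiffest_string(self, kind: str) -> str:
        return str(self.stiffest[kind])


def _stiffest(matrix: SensitivityMatrix, threshold: float = 0.2) -> Eigenparameter:
    dec = eigendecompose(matrix)
    return to_eigenparameter(dec.vector(0), dec.names, threshold, dec.eigenvalues[0], 0)


def run_mm_scenario(
    scenario: int,
    data_seed: int,
    smc_settings: SMCSettings | None = None,
    fd: FDConfig = FDConfig(),
    subsample: int = 200,
) -> ScenarioResult:
    """Full sloppiness analysis of one Michaelis-Menten scenario.

    SMC posterior -> posterior-mean-initialised MLE -> H, L at the MLE,
    P and G from the ensemble -> stiffest eigenparameters -> diagnosis.
    """
    model = MichaelisMentenModel()
    which = "A" if scenario in (1, 2) else "B"
    data = mm_dataset(which, data_seed)
    prior = mm_prior(scenario)
    settings = smc_settings or SMCSettings(M=1000, seed=data_seed + 1)
    ensemble = smc_sample(model, data, prior, settings)

    post_mean_log, _ = posterior_log_moments(ensemble)
    theta_init = ParameterSet.from_log(prior.names, post_mean_log)
    mle = fit_mle(model, data, prior, theta_init)

    matrices = {
        "H": hessian_H(model, data, mle.theta, fd, _MM_NUISANCE),
        "L": levenberg_marquardt_L(model, data, mle.theta, fd, _MM_NUISANCE),
        "P": pca_P(ensemble, _MM_NUISANCE),
        "G": lis_G(ensemble, prior, model, data, fd, _MM_NUISANCE, subsample=subsample, seed=data_seed),
        "K": lis_K(ensemble, prior, nuisance=_MM_NUISANCE),
    }
    stiffest = {kind: _stiffest(m) for kind, m in matrices.items()}
    label, scores = diagnose_information_source({k: stiffest[k] for k in ("H", "L", "P", "G") if k in stiffest})
    return ScenarioResult(scenario, data, prior, ensemble, mle, matrices, stiffest, label, scores)
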