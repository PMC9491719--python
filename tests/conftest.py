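"""Shared fixtures: toy models with analytic likelihoods and the expensive
session-scoped pipeline runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from sloppykit import ParameterSet
from sloppykit.inference import fit_mle
from sloppykit.models.base import DeterministicModel
from sloppykit.scenarios import br_dataset, br_prior, run_mm_scenario
from sloppykit.sensitivity import levenberg_marquardt_L

SEED = 1  # suite-wide default seed for stochastic fixtures


class LogLinearModel(DeterministicModel):
    """y = A @ log(theta): linear in log-parameters, so the Gaussian
    log-likelihood is exactly quadratic and every curvature matrix has a
    closed form (J = -A for unit-sigma residuals)."""

    name = "log_linear"
    input_dim = 1  # the input condition is the row index of A

    def __init__(self, A: np.ndarray, names: tuple[str, ...]):
        self.A = np.asarray(A, dtype=float)
        self.names = names
        self.output_dim = 1

    def parameter_template(self) -> ParameterSet:
        return ParameterSet(self.names, np.ones(len(self.names)))

    def predict(self, X, theta):
        X = self._check_X(X)
        phi = np.array([np.log(self._value(theta, n)) for n in self.names])
        rows = X[:, 0].astype(int)
        return (self.A @ phi)[rows].reshape(-1, 1)

    def predict_batch(self, X, values, names):
        X = self._check_X(X)
        idx = [list(names).index(n) for n in self.names]
        phi = np.log(values[:, idx])  # (M, d)
        rows = X[:, 0].astype(int)
        return (phi @ self.A.T)[:, rows][:, :, None]


@pytest.fixture(scope="session")
def scenario_results():
    """Cache of full MM pipeline runs keyed by (scenario, data_seed)."""
    cache: dict[tuple[int, int], object] = {}

    def get(scenario: int, seed: int = SEED):
        key = (scenario, seed)
        if key not in cache:
            cache[key] = run_mm_scenario(scenario, data_seed=seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def br_mle_fit():
    """Beeler-Reuter fit to one noisy action potential + L at the MLE.

    The simplex is budgeted to 600 cost evaluations: the data are generated
    from the reference parameters, so the optimum is near the well-specified
    prior mean and a bounded local refinement suffices.
    """
    model, data = br_dataset(seed=SEED)
    prior = br_prior()
    init = ParameterSet.from_log(prior.names, prior.log_mean())
    mle = fit_mle(model, data, prior, init, maxfev=600)
    L = levenberg_marquardt_L(model, data, mle.theta, nuisance=("sigma",))
    return {"model": model, "data": data, "prior": prior, "mle": mle, "L": L}
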