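"""A small discrete-time consumer-resource demo ecosystem.

A synthetic four-species network used as a many-parameter test fixture:
pasture biomass V supports rabbits N and native mammals M, and foxes P prey
on both.  One time step (~a season) updates abundances with Lotka-Volterra
style gain/loss terms; abundances are clipped at zero, making the origin an
absorbing state.  This model is an in-package fixture for exercising the
sloppiness machinery on a system with more parameters than a handful of
noisy time series can constrain; it is not calibrated to any real ecosystem.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..parameters import ParameterSet
from .base import DeterministicModel

__all__ = ["demo_ecosystem_step", "DemoEcosystemModel", "ECO_REFERENCE"]

#: Reference parameter values for the synthetic demo ecosystem.
ECO_REFERENCE = ParameterSet.from_dict(
    {
        "r_V": 0.8,    # pasture intrinsic growth rate (1/step)
        "K_V": 100.0,  # pasture carrying capacity
        "c_N": 0.02,   # rabbit grazing rate on pasture
        "c_M": 0.014,  # mammal grazing rate on pasture
        "a_N": 0.5,    # rabbit conversion efficiency
        "a_M": 0.4,    # mammal conversion efficiency
        "d_N": 0.3,    # rabbit per-step mortality
        "d_M": 0.2,    # mammal per-step mortality
        "c_P": 0.05,   # fox predation rate on rabbits
        "e_P": 0.02,   # fox predation rate on mammals
        "a_P": 0.3,    # fox conversion efficiency
        "d_P": 0.25,   # fox per-step mortality
    }
)


def demo_ecosystem_step(state: np.ndarray, theta: ParameterSet | Mapping[str, float]) -> np.ndarray:
    """One deterministic time step; abundances stay >= 0 (clipped)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (4,):
        raise ValueError("state must be (V, N, M, P)")
    if np.any(state < 0):
        raise ValueError("abundances must be >= 0")
    p = theta.as_dict() if isinstance(theta, ParameterSet) else dict(theta)
    V, N, M, P = state
    V1 = V + p["r_V"] * V * (1.0 - V / p["K_V"]) - p["c_N"] * V * N - p["c_M"] * V * M
    N1 = N + p["a_N"] * p["c_N"] * V * N - p["d_N"] * N - p["c_P"] * N * P
    M1 = M + p["a_M"] * p["c_M"] * V * M - p["d_M"] * M - p["e_P"] * M * P
    P1 = P + p["a_P"] * (p["c_P"] * N + p["e_P"] * M) * P - p["d_P"] * P
    return np.clip(np.array([V1, N1, M1, P1]), 0.0, None)


class DemoEcosystemModel(DeterministicModel):
    """Forward model: input x = integer time step, outputs all 4 abundances."""

    name = "demo_ecosystem"
    input_dim = 1
    output_dim = 4

    #: Initial abundances (V, N, M, P) used for every trajectory.
    initial_state = np.array([60.0, 10.0, 8.0, 3.0])

    def parameter_template(self) -> ParameterSet:
        return ECO_REFERENCE

    def predict(self, X: np.ndarray, theta: ParameterSet | Mapping[str, float]) -> np.ndarray:
        X = self._check_X(X)
        steps = X[:, 0]
        if np.any(steps < 0) or np.any(steps != np.round(steps)):
            raise ValueError("input condition must be a non-negative integer time step")
        horizon = int(steps.max())
        traj = np.empty((horizon + 1, 4))
        traj[0] = self.initial_state
        s = self.initial_state
        for t in range(1, horizon + 1):
            s = demo_ecosystem_step(s, theta)
            traj[t] = s
        return traj[steps.astype(int)]
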