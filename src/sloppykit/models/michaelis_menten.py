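"""Michaelis-Menten enzyme kinetics.

The reaction rate of an enzyme-catalysed reaction as a function of substrate
concentration [S],

    v = k_cat [E_T] [S] / (K_M + [S]),

has two rate-limiting regimes: zero-order kinetics at high [S], where
v -> k_cat [E_T] and the data carry no information about K_M, and first-order
kinetics at low [S], where v ~ (k_cat [E_T] / K_M) [S] and only that single
coefficient is identifiable.  This makes the model a canonical example of
practical non-identifiability: individual parameters are poorly constrained
even when their product (or product/quotient) is pinned down precisely.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..parameters import ParameterSet
from .base import DeterministicModel

__all__ = ["michaelis_menten_rate", "MichaelisMentenModel", "MM_REFERENCE"]

#: Reference values: k_cat in 1/min, E_T and K_M in uM.
MM_REFERENCE = ParameterSet(("k_cat", "E_T", "K_M"), np.array([100.0, 5.0, 146.7]))


def michaelis_menten_rate(S, k_cat: float, E_T: float, K_M: float):
    """Reaction rate v = k_cat*E_T*S/(K_M + S) in uM/min.

    ``S`` may be a scalar or array of substrate concentrations (uM, >= 0);
    the kinetic parameters must be strictly positive.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration S must be >= 0")
    for label, val in (("k_cat", k_cat), ("E_T", E_T), ("K_M", K_M)):
        if not val > 0:
            raise ValueError(f"{label} must be > 0, got {val}")
    rate = k_cat * E_T * S / (K_M + S)
    return rate if rate.ndim else float(rate)


class MichaelisMentenModel(DeterministicModel):
    """Forward model: input condition x = [S] (uM), output v (uM/min)."""

    name = "michaelis_menten"
    input_dim = 1
    output_dim = 1

    def parameter_template(self) -> ParameterSet:
        return MM_REFERENCE

    def predict(self, X: np.ndarray, theta: ParameterSet | Mapping[str, float]) -> np.ndarray:
        X = self._check_X(X)
        v = michaelis_menten_rate(
            X[:, 0], self._value(theta, "k_cat"), self._value(theta, "E_T"), self._value(theta, "K_M")
        )
        return np.asarray(v).reshape(-1, 1)

    def predict_batch(self, X: np.ndarray, values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
        X = self._check_X(X)
        cols = {n: i for i, n in enumerate(names)}
        k_cat = values[:, cols["k_cat"]][:, None]
        E_T = values[:, cols["E_T"]][:, None]
        K_M = values[:, cols["K_M"]][:, None]
        S = X[:, 0][None, :]
        return (k_cat * E_T * S / (K_M + S))[:, :, None]
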