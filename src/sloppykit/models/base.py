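"""Deterministic model abstraction and the model registry.

A model maps (input conditions x, parameters theta) to output predictions
y_model = f(x, theta).  Inputs are passed as a matrix of condition rows so
that models whose evaluation is expensive (e.g. an ODE solve) can produce
all requested outputs in a single pass.  Models look parameters up by name,
so predictions are invariant to the ordering of a ParameterSet.
"""

from __future__ import annotations

import importlib
import importlib.util
import sys
from abc import ABC, abstractmethod
from typing import Callable, Mapping

import numpy as np

from ..parameters import ParameterSet

__all__ = ["DeterministicModel", "register_model", "get_model", "available_models"]


class DeterministicModel(ABC):
    """Base class for deterministic forward models.

    Subclasses define :attr:`name`, :attr:`input_dim`, :attr:`output_dim`,
    a :meth:`parameter_template` of reference values, and :meth:`predict`.
    Identical (x, theta) must always give identical output, and output must
    be finite for parameters within the prior support.
    """

    name: str = "model"
    input_dim: int = 1
    output_dim: int = 1

    @abstractmethod
    def parameter_template(self) -> ParameterSet:
        """Reference (true) parameter values used by data generators."""

    @abstractmethod
    def predict(self, X: np.ndarray, theta: ParameterSet | Mapping[str, float]) -> np.ndarray:
        """Predict outputs for each input-condition row.

        Parameters
        ----------
        X
            Array of shape (n, input_dim): one input condition per row.
        theta
            Parameter values, addressed by name.

        Returns
        -------
        Array of shape (n, output_dim).
        """

    # Optional fast path: subclasses may override to evaluate many
    # parameter vectors at once (used by the SMC sampler).
    def predict_batch(self, X: np.ndarray, values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
        """Predict for a batch of parameter vectors; shape (M, n, output_dim)."""
        out = np.empty((values.shape[0], X.shape[0], self.output_dim))
        for m in range(values.shape[0]):
            out[m] = self.predict(X, dict(zip(names, values[m])))
        return out

    @staticmethod
    def _value(theta: ParameterSet | Mapping[str, float], name: str) -> float:
        if isinstance(theta, ParameterSet):
            return theta[name]
        return float(theta[name])

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"{self.name}: expected {self.input_dim} input column(s), got {X.shape[1]}")
        return X


_REGISTRY: dict[str, Callable[[], DeterministicModel]] = {}


def register_model(factory: Callable[[], DeterministicModel], name: str | None = None) -> None:
    _REGISTRY[name or factory().name] = factory


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str, plugin_path: str | None = None) -> DeterministicModel:
    """Instantiate a registered model by name.

    ``plugin_path`` may point to a python file defining additional models;
    it is imported (registering anything it declares) before lookup.
    """
    if plugin_path is not None:
        spec = importlib.util.spec_from_file_location("sloppykit_user_models", plugin_path)
        if spec is None or spec.loader is None:
            raise ValueError(f"cannot import plugin path {plugin_path!r}")
        mod = importlib.util.module_from_spec(spec)
        sys.modules[spec.name] = mod
        spec.loader.exec_module(mod)
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {available_models()}") from None
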