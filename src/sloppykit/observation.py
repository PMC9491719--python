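"""Gaussian observation model: likelihood, cost, and synthetic-data generation.

Observations are modelled as independent Gaussians centred on the model
prediction.  Two error structures are supported:

* heteroscedastic - SD proportional to the prediction, sigma = eps * y_model,
  with synthetic draws truncated below at zero (observations are magnitudes);
* homoscedastic  - constant SD sigma in the output units.

The log-likelihood for a dataset is

    log L = sum_k [ -1/2 log(2 pi) - log sigma_k - 1/2 ((y_obs,k - y_k)/sigma_k)^2 ],

where, importantly, the heteroscedastic sigma_k = eps * y_model,k(x, theta)
is evaluated at the *current* parameters, so the noise scale moves with the
fit.  Minimising the cost C(theta) = -log L is equivalent to maximising the
likelihood; for homoscedastic errors it reduces to least squares.

The error magnitude (eps or sigma) is itself an inferable parameter: if the
parameter vector carries a value under the error's name, that value is used
in the likelihood.  It is a nuisance parameter for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .models.base import DeterministicModel
from .parameters import ParameterSet

__all__ = [
    "ErrorSpec",
    "Dataset",
    "log_likelihood",
    "log_likelihood_batch",
    "cost",
    "generate_heteroscedastic",
    "generate_homoscedastic",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class ErrorSpec:
    """Observation-error structure.

    Exactly one of ``eps`` (relative error, heteroscedastic) or ``sigma``
    (absolute SD, homoscedastic) is set, matching ``kind``.  ``param_name``
    is the name under which the error magnitude appears when it is inferred
    alongside the model parameters.
    """

    kind: str  # "heteroscedastic" | "homoscedastic"
    eps: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "heteroscedastic":
            if self.eps is None or self.sigma is not None:
                raise ValueError("heteroscedastic errors require eps and no sigma")
            if not 0.0 < self.eps < 1.0:
                raise ValueError(f"relative error eps must be in (0, 1), got {self.eps}")
        elif self.kind == "homoscedastic":
            if self.sigma is None or self.eps is not None:
                raise ValueError("homoscedastic errors require sigma and no eps")
            if not self.sigma > 0:
                raise ValueError(f"sigma must be > 0, got {self.sigma}")
        else:
            raise ValueError(f"unknown error kind {self.kind!r}")

    @property
    def param_name(self) -> str:
        return "eps" if self.kind == "heteroscedastic" else "sigma"

    @property
    def value(self) -> float:
        return float(self.eps if self.kind == "heteroscedastic" else self.sigma)  # type: ignore[arg-type]

    def with_value(self, value: float) -> "ErrorSpec":
        if self.kind == "heteroscedastic":
            return ErrorSpec("heteroscedastic", eps=value)
        return ErrorSpec("homoscedastic", sigma=value)


@dataclass(frozen=True)
class Dataset:
    """Paired input conditions and noisy observations.

    ``X`` has one row per observation (shape (N_obs, N_x)); ``output_index``
    selects which model output each row observes; ``y_obs`` holds the
    observed values.  ``provenance`` records the generator's reference
    parameters and seed for synthetic data.
    """

    X: np.ndarray
    output_index: np.ndarray
    y_obs: np.ndarray
    error: ErrorSpec
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        j = np.asarray(self.output_index, dtype=int)
        y = np.asarray(self.y_obs, dtype=float)
        if not (X.shape[0] == j.size == y.size):
            raise ValueError("X, output_index and y_obs must agree in length")
        if self.error.kind == "heteroscedastic" and np.any(y < 0):
            raise ValueError("heteroscedastic observations must be >= 0")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "output_index", j)
        object.__setattr__(self, "y_obs", y)

    @property
    def n_obs(self) -> int:
        return int(self.y_obs.size)


def _error_value(data: Dataset, theta: ParameterSet | Mapping[str, float]) -> float:
    """Error magnitude: from theta if inferred there, else the dataset's."""
    name = data.error.param_name
    if isinstance(theta, ParameterSet):
        return theta[name] if name in theta else data.error.value
    return float(theta.get(name, data.error.value))


def _sigmas(data: Dataset, y_model: np.ndarray, err_value: float) -> np.ndarray:
    if data.error.kind == "heteroscedastic":
        if np.any(y_model <= 0):
            raise ValueError(
                "heteroscedastic SD undefined: model prediction <= 0 at some observation"
            )
        return err_value * y_model
    return np.full(y_model.shape, err_value)


def _gauss_loglik(y_obs: np.ndarray, y_model: np.ndarray, sigmas: np.ndarray) -> float:
    r = (y_obs - y_model) / sigmas
    return float(np.sum(-0.5 * np.log(2.0 * np.pi) - np.log(sigmas) - 0.5 * r * r))


def log_likelihood(model: DeterministicModel, data: Dataset, theta: ParameterSet | Mapping[str, float]) -> float:
    """Gaussian log-likelihood of the dataset under ``theta``."""
    pred = model.predict(data.X, theta)
    y_model = pred[np.arange(data.n_obs), data.output_index]
    sig = _sigmas(data, y_model, _error_value(data, theta))
    return _gauss_loglik(data.y_obs, y_model, sig)


def log_likelihood_batch(
    model: DeterministicModel, data: Dataset, values: np.ndarray, names: tuple[str, ...]
) -> np.ndarray:
    """Log-likelihood for M parameter vectors at once (rows of ``values``).

    Uses the model's vectorised batch prediction when available; parameter
    vectors for which the likelihood is undefined (e.g. non-positive
    predictions under heteroscedastic errors) get -inf rather than raising.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    M = values.shape[0]
    rows = np.arange(data.n_obs)
    err_col = names.index(data.error.param_name) if data.error.param_name in names else None
    try:
        preds = model.predict_batch(data.X, values, names)  # (M, n, N_y)
    except Exception:
        preds = None
    out = np.full(M, -np.inf)
    if preds is not None:
        y_model = preds[:, rows, data.output_index]  # (M, n)
        err = values[:, err_col] if err_col is not None else np.full(M, data.error.value)
        if data.error.kind == "heteroscedastic":
            ok = np.all(y_model > 0, axis=1) & np.all(np.isfinite(y_model), axis=1)
            sig = np.where(y_model > 0, err[:, None] * y_model, 1.0)
        else:
            ok = np.all(np.isfinite(y_model), axis=1)
            sig = np.broadcast_to(err[:, None], y_model.shape)
        with np.errstate(over="ignore", invalid="ignore"):
            r = (data.y_obs[None, :] - y_model) / sig
            ll = np.sum(-0.5 * np.log(2.0 * np.pi) - np.log(sig) - 0.5 * r * r, axis=1)
        ll = np.where(np.isnan(ll), -np.inf, ll)
        out[ok] = ll[ok]
        return out
    for m in range(M):
        theta = dict(zip(names, values[m]))
        try:
            out[m] = log_likelihood(model, data, theta)
        except (ValueError, RuntimeError):
            out[m] = -np.inf
    return out


def cost(model: DeterministicModel, data: Dataset, theta: ParameterSet | Mapping[str, float]) -> float:
    """Cost function C(theta) = -log L; its minimiser is the MLE."""
    return -log_likelihood(model, data, theta)


# ---------------------------------------------------------------------------
# synthetic-data generators
# ---------------------------------------------------------------------------

def _predict_clean(model: DeterministicModel, X: np.ndarray, theta_R: ParameterSet) -> np.ndarray:
    pred = model.predict(np.atleast_2d(np.asarray(X, dtype=float)), theta_R)
    return pred  # (n, N_y)


def generate_heteroscedastic(
    model: DeterministicModel,
    X: np.ndarray,
    theta_R: ParameterSet,
    eps: float,
    seed: int,
    output_index: np.ndarray | None = None,
) -> Dataset:
    """Draw observations ~ Normal(y_model, eps*y_model) truncated below at 0.

    Truncation is by rejection (redraw), so for eps << 1 the acceptance rate
    is essentially 1 and the sample mean sits only marginally above y_model.
    """
    error = ErrorSpec("heteroscedastic", eps=eps)
    rng = np.random.default_rng(seed)
    clean = _predict_clean(model, X, theta_R)
    n = clean.shape[0]
    if output_index is None:
        if model.output_dim == 1:
            output_index = np.zeros(n, dtype=int)
        else:
            # observe every output at every condition
            X = np.repeat(np.atleast_2d(X), model.output_dim, axis=0)
            output_index = np.tile(np.arange(model.output_dim), n)
            clean = np.repeat(clean, model.output_dim, axis=0)
            n = clean.shape[0]
    output_index = np.asarray(output_index, dtype=int)
    mu = clean[np.arange(n), output_index]
    if np.any(mu < 0):
        raise ValueError("model prediction < 0: heteroscedastic generation undefined")
    y = mu + eps * mu * rng.standard_normal(n)
    for _ in range(1000):
        neg = y < 0
        if not np.any(neg):
            break
        y[neg] = mu[neg] + eps * mu[neg] * rng.standard_normal(int(neg.sum()))
    else:  # pragma: no cover
        raise RuntimeError("truncated-normal rejection sampling did not converge")
    prov = {
        "generator": "heteroscedastic",
        "seed": int(seed),
        "eps": float(eps),
        "theta_R": theta_R.as_dict(),
    }
    return Dataset(np.atleast_2d(X), output_index, y, error, prov)


def generate_homoscedastic(
    model: DeterministicModel,
    X: np.ndarray,
    theta_R: ParameterSet,
    sigma: float,
    seed: int,
    output_index: np.ndarray | None = None,
) -> Dataset:
    """Draw observations ~ Normal(y_model, sigma) with constant SD."""
    error = ErrorSpec("homoscedastic", sigma=sigma)
    rng = np.random.default_rng(seed)
    clean = _predict_clean(model, X, theta_R)
    n = clean.shape[0]
    if output_index is None:
        if model.output_dim == 1:
            output_index = np.zeros(n, dtype=int)
        else:
            X = np.repeat(np.atleast_2d(X), model.output_dim, axis=0)
            output_index = np.tile(np.arange(model.output_dim), n)
            clean = np.repeat(clean, model.output_dim, axis=0)
            n = clean.shape[0]
    output_index = np.asarray(output_index, dtype=int)
    mu = clean[np.arange(n), output_index]
    y = mu + sigma * rng.standard_normal(n)
    prov = {
        "generator": "homoscedastic",
        "seed": int(seed),
        "sigma": float(sigma),
        "theta_R": theta_R.as_dict(),
    }
    return Dataset(np.atleast_2d(X), output_index, y, error, prov)


# ---------------------------------------------------------------------------
# delimited-text I/O (CSV + JSON provenance sidecar)
# ---------------------------------------------------------------------------

def save_dataset(data: Dataset, path: str | Path) -> None:
    """Write the dataset as CSV, with provenance in a ``.json`` sidecar."""
    path = Path(path)
    cols = {f"x{i}": data.X[:, i] for i in range(data.X.shape[1])}
    cols["output_index"] = data.output_index
    cols["y_obs"] = data.y_obs
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "error": {"kind": data.error.kind, data.error.param_name: data.error.value},
        "provenance": data.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    err = meta["error"]
    error = ErrorSpec(err["kind"], eps=err.get("eps"), sigma=err.get("sigma"))
    xcols = [c for c in df.columns if c.startswith("x")]
    return Dataset(
        df[xcols].to_numpy(float),
        df["output_index"].to_numpy(int),
        df["y_obs"].to_numpy(float),
        error,
        meta.get("provenance", {}),
    )
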