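"""Sensitivity matrices over log-parameters: H, L, P, G and K.

Five square symmetric matrices, all defined on the natural logarithms of the
model parameters with the measurement-error (nuisance) parameter excluded,
characterise how the model-data fit responds to parameter changes:

* ``H`` - Hessian of the negative log-likelihood at a point (usually the
  MLE), by central finite differences in log space;
* ``L`` - Levenberg-Marquardt (Gauss-Newton) approximation, the outer
  product of scaled-residual first derivatives: positive semidefinite, and
  equal to H at a zero-residual optimum;
* ``P`` - inverse posterior covariance of the log-parameters (the PCA
  Hessian), a global, sampling-based curvature summary;
* ``G`` - likelihood-informed-subspace matrix: the prior-preconditioned
  Hessian Lp^T H(theta) Lp (with Lp the Cholesky factor of the prior
  log-covariance Omega) averaged over posterior samples, isolating the
  directions where the data inform beyond the prior;
* ``K`` - likelihood-free approximation to G: Lp^T Sigma^{-1} Lp, valid
  when the posterior is close to Gaussian in log space.

Finite differences use a symmetric log-space step h = log(1 + delta), i.e.
evaluation at theta_i * e^{+-h}; this matches the relative step
Delta theta_i = delta * theta_i to second order and makes every matrix
exactly invariant to a change of parameter units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorEnsemble, posterior_log_moments
from .models.base import DeterministicModel
from .observation import Dataset, log_likelihood
from .parameters import ParameterSet
from .priors import Prior

__all__ = [
    "FDConfig",
    "SensitivityMatrix",
    "hessian_H",
    "levenberg_marquardt_L",
    "pca_P",
    "lis_G",
    "lis_K",
    "prior_log_covariance",
    "drop_nuisance",
    "save_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class FDConfig:
    """Central finite-difference configuration: relative step delta."""

    delta: float = 1e-3
    scheme: str = "central"

    def __post_init__(self) -> None:
        if not 1e-4 <= self.delta <= 1e-2:
            raise ValueError(f"delta must lie in [1e-4, 1e-2], got {self.delta}")
        if self.scheme != "central":
            raise ValueError("only the central difference scheme is supported")

    @property
    def log_step(self) -> float:
        return float(np.log1p(self.delta))


@dataclass(frozen=True)
class SensitivityMatrix:
    """A square symmetric sensitivity matrix tagged by kind (H|L|P|G|K)."""

    kind: str
    entries: np.ndarray
    names: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("H", "L", "P", "G", "K"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        A = np.asarray(self.entries, dtype=float)
        d = len(self.names)
        if A.shape != (d, d):
            raise ValueError("entries must be square and match names")
        scale = np.max(np.abs(A)) or 1.0
        if np.max(np.abs(A - A.T)) > 1e-10 * scale:
            raise ValueError(f"matrix {self.kind} is asymmetric beyond tolerance")
        object.__setattr__(self, "entries", 0.5 * (A + A.T))
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def dim(self) -> int:
        return len(self.names)


def _free_names(all_names: Sequence[str], nuisance: Iterable[str]) -> tuple[str, ...]:
    nuisance = set(nuisance)
    missing = nuisance - set(all_names)
    if missing:
        raise KeyError(f"nuisance names not in parameter template: {sorted(missing)}")
    return tuple(n for n in all_names if n not in nuisance)


def _neg_loglik_fn(model, data, theta: ParameterSet, free: tuple[str, ...]):
    """Negative log-likelihood as a function of the free log-parameters."""
    base = theta.as_dict()
    phi0 = np.array([np.log(base[n]) for n in free])

    def f(phi: np.ndarray) -> float:
        th = dict(base)
        for n, v in zip(free, np.exp(phi)):
            th[n] = v
        try:
            val = -log_likelihood(model, data, th)
        except (ValueError, RuntimeError) as exc:
            raise FloatingPointError(str(exc)) from exc
        if not np.isfinite(val):
            raise FloatingPointError("non-finite log-likelihood in FD stencil")
        return val

    return f, phi0


def hessian_H(
    model: DeterministicModel,
    data: Dataset,
    theta: ParameterSet,
    fd: FDConfig = FDConfig(),
    nuisance: Iterable[str] = (),
) -> SensitivityMatrix:
    """Hessian of -log L w.r.t. log-parameters by central differences.

    ``theta`` is the evaluation point (all parameters, including any
    nuisance error parameter, whose rows/columns are simply not computed).
    Symmetrised as (H + H^T)/2 before being returned.
    """
    free = _free_names(theta.names, nuisance)
    f, phi0 = _neg_loglik_fn(model, data, theta, free)
    h = fd.log_step
    d = len(free)
    H = np.empty((d, d))
    try:
        f0 = f(phi0)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            H[i, i] = (f(phi0 + ei) - 2.0 * f0 + f(phi0 - ei)) / h**2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d)
                ej = np.zeros(d)
                ei[i] = h
                ej[j] = h
                H[i, j] = H[j, i] = (
                    f(phi0 + ei + ej) - f(phi0 + ei - ej) - f(phi0 - ei + ej) + f(phi0 - ei - ej)
                ) / (4.0 * h * h)
    except FloatingPointError as exc:
        raise ValueError(f"Hessian stencil failed around parameters {free}: {exc}") from exc
    H = 0.5 * (H + H.T)
    return SensitivityMatrix("H", H, free, {"at": theta.as_dict(), "delta": fd.delta})


def _residuals(model, data: Dataset, theta_map) -> np.ndarray:
    """Scaled residuals r_k = (y_obs - y_model)/sigma_k at theta."""
    pred = model.predict(data.X, theta_map)
    y_model = pred[np.arange(data.n_obs), data.output_index]
    if data.error.kind == "heteroscedastic":
        eps = theta_map.get(data.error.param_name, data.error.value) if isinstance(theta_map, dict) else data.error.value
        if np.any(y_model <= 0):
            raise FloatingPointError("non-positive prediction: residual SD undefined")
        sig = eps * y_model
    else:
        sig = theta_map.get(data.error.param_name, data.error.value) if isinstance(theta_map, dict) else data.error.value
        sig = np.full(y_model.shape, sig)
    return (data.y_obs - y_model) / sig


def levenberg_marquardt_L(
    model: DeterministicModel,
    data: Dataset,
    theta: ParameterSet,
    fd: FDConfig = FDConfig(),
    nuisance: Iterable[str] = (),
) -> SensitivityMatrix:
    """Gauss-Newton matrix L = J^T J with J_ki = d r_k / d log theta_i.

    First derivatives of the scaled residuals by central differences in log
    space; positive semidefinite by construction.
    """
    free = _free_names(theta.names, nuisance)
    base = theta.as_dict()
    h = fd.log_step
    d = len(free)
    J = np.empty((data.n_obs, d))
    try:
        for i, name in enumerate(free):
            up = dict(base)
            dn = dict(base)
            up[name] = base[name] * np.exp(h)
            dn[name] = base[name] * np.exp(-h)
            J[:, i] = (_residuals(model, data, up) - _residuals(model, data, dn)) / (2.0 * h)
    except FloatingPointError as exc:
        raise ValueError(f"residual stencil failed for parameter {free[i]}: {exc}") from exc
    L = J.T @ J
    return SensitivityMatrix("L", L, free, {"at": theta.as_dict(), "delta": fd.delta})


def pca_P(ensemble: PosteriorEnsemble, nuisance: Iterable[str] = ()) -> SensitivityMatrix:
    """Inverse posterior log-covariance (the PCA Hessian).

    Near-singular covariances (condition number > 1e12) are regularised with
    a trace-scaled diagonal jitter and a warning: in sloppy models the
    flattest directions make Sigma ill-conditioned by design.
    """
    ens = ensemble.drop(nuisance) if nuisance else ensemble
    _, cov = posterior_log_moments(ens)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        jitter = 1e-10 * np.trace(cov) / cov.shape[0]
        warnings.warn(
            f"posterior covariance condition number {cond:.3g}; adding diagonal jitter {jitter:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = cov + jitter * np.eye(cov.shape[0])
    P = np.linalg.inv(cov)
    P = 0.5 * (P + P.T)
    return SensitivityMatrix("P", P, ens.names, {"M": ens.M, "condition_number": float(cond)})


def prior_log_covariance(prior: Prior, names: Sequence[str] | None = None) -> np.ndarray:
    """Log-space prior covariance Omega (optionally restricted to names)."""
    return prior.log_covariance(names)


def _prior_chol(prior: Prior, names: Sequence[str]) -> np.ndarray:
    omega = prior.log_covariance(names)
    try:
        return np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("prior log-covariance Omega is not positive definite") from exc


def lis_G(
    ensemble: PosteriorEnsemble,
    prior: Prior,
    model: DeterministicModel,
    data: Dataset,
    fd: FDConfig = FDConfig(),
    nuisance: Iterable[str] = (),
    subsample: int | None = 500,
    seed: int = 0,
) -> SensitivityMatrix:
    """Likelihood-informed-subspace matrix G = mean_m Lp^T H(theta_m) Lp.

    The Hessian is evaluated at each of up to ``subsample`` posterior draws
    (uniform random subsample, seeded) and preconditioned by the Cholesky
    factor Lp of the prior log-covariance restricted to the non-nuisance
    parameters.  Raises if more than 5% of the per-sample Hessians fail.
    """
    free = _free_names(ensemble.names, nuisance)
    Lp = _prior_chol(prior, free)
    rng = np.random.default_rng(seed)
    idx = np.arange(ensemble.M)
    if subsample is not None and subsample < ensemble.M:
        idx = rng.choice(ensemble.M, size=subsample, replace=False)
    acc = np.zeros((len(free), len(free)))
    failures = 0
    used = 0
    for m in idx:
        theta_m = ParameterSet(ensemble.names, np.exp(ensemble.log_samples[m]))
        try:
            Hm = hessian_H(model, data, theta_m, fd, nuisance).entries
        except (ValueError, FloatingPointError):
            failures += 1
            continue
        acc += Lp.T @ Hm @ Lp
        used += 1
    if failures > 0.05 * len(idx) or used == 0:
        raise RuntimeError(
            f"{failures}/{len(idx)} per-sample Hessians were non-finite; "
            "the posterior may extend into a region where the likelihood is undefined"
        )
    G = acc / used
    G = 0.5 * (G + G.T)
    return SensitivityMatrix("G", G, free, {"subsample": used, "delta": fd.delta, "seed": int(seed)})


def lis_K(
    sigma_hat: np.ndarray | PosteriorEnsemble,
    prior: Prior,
    names: Sequence[str] | None = None,
    nuisance: Iterable[str] = (),
) -> SensitivityMatrix:
    """Likelihood-free LIS approximation K = Lp^T Sigma^{-1} Lp.

    ``sigma_hat`` may be a posterior log-covariance (with ``names``) or a
    PosteriorEnsemble from which the covariance is estimated.
    """
    if isinstance(sigma_hat, PosteriorEnsemble):
        ens = sigma_hat.drop(nuisance) if nuisance else sigma_hat
        _, cov = posterior_log_moments(ens)
        names = ens.names
    else:
        if names is None:
            raise ValueError("names are required when passing a covariance matrix")
        names = _free_names(tuple(names), nuisance)
        cov = np.asarray(sigma_hat, dtype=float)
    Lp = _prior_chol(prior, names)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        jitter = 1e-10 * np.trace(cov) / cov.shape[0]
        warnings.warn(
            f"posterior covariance condition number {cond:.3g}; adding diagonal jitter {jitter:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = cov + jitter * np.eye(cov.shape[0])
    K = Lp.T @ np.linalg.inv(cov) @ Lp
    K = 0.5 * (K + K.T)
    return SensitivityMatrix("K", K, tuple(names), {"condition_number": float(cond)})


def drop_nuisance(matrix: SensitivityMatrix, nuisance: Iterable[str]) -> SensitivityMatrix:
    """Remove nuisance rows/columns from an already-built matrix.

    The main constructors above never compute nuisance rows in the first
    place; this helper covers matrices built elsewhere.  With no nuisance
    names it is an identity pass-through.
    """
    nuisance = set(nuisance)
    if not nuisance:
        return matrix
    missing = nuisance - set(matrix.names)
    if missing:
        raise KeyError(f"unknown parameter names {sorted(missing)}")
    keep = [i for i, n in enumerate(matrix.names) if n not in nuisance]
    return SensitivityMatrix(
        matrix.kind,
        matrix.entries[np.ix_(keep, keep)],
        tuple(matrix.names[i] for i in keep),
        dict(matrix.meta),
    )


def save_matrix(matrix: SensitivityMatrix, path: str | Path) -> None:
    """CSV with a parameter-name header, plus a JSON sidecar of metadata."""
    path = Path(path)
    pd.DataFrame(matrix.entries, columns=list(matrix.names)).to_csv(
        path, index=False, float_format="%.17g"
    )
    sidecar = {"kind": matrix.kind, "names": list(matrix.names), "meta": matrix.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_matrix(path: str | Path) -> SensitivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SensitivityMatrix(
        sidecar["kind"], df.to_numpy(float), tuple(sidecar["names"]), sidecar.get("meta", {})
    )
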