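"""Model fitting: maximum likelihood and adaptive annealing SMC.

Both fitters work in the space of natural logarithms of the parameters.

The sequential Monte Carlo sampler anneals from the prior to the posterior
through tempered targets pi_t proportional to L^{gamma_t} p, with the inverse
temperatures chosen adaptively: the next gamma is found by bisection so the
effective sample size (ESS) of the incremental importance weights stays at or
above (1 - Delta) * M, i.e. the ESS may fall by at most the fraction Delta
per anneal step.  After each reweighting the population is multinomially
resampled back to equal weights and diversified with Gaussian random-walk
Metropolis-Hastings moves whose proposal covariance is the classic
(2.38^2 / d) scaling of the current population covariance; the number of
sweeps is chosen from the measured acceptance rate so that each particle
moves at least once with probability >= C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .models.base import DeterministicModel
from .observation import Dataset, log_likelihood, log_likelihood_batch
from .parameters import ParameterSet
from .priors import Prior

__all__ = [
    "SMCSettings",
    "PosteriorEnsemble",
    "MLEResult",
    "fit_mle",
    "fit_mle_multistart",
    "smc_sample",
    "posterior_log_moments",
]

_BIG = 1e300  # pseudo-infinite cost outside the prior support


@dataclass(frozen=True)
class SMCSettings:
    """Sampler settings.

    M
        Number of particles (>= 2).
    mh_acceptance_target
        Probability C that each particle accepts at least one move per
        diversification stage; sets the number of MH sweeps.
    ess_reduction
        Per-step ESS reduction target Delta: the adaptive temperature step
        is the largest one keeping ESS >= (1 - Delta) * M.
    """

    M: int = 10_000
    mh_acceptance_target: float = 0.95
    ess_reduction: float = 0.001
    seed: int = 0
    max_sweeps: int = 30

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if not 0.0 < self.mh_acceptance_target < 1.0:
            raise ValueError("mh_acceptance_target must be in (0, 1)")
        if not 0.0 < self.ess_reduction < 1.0:
            raise ValueError("ess_reduction must be in (0, 1)")


@dataclass(frozen=True)
class PosteriorEnsemble:
    """M equally weighted posterior samples, stored in log space."""

    names: tuple[str, ...]
    log_samples: np.ndarray  # (M, d)
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ls = np.asarray(self.log_samples, dtype=float)
        if ls.ndim != 2 or ls.shape[1] != len(self.names):
            raise ValueError("log_samples must be (M, len(names))")
        object.__setattr__(self, "log_samples", ls)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def M(self) -> int:
        return self.log_samples.shape[0]

    @property
    def samples(self) -> np.ndarray:
        """Samples in the natural parameter scale."""
        return np.exp(self.log_samples)

    def parameter_sets(self) -> list[ParameterSet]:
        return [ParameterSet(self.names, row) for row in self.samples]

    def drop(self, names) -> "PosteriorEnsemble":
        drop = set(names)
        keep = [i for i, n in enumerate(self.names) if n not in drop]
        missing = drop - set(self.names)
        if missing:
            raise KeyError(f"unknown parameter names {sorted(missing)}")
        return PosteriorEnsemble(
            tuple(self.names[i] for i in keep), self.log_samples[:, keep], self.provenance
        )


@dataclass(frozen=True)
class MLEResult:
    theta: ParameterSet
    cost: float
    converged: bool
    n_iter: int


def _cost_in_log_space(model, data, prior, names):
    lo, hi = prior.log_bounds()

    def f(phi: np.ndarray) -> float:
        if np.any(phi < lo) or np.any(phi > hi):
            return _BIG
        try:
            ll = log_likelihood(model, data, dict(zip(names, np.exp(phi))))
        except (ValueError, RuntimeError):
            return _BIG
        return -ll if np.isfinite(ll) else _BIG

    return f


def fit_mle(
    model: DeterministicModel,
    data: Dataset,
    prior: Prior,
    theta_init: ParameterSet,
    maxfev: int | None = None,
    polish: bool = False,
) -> MLEResult:
    """Minimise the cost in log-parameter space with a Nelder-Mead simplex.

    The prior enters only through its support: uniform components bound the
    search box, matching an (otherwise unconstrained) maximum-likelihood fit.
    """
    names = prior.names
    phi0 = np.array([math.log(theta_init[n]) for n in names])
    f = _cost_in_log_space(model, data, prior, names)
    c0 = f(phi0)
    if c0 >= _BIG:
        raise ValueError("cost is not finite at theta_init (outside support or invalid)")
    options = {"xatol": 1e-8, "fatol": 1e-10, "adaptive": True}
    if maxfev is not None:
        options["maxfev"] = maxfev
    res = minimize(f, phi0, method="Nelder-Mead", options=options)
    phi, cost_val, converged = res.x, float(res.fun), bool(res.success)
    if polish:
        res2 = minimize(f, phi, method="Powell", options={"xtol": 1e-10, "ftol": 1e-12})
        if res2.fun < cost_val:
            phi, cost_val, converged = res2.x, float(res2.fun), bool(res2.success)
    if cost_val > c0:  # never worse than the start
        phi, cost_val = phi0, c0
    theta = ParameterSet.from_log(names, phi)
    return MLEResult(theta, cost_val, converged, int(res.nit))


def fit_mle_multistart(
    model: DeterministicModel,
    data: Dataset,
    prior: Prior,
    n_starts: int,
    seed: int,
    maxfev: int | None = None,
) -> list[MLEResult]:
    """Independent simplex fits from prior draws, best cost first."""
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_starts):
        phi0 = prior.sample_log(1, rng)[0]
        theta0 = ParameterSet.from_log(prior.names, phi0)
        try:
            results.append(fit_mle(model, data, prior, theta0, maxfev=maxfev))
        except ValueError:
            continue
    if not results:
        raise RuntimeError("no start point yielded a finite cost")
    return sorted(results, key=lambda r: r.cost)


def _ess(logw: np.ndarray) -> float:
    w = np.exp(logw - logw.max())
    s = w.sum()
    return float(s * s / np.dot(w, w))


def smc_sample(
    model: DeterministicModel,
    data: Dataset,
    prior: Prior,
    settings: SMCSettings = SMCSettings(),
) -> PosteriorEnsemble:
    """Sample the posterior by adaptive likelihood-annealing SMC.

    Returns M equally weighted samples targeting pi(theta | y_obs)
    proportional to L(y_obs | theta) p(theta), with the realised temperature
    ladder, settings and seed recorded in the ensemble provenance.
    """
    rng = np.random.default_rng(settings.seed)
    names = prior.names
    M, d = settings.M, prior.dim
    phi = prior.sample_log(M, rng)
    loglik = log_likelihood_batch(model, data, np.exp(phi), names)
    if not np.any(np.isfinite(loglik)):
        raise RuntimeError(
            "likelihood underflowed to zero for every prior particle; "
            "check the prior support and the dataset"
        )
    logprior = prior.logpdf_log(phi)
    gamma = 0.0
    ladder = [0.0]
    sweeps_used: list[int] = []
    target_ess = (1.0 - settings.ess_reduction) * M

    while gamma < 1.0:
        # --- adapt the next inverse temperature by bisection ------------
        def ess_at(g: float) -> float:
            return _ess((g - gamma) * loglik)

        if ess_at(1.0) >= target_ess:
            new_gamma = 1.0
        else:
            lo_g, hi_g = gamma, 1.0
            for _ in range(100):
                mid = 0.5 * (lo_g + hi_g)
                if ess_at(mid) >= target_ess:
                    lo_g = mid
                else:
                    hi_g = mid
            new_gamma = lo_g if lo_g > gamma else gamma + (hi_g - gamma) * 1e-10
        logw = (new_gamma - gamma) * loglik
        gamma = new_gamma
        ladder.append(gamma)

        # --- multinomial resampling to equal weights --------------------
        w = np.exp(logw - logw.max())
        w /= w.sum()
        idx = rng.choice(M, size=M, p=w)
        phi, loglik, logprior = phi[idx], loglik[idx], logprior[idx]

        # --- random-walk MH diversification -----------------------------
        cov = np.cov(phi, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(d)
        prop_chol = np.linalg.cholesky((2.38**2 / d) * cov)

        def sweep():
            nonlocal phi, loglik, logprior
            prop = phi + rng.standard_normal((M, d)) @ prop_chol.T
            prop_prior = prior.logpdf_log(prop)
            ok = np.isfinite(prop_prior)
            prop_ll = np.full(M, -np.inf)
            if np.any(ok):
                prop_ll[ok] = log_likelihood_batch(model, data, np.exp(prop[ok]), names)
            log_alpha = (gamma * prop_ll + prop_prior) - (gamma * loglik + logprior)
            accept = np.log(rng.uniform(size=M)) < log_alpha
            phi[accept] = prop[accept]
            loglik[accept] = prop_ll[accept]
            logprior[accept] = prop_prior[accept]
            return float(accept.mean())

        acc = sweep()
        n_sweeps = 1
        if acc <= 0.0:
            extra = settings.max_sweeps - 1
        else:
            want = math.ceil(math.log(1.0 - settings.mh_acceptance_target) / math.log(1.0 - min(acc, 0.999)))
            extra = min(settings.max_sweeps, max(1, want)) - 1
        for _ in range(extra):
            sweep()
            n_sweeps += 1
        sweeps_used.append(n_sweeps)

    provenance = {
        "sampler": "adaptive annealing SMC",
        "seed": int(settings.seed),
        "M": M,
        "mh_acceptance_target": settings.mh_acceptance_target,
        "ess_reduction": settings.ess_reduction,
        "temperature_ladder": ladder,
        "sweeps_per_step": sweeps_used,
    }
    return PosteriorEnsemble(names, phi, provenance)


def save_ensemble(ensemble: PosteriorEnsemble, path) -> None:
    """CSV of samples in the natural scale + JSON sidecar of provenance."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    pd.DataFrame(ensemble.samples, columns=list(ensemble.names)).to_csv(
        path, index=False, float_format="%.17g"
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(ensemble.provenance, indent=2, default=str)
    )


def load_ensemble(path) -> PosteriorEnsemble:
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return PosteriorEnsemble(tuple(df.columns), np.log(df.to_numpy(float)), prov)


def posterior_log_moments(ensemble: PosteriorEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and (M-1)-normalised covariance of the log-samples."""
    if ensemble.M < 2:
        raise ValueError("need at least two samples")
    mean = ensemble.log_samples.mean(axis=0)
    dev = ensemble.log_samples - mean
    cov = dev.T @ dev / (ensemble.M - 1)
    return mean, cov
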