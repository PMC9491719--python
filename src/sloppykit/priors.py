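"""Prior distributions on strictly positive parameters.

Supported components: uniform on a positive interval (in the natural
parameter scale), log-normal, and multivariate log-normal blocks with full
log-space covariance.  Because all sampling and optimisation happen in the
space of log-parameters, each component exposes its density *over the log
parameter* (the uniform picks up an exp Jacobian), its sampler, and its
exact log-space mean and covariance; the assembled covariance is the matrix
Omega used to precondition the likelihood-informed-subspace analysis.

For a uniform(a, b) component the log-space moments are closed form:

    E[log U]   = (b log b - a log a)/(b - a) - 1
    Var[log U] = 1 - a b (log b - log a)^2 / (b - a)^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["UniformComponent", "LogNormalComponent", "MultivariateLogNormalBlock", "Prior"]


@dataclass(frozen=True)
class UniformComponent:
    """Uniform(lo, hi) in the natural scale, on strictly positive support."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lo < self.hi:
            raise ValueError(f"uniform component {self.name!r} needs 0 < lo < hi")

    names = property(lambda self: (self.name,))
    dim = 1

    def logpdf_log(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        inside = (phi >= np.log(self.lo)) & (phi <= np.log(self.hi))
        # density over log theta: p(theta) * theta
        return np.where(inside, phi - np.log(self.hi - self.lo), -np.inf)

    def sample_log(self, M: int, rng: np.random.Generator) -> np.ndarray:
        return np.log(rng.uniform(self.lo, self.hi, size=(M, 1)))

    def log_mean(self) -> np.ndarray:
        a, b = self.lo, self.hi
        return np.array([(b * np.log(b) - a * np.log(a)) / (b - a) - 1.0])

    def log_cov(self) -> np.ndarray:
        a, b = self.lo, self.hi
        return np.array([[1.0 - a * b * (np.log(b) - np.log(a)) ** 2 / (b - a) ** 2]])

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([np.log(self.lo)]), np.array([np.log(self.hi)])


@dataclass(frozen=True)
class LogNormalComponent:
    """log theta ~ Normal(mu_log, sigma_log^2)."""

    name: str
    mu_log: float
    sigma_log: float

    def __post_init__(self) -> None:
        if not self.sigma_log > 0:
            raise ValueError(f"log-normal component {self.name!r} needs sigma_log > 0")

    names = property(lambda self: (self.name,))
    dim = 1

    def logpdf_log(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        z = (phi - self.mu_log) / self.sigma_log
        return -0.5 * np.log(2.0 * np.pi) - np.log(self.sigma_log) - 0.5 * z * z

    def sample_log(self, M: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu_log, self.sigma_log, size=(M, 1))

    def log_mean(self) -> np.ndarray:
        return np.array([self.mu_log])

    def log_cov(self) -> np.ndarray:
        return np.array([[self.sigma_log**2]])

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([-np.inf]), np.array([np.inf])


class MultivariateLogNormalBlock:
    """log theta ~ MVN(mu_log, cov_log) for a block of parameters."""

    def __init__(self, names: Sequence[str], mu_log: np.ndarray, cov_log: np.ndarray):
        self._names = tuple(names)
        self.mu_log = np.asarray(mu_log, dtype=float)
        self.cov_log = np.asarray(cov_log, dtype=float)
        d = len(self._names)
        if self.mu_log.shape != (d,) or self.cov_log.shape != (d, d):
            raise ValueError("mu_log/cov_log shapes must match the number of names")
        if not np.allclose(self.cov_log, self.cov_log.T):
            raise ValueError("cov_log must be symmetric")
        np.linalg.cholesky(self.cov_log)  # must be SPD
        self._mvn = stats.multivariate_normal(self.mu_log, self.cov_log)

    names = property(lambda self: self._names)

    @property
    def dim(self) -> int:
        return len(self._names)

    def logpdf_log(self, phi: np.ndarray) -> np.ndarray:
        return np.asarray(self._mvn.logpdf(phi), dtype=float)

    def sample_log(self, M: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mu_log, self.cov_log, size=M)

    def log_mean(self) -> np.ndarray:
        return self.mu_log.copy()

    def log_cov(self) -> np.ndarray:
        return self.cov_log.copy()

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.full(self.dim, -np.inf), np.full(self.dim, np.inf)


class Prior:
    """A joint prior assembled from independent components/blocks."""

    def __init__(self, components: Sequence[UniformComponent | LogNormalComponent | MultivariateLogNormalBlock]):
        self.components = tuple(components)
        names: list[str] = []
        for c in self.components:
            names.extend(c.names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names across prior components")
        self.names: tuple[str, ...] = tuple(names)

    @property
    def dim(self) -> int:
        return len(self.names)

    def _slices(self):
        start = 0
        for c in self.components:
            yield c, slice(start, start + c.dim)
            start += c.dim

    def logpdf_log(self, phi: np.ndarray) -> np.ndarray:
        """Log-density over log-parameters; phi of shape (..., dim)."""
        phi = np.asarray(phi, dtype=float)
        squeeze = phi.ndim == 1
        phi2 = np.atleast_2d(phi)
        total = np.zeros(phi2.shape[0])
        for c, sl in self._slices():
            block = phi2[:, sl]
            lp = c.logpdf_log(block if c.dim > 1 else block[:, 0])
            total = total + np.asarray(lp, dtype=float).reshape(-1)
        return total[0] if squeeze else total

    def sample_log(self, M: int, rng: np.random.Generator) -> np.ndarray:
        cols = [np.atleast_2d(c.sample_log(M, rng).reshape(M, c.dim)) for c, _ in self._slices()]
        return np.hstack(cols)

    def log_mean(self) -> np.ndarray:
        return np.concatenate([c.log_mean() for c, _ in self._slices()])

    def log_covariance(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Block-diagonal log-space covariance Omega (optionally reordered
        and restricted to ``names``)."""
        d = self.dim
        omega = np.zeros((d, d))
        for c, sl in self._slices():
            omega[sl, sl] = c.log_cov()
        if names is None:
            return omega
        idx = [self.names.index(n) for n in names]
        return omega[np.ix_(idx, idx)]

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*[c.log_bounds() for c, _ in self._slices()])
        return np.concatenate(los), np.concatenate(his)

    def in_support(self, phi: np.ndarray) -> np.ndarray:
        lo, hi = self.log_bounds()
        phi2 = np.atleast_2d(np.asarray(phi, dtype=float))
        ok = np.all((phi2 >= lo) & (phi2 <= hi), axis=1)
        return ok[0] if np.asarray(phi).ndim == 1 else ok
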