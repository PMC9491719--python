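"""Eigendecomposition, eigenparameters, and the prior-vs-data diagnosis.

An eigenvector v_n of a sensitivity matrix over log-parameters defines an
*eigenparameter*: the product/quotient of bare parameters

    theta_hat_n = prod_j theta_j ^ (v_n)_j,

stiff for large eigenvalues (tightly constrained combinations) and sloppy
for small ones.  For reporting, eigenvector elements with magnitude below a
threshold (default 0.2) are dropped, the surviving exponents are rescaled so
the largest magnitude is exactly 1, and the sign is canonicalised so the
largest-magnitude exponent is positive (an eigenparameter and its reciprocal
are the same direction).

Comparing the stiffest eigenparameters across matrix kinds diagnoses where
the information comes from: if H/L (likelihood only), P (posterior) and G
(data-beyond-prior) all agree, the priors are weakly informative and the
data dominate; if only P disagrees, the combination P finds is propped up
by the prior; if G disagrees with H/L, the prior is influencing the fit
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameters import ParameterSet
from .sensitivity import SensitivityMatrix

__all__ = [
    "EigenDecomposition",
    "Eigenparameter",
    "eigendecompose",
    "to_eigenparameter",
    "eigenparameter_value",
    "diagnose_information_source",
    "perturb_along_direction",
    "plot_eigenvalue_spectrum",
]


@dataclass(frozen=True)
class EigenDecomposition:
    """Eigenvalues (descending) and orthonormal eigenvectors of a matrix."""

    kind: str
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column n is v_n
    names: tuple[str, ...]

    def vector(self, n: int) -> np.ndarray:
        return self.eigenvectors[:, n]


@dataclass(frozen=True)
class Eigenparameter:
    """A ranked product/quotient of bare parameters with rescaled exponents."""

    rank: int
    exponents: dict[str, float]  # only parameters surviving the threshold
    eigenvalue: float
    raw_vector: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]
    names: tuple[str, ...] = field(default=(), compare=False)

    def __str__(self) -> str:
        num = [(n, e) for n, e in self.exponents.items() if e > 0]
        den = [(n, -e) for n, e in self.exponents.items() if e < 0]
        fmt = lambda items: "·".join(f"{n}^{e:.1f}" for n, e in items)
        s = fmt(num) or "1"
        if den:
            s += "/" + fmt(den)
        return s


def eigendecompose(S: SensitivityMatrix) -> EigenDecomposition:
    """Spectral decomposition with eigenvalues sorted stiffest-first."""
    vals, vecs = np.linalg.eigh(S.entries)
    order = np.argsort(vals)[::-1]
    return EigenDecomposition(S.kind, vals[order], vecs[:, order], S.names)


def to_eigenparameter(
    v: np.ndarray,
    names: Sequence[str],
    threshold: float = 0.2,
    eigenvalue: float = np.nan,
    rank: int = 0,
) -> Eigenparameter:
    """Convert a normalised eigenvector into a canonical eigenparameter.

    Elements with magnitude below ``threshold`` are dropped first; the
    surviving exponents are divided by the largest surviving magnitude, and
    the whole vector is flipped if needed so that the largest-magnitude
    exponent is positive.
    """
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("eigenvector must be normalised to unit length")
    keep = np.abs(v) >= threshold
    if not np.any(keep):
        raise ValueError(
            f"degenerate eigenvector: no element reaches the threshold {threshold}"
        )
    scale = np.max(np.abs(v[keep]))
    sign = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
    canonical = sign * v / scale
    exponents = {n: float(canonical[i]) for i, n in enumerate(names) if keep[i]}
    return Eigenparameter(rank, exponents, float(eigenvalue), sign * v, tuple(names))


def eigenparameter_value(ep: Eigenparameter, theta: ParameterSet | Mapping[str, float]) -> float:
    """theta_hat = prod theta_j ^ exponent_j over the surviving parameters."""
    get = theta.__getitem__
    return float(np.exp(sum(e * np.log(get(n)) for n, e in ep.exponents.items())))


def _similarity(a: Eigenparameter, b: Eigenparameter) -> float:
    """|cosine| between the full-length eigenvector directions."""
    va, vb = a.raw_vector, b.raw_vector
    return float(abs(np.dot(va, vb)) / (np.linalg.norm(va) * np.linalg.norm(vb)))


def diagnose_information_source(
    stiffest: Mapping[str, Eigenparameter],
    similar_threshold: float = 0.9,
) -> tuple[str, dict[str, float]]:
    """Classify the information source behind the stiffest eigenparameters.

    ``stiffest`` maps matrix kind ("H" or "L", "P", "G") to its stiffest
    eigenparameter.  Returns a label and the pairwise |cosine| similarities:

    * ``data_dominated``      - all kinds agree: priors weakly informative;
    * ``P_prior_influenced``  - H/L and G agree but P differs: the posterior
      covariance's stiff combination is propped up by the prior;
    * ``prior_influences_fit`` - G differs from H/L: the prior moves the
      plausible region and the data inform different combinations there.
    """
    hl = stiffest.get("H") or stiffest.get("L")
    P = stiffest.get("P")
    G = stiffest.get("G")
    scores: dict[str, float] = {}
    if hl is not None and P is not None:
        scores["HL_vs_P"] = _similarity(hl, P)
    if hl is not None and G is not None:
        scores["HL_vs_G"] = _similarity(hl, G)
    if P is not None and G is not None:
        scores["P_vs_G"] = _similarity(P, G)
    if hl is None or P is None or G is None:
        import warnings

        warnings.warn("missing matrix kind: diagnosis is partial", RuntimeWarning, stacklevel=2)
        return "partial", scores
    if scores["HL_vs_G"] >= similar_threshold and scores["HL_vs_P"] >= similar_threshold:
        return "data_dominated", scores
    if scores["HL_vs_G"] >= similar_threshold:
        return "P_prior_influenced", scores
    return "prior_influences_fit", scores


def plot_eigenvalue_spectrum(decompositions: Mapping[str, EigenDecomposition], path) -> None:
    """Log-scale eigenvalue spectra, one marker column per matrix kind.

    A spectrum spanning many decades is the signature of sloppiness: a few
    stiff directions and a long tail of sloppy ones.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(decompositions), 4.0))
    for x, (kind, dec) in enumerate(decompositions.items()):
        vals = np.abs(dec.eigenvalues)
        vals = np.where(vals > 0, vals, np.nan)
        ax.plot(np.full(vals.size, x), vals, "_", markersize=22, markeredgewidth=2)
    ax.set_yscale("log")
    ax.set_xticks(range(len(decompositions)), list(decompositions))
    ax.set_xlim(-0.5, len(decompositions) - 0.5)
    ax.set_ylabel("eigenvalue (log scale)")
    ax.set_xlabel("sensitivity matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def perturb_along_direction(
    theta0: ParameterSet,
    v: np.ndarray,
    magnitudes: Sequence[float],
    names: Sequence[str] | None = None,
) -> list[ParameterSet]:
    """Parameter sets theta_c = exp(log theta0 + c v) for each magnitude c.

    Moving along a sloppy eigenvector leaves every eigenparameter built from
    orthogonal (stiff) eigenvectors exactly unchanged, because the map is
    linear in log space.  ``names`` selects which parameters v spans when it
    is lower-dimensional than theta0 (e.g. after nuisance exclusion).
    """
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    span = tuple(names) if names is not None else theta0.names
    idx = [theta0.names.index(n) for n in span]
    out = []
    for c in magnitudes:
        if c == 0.0:  # exact identity, no exp/log round trip
            out.append(theta0)
            continue
        log_theta = theta0.log_values.copy()
        log_theta[idx] += float(c) * v
        out.append(ParameterSet.from_log(theta0.names, log_theta))
    return out
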