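"""Beeler-Reuter (1977) ventricular action-potential model.

The model describes the transmembrane potential V_m of a single mammalian
ventricular myocyte through four ionic currents:

* I_Na  - fast inward sodium current (upstroke), gated by m, h, j;
* I_s   - slow inward (calcium) current (plateau), gated by d, f, with a
  reversal potential set by intracellular calcium [Ca]_i;
* I_K1  - time-independent outward potassium current (resting/repolarising);
* I_x1  - time-activated outward current (repolarisation), gated by x_1.

The state vector is (V_m, [Ca]_i, x_1, m, h, j, d, f); each gate g obeys
dg/dt = alpha_g(V)(1-g) - beta_g(V) g, which confines it to [0, 1].

The nine free parameters exposed for fitting are the conductances and
magnitude factors g_Na, g_NaC, E_Na, g_s, multiplicative amplitude scalers
A_K1 and A_x1 on the two potassium currents, and three rate scalers on the
gating kinetics (k_Na for m/h/j, k_x1 for x_1, k_si for d/f).  Reference
values are the published 1977 constants with all pure scalers at 1, so the
reference model is exactly the original formulation.  Stimulus and initial
conditions are treated as known experimental settings, not fitted.

Units: mV, ms, uA/cm^2, uF/cm^2, mmho/cm^2; [Ca]_i in mol/l.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ..parameters import ParameterSet
from .base import DeterministicModel

__all__ = [
    "BR_REFERENCE",
    "BeelerReuterState",
    "StimulusProtocol",
    "IntegrationError",
    "beeler_reuter_simulate",
    "resting_state",
    "BeelerReuterModel",
    "apd90",
]

#: 1977 reference constants; the three kinetic scalers are pure numbers.
BR_REFERENCE = ParameterSet(
    ("g_Na", "g_NaC", "E_Na", "g_s", "A_K1", "A_x1", "k_Na", "k_x1", "k_si"),
    np.array([4.0, 0.003, 50.0, 0.09, 1.0, 1.0, 1.0, 1.0, 1.0]),
)


class IntegrationError(RuntimeError):
    """Raised when the action-potential ODE integration fails."""


@dataclass(frozen=True)
class BeelerReuterState:
    """Full model state: potential, calcium, and the six gates."""

    V_m: float
    Ca_i: float
    x_1: float
    m: float
    h: float
    j: float
    d: float
    f: float

    def __post_init__(self) -> None:
        if not self.Ca_i > 0:
            raise ValueError("[Ca]_i must be > 0")
        gates = (self.x_1, self.m, self.h, self.j, self.d, self.f)
        if any(g < -1e-9 or g > 1 + 1e-9 for g in gates):
            raise ValueError(f"gate variables must lie in [0, 1], got {gates}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V_m, self.Ca_i, self.x_1, self.m, self.h, self.j, self.d, self.f])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "BeelerReuterState":
        return cls(*[float(v) for v in y])


@dataclass(frozen=True)
class StimulusProtocol:
    """Rectangular stimulus: amplitude A_s (uA/cm^2) on [t_on, t_on + t_dur)."""

    A_s: float = 30.0
    t_on: float = 10.0
    t_dur: float = 2.0
    C_m: float = 1.0  # membrane capacitance, uF/cm^2

    def __post_init__(self) -> None:
        if not self.t_dur > 0:
            raise ValueError("stimulus duration t_dur must be > 0")
        if self.C_m <= 0:
            raise ValueError("membrane capacitance C_m must be > 0")

    def current(self, t: float) -> float:
        return self.A_s if self.t_on <= t < self.t_on + self.t_dur else 0.0


def _safe_ratio(x, a):
    """x / (1 - exp(-a*x)) with its removable singularity filled at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(a * x) < 1e-7
    denom = np.where(small, 1.0, 1.0 - np.exp(-a * np.where(small, 1.0, x)))
    return np.where(small, 1.0 / a + x / 2.0, x / denom)


def _gate_rates(V):
    """1977 rate coefficients alpha, beta (1/ms) for each of the six gates."""
    V = float(V)
    e = np.exp
    a_x1 = 0.0005 * e(0.083 * (V + 50.0)) / (e(0.057 * (V + 50.0)) + 1.0)
    b_x1 = 0.0013 * e(-0.06 * (V + 20.0)) / (e(-0.04 * (V + 20.0)) + 1.0)
    a_m = float(_safe_ratio(V + 47.0, 0.1))
    b_m = 40.0 * e(-0.056 * (V + 72.0))
    a_h = 0.126 * e(-0.25 * (V + 77.0))
    b_h = 1.7 / (e(-0.082 * (V + 22.5)) + 1.0)
    a_j = 0.055 * e(-0.25 * (V + 78.0)) / (e(-0.2 * (V + 78.0)) + 1.0)
    b_j = 0.3 / (e(-0.1 * (V + 32.0)) + 1.0)
    a_d = 0.095 * e(-0.01 * (V - 5.0)) / (e(-0.072 * (V - 5.0)) + 1.0)
    b_d = 0.07 * e(-0.017 * (V + 44.0)) / (e(0.05 * (V + 44.0)) + 1.0)
    a_f = 0.012 * e(-0.008 * (V + 28.0)) / (e(0.15 * (V + 28.0)) + 1.0)
    b_f = 0.0065 * e(-0.02 * (V + 30.0)) / (e(-0.2 * (V + 30.0)) + 1.0)
    return {
        "x_1": (a_x1, b_x1),
        "m": (a_m, b_m),
        "h": (a_h, b_h),
        "j": (a_j, b_j),
        "d": (a_d, b_d),
        "f": (a_f, b_f),
    }


def _currents(V, Ca, x1, m, h, j, d, f, p: Mapping[str, float]):
    """Ionic currents (uA/cm^2) at the given state."""
    e = np.exp
    i_K1 = p["A_K1"] * 0.35 * (
        4.0 * (e(0.04 * (V + 85.0)) - 1.0) / (e(0.08 * (V + 53.0)) + e(0.04 * (V + 53.0)))
        + 0.2 * float(_safe_ratio(V + 23.0, 0.04))
    )
    i_x1 = p["A_x1"] * x1 * 0.8 * (e(0.04 * (V + 77.0)) - 1.0) / e(0.04 * (V + 35.0))
    i_Na = (p["g_Na"] * m**3 * h * j + p["g_NaC"]) * (V - p["E_Na"])
    E_s = -82.3 - 13.0287 * np.log(Ca)
    i_s = p["g_s"] * d * f * (V - E_s)
    return i_K1, i_x1, i_Na, i_s


def _rhs(t, y, p: Mapping[str, float], stim: StimulusProtocol, stim_on: bool):
    V, Ca, x1, m, h, j, d, f = y
    i_K1, i_x1, i_Na, i_s = _currents(V, Ca, x1, m, h, j, d, f, p)
    i_stim = stim.A_s if stim_on else 0.0
    dV = (i_stim - (i_K1 + i_x1 + i_Na + i_s)) / stim.C_m
    dCa = -1.0e-7 * i_s + 0.07 * (1.0e-7 - Ca)
    rates = _gate_rates(V)
    scale = {"x_1": p["k_x1"], "m": p["k_Na"], "h": p["k_Na"], "j": p["k_Na"], "d": p["k_si"], "f": p["k_si"]}
    gates = dict(zip(("x_1", "m", "h", "j", "d", "f"), (x1, m, h, j, d, f)))
    dgates = [scale[g] * (rates[g][0] * (1.0 - gates[g]) - rates[g][1] * gates[g]) for g in gates]
    return [dV, dCa, *dgates]


def _theta_dict(theta: ParameterSet | Mapping[str, float]) -> dict[str, float]:
    if isinstance(theta, ParameterSet):
        return theta.as_dict()
    return {k: float(v) for k, v in theta.items()}


def resting_state(theta: ParameterSet | Mapping[str, float] | None = None) -> BeelerReuterState:
    """Quiescent equilibrium: gates at their steady states, zero net current.

    Solves the coupled fixed point (V with gates at alpha/(alpha+beta),
    [Ca]_i at its balance value) by nested root finding; the returned state
    is an exact stationary point of the ODE system, so an unstimulated
    simulation started there stays put to within solver tolerance.
    """
    p = _theta_dict(theta if theta is not None else BR_REFERENCE)

    def ca_balance(V, gates):
        d, f = gates["d"], gates["f"]

        def g(ca):
            E_s = -82.3 - 13.0287 * np.log(ca)
            i_s = p["g_s"] * d * f * (V - E_s)
            return 0.07 * (1.0e-7 - ca) - 1.0e-7 * i_s

        return brentq(g, 1e-10, 1e-3, xtol=1e-16, rtol=1e-14)

    def net_current(V):
        rates = _gate_rates(V)
        gates = {k: a / (a + b) for k, (a, b) in rates.items()}
        ca = ca_balance(V, gates)
        i = _currents(V, ca, gates["x_1"], gates["m"], gates["h"], gates["j"], gates["d"], gates["f"], p)
        return sum(i)

    V0 = brentq(net_current, -95.0, -60.0, xtol=1e-12)
    rates = _gate_rates(V0)
    gates = {k: a / (a + b) for k, (a, b) in rates.items()}
    ca0 = ca_balance(V0, gates)
    return BeelerReuterState(V0, ca0, gates["x_1"], gates["m"], gates["h"], gates["j"], gates["d"], gates["f"])


def _simulate_states(
    theta: ParameterSet | Mapping[str, float],
    stim: StimulusProtocol,
    t_grid: np.ndarray,
    init: BeelerReuterState,
    rtol: float = 1e-6,
) -> np.ndarray:
    p = _theta_dict(theta)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with at least two points")
    # [Ca]_i lives at the 1e-7 mol/l scale: give it a much tighter absolute floor.
    atol = np.full(8, 1e-8)
    atol[1] = 1e-13
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    # integrate piecewise across the stimulus discontinuities
    edges = [t for t in (stim.t_on, stim.t_on + stim.t_dur) if t0 < t < t_end]
    segments = list(zip([t0, *edges], [*edges, t_end]))
    y = init.as_array()
    out = np.empty((t_grid.size, 8))
    filled = 0
    for a, b in segments:
        stim_on = stim.t_on <= (a + b) / 2.0 < stim.t_on + stim.t_dur and stim.A_s != 0.0
        sol = solve_ivp(
            _rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=True, args=(p, stim, stim_on), max_step=b - a,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(f"action-potential integration failed near t = {sol.t[-1]:.3f} ms")
        remaining = t_grid[filled:]
        ts = remaining[remaining <= b + 1e-12]
        if ts.size:
            out[filled : filled + ts.size] = sol.sol(ts).T
            filled += ts.size
        y = sol.y[:, -1]
    if filled != t_grid.size:  # pragma: no cover - defensive
        raise IntegrationError("time grid not fully covered by integration segments")
    if not np.all(np.isfinite(out)):
        bad = t_grid[~np.all(np.isfinite(out), axis=1)][0]
        raise IntegrationError(f"non-finite state at t = {bad:.3f} ms")
    return out


def beeler_reuter_simulate(
    theta: ParameterSet | Mapping[str, float],
    stim: StimulusProtocol,
    t_grid: np.ndarray,
    init: BeelerReuterState | None = None,
    full_state: bool = False,
) -> np.ndarray:
    """Integrate the model and return V_m (mV) on ``t_grid``.

    ``init`` defaults to the quiescent equilibrium of ``theta``.  With
    ``full_state=True`` the whole (n, 8) state trajectory is returned.
    """
    if init is None:
        init = resting_state(theta)
    states = _simulate_states(theta, stim, np.asarray(t_grid, dtype=float), init)
    return states if full_state else states[:, 0]


def apd90(t: np.ndarray, V: np.ndarray) -> float:
    """Action-potential duration at 90% repolarisation (ms).

    Measured as the time spent above V_rest + 0.1 * (V_peak - V_rest),
    using the first sample as the resting level.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    rest = V[0]
    level = rest + 0.1 * (V.max() - rest)
    above = np.nonzero(V > level)[0]
    if above.size == 0:
        return 0.0
    return float(t[above[-1]] - t[above[0]])


class BeelerReuterModel(DeterministicModel):
    """Forward model: input condition x = time (ms), output V_m (mV).

    The stimulus protocol and the initial state are experimental settings
    fixed at construction (the initial state defaults to the quiescent
    equilibrium of the reference parameters) and are not fitted.
    """

    name = "beeler_reuter"
    input_dim = 1
    output_dim = 1

    def __init__(self, stim: StimulusProtocol | None = None, init: BeelerReuterState | None = None):
        self.stim = stim or StimulusProtocol()
        self.init = init or resting_state(BR_REFERENCE)

    def parameter_template(self) -> ParameterSet:
        return BR_REFERENCE

    def predict(self, X: np.ndarray, theta: ParameterSet | Mapping[str, float]) -> np.ndarray:
        X = self._check_X(X)
        times = X[:, 0]
        order = np.argsort(times, kind="stable")
        t_sorted = times[order]
        if np.any(np.diff(t_sorted) <= 0):
            t_unique, inverse = np.unique(times, return_inverse=True)
            V = beeler_reuter_simulate(theta, self.stim, t_unique, self.init)
            return V[inverse].reshape(-1, 1)
        V = beeler_reuter_simulate(theta, self.stim, t_sorted, self.init)
        out = np.empty_like(V)
        out[order] = V
        return out.reshape(-1, 1)
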