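"""Forward pharmacokinetic models.

The built-in model is a linear three-compartment system with first-order
absorption, central elimination and peripheral exchange::

    dx1/dt = -Ka*x1                                   (absorption depot)
    dx2/dt =  Ka*x1 - (Ke+Kcp)*x2 + Kpc*x3 + r(t)     (central)
    dx3/dt =  Kcp*x2 - Kpc*x3                         (peripheral)

with output ``y(t) = x2(t)/V``.  Boluses are instantaneous additions to a
compartment's state; infusions are zero-order (constant-rate) inputs over a
finite duration.  Compartments are 0-based: 0 = depot, 1 = central,
2 = peripheral.

Two evaluation paths are provided.  The analytic path integrates the
constant-coefficient system exactly between dose breakpoints using the
matrix exponential of an augmented (state + constant forcing) matrix; it is
vectorised over batches of parameter vectors and is the production path.
The ODE path drives an adaptive stiff-capable integrator piece by piece and
serves as an independent numerical cross-check.

An observation falling exactly on an event time is evaluated after the
event is applied; because infusion rates enter continuously this only
matters for boluses.  An observation at an infusion stop time therefore
sees the (continuous) state with the infusion integrated over its full
half-open activity window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .data import DoseEvent

__all__ = [
    "PKParameters",
    "PKModelSpec",
    "ThreeCompartmentModel",
    "three_comp_predict",
    "get_model",
    "register_model",
]

N_STATE = 3


@dataclass(frozen=True)
class PKParameters:
    """Parameters of the three-compartment model.

    V is the central volume of distribution (L); Ka, Ke, Kcp, Kpc are
    first-order rate constants (1/hour): absorption, elimination, central->
    peripheral and peripheral->central transfer.  Rate constants of zero
    give the usual reduced models (e.g. Kcp=Kpc=0 is one-compartment).
    """

    V: float
    Ka: float
    Ke: float
    Kcp: float
    Kpc: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("V must be > 0")
        for name in ("Ka", "Ke", "Kcp", "Kpc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.Ka, self.Ke, self.Kcp, self.Kpc])


def _system_matrix(theta: np.ndarray) -> np.ndarray:
    """Batched compartmental matrix A(theta): theta (K,5) -> (K,3,3)."""
    V, Ka, Ke, Kcp, Kpc = theta.T
    K = theta.shape[0]
    A = np.zeros((K, N_STATE, N_STATE))
    A[:, 0, 0] = -Ka
    A[:, 1, 0] = Ka
    A[:, 1, 1] = -(Ke + Kcp)
    A[:, 1, 2] = Kpc
    A[:, 2, 1] = Kcp
    A[:, 2, 2] = -Kpc
    return A


def _event_schedule(doses: Sequence[DoseEvent], t_max: float):
    """Breakpoints, per-piece constant infusion forcing, and bolus jumps.

    Returns (breaks, forcing, bolus_map): ``breaks`` sorted start times of
    the constant-coefficient pieces (breaks[0] == 0), ``forcing[p]`` the
    length-3 rate vector active on [breaks[p], breaks[p+1]), ``bolus_map``
    mapping a break time to the state increment applied at that instant.
    """
    cuts = {0.0}
    for d in doses:
        cuts.add(float(d.time))
        if d.kind == "infusion":
            cuts.add(float(d.end_time))
    breaks = sorted(c for c in cuts if c <= t_max or np.isclose(c, t_max))
    if breaks[0] != 0.0:
        breaks.insert(0, 0.0)

    forcing = np.zeros((len(breaks), N_STATE))
    bolus_map: dict[float, np.ndarray] = {}
    for d in doses:
        if d.kind == "bolus":
            if d.time <= t_max:
                jump = bolus_map.setdefault(float(d.time), np.zeros(N_STATE))
                jump[d.compartment] += d.amount
        else:
            for p, t0 in enumerate(breaks):
                if d.time <= t0 < d.end_time:
                    forcing[p, d.compartment] += d.rate
    return np.asarray(breaks), forcing, bolus_map


def _propagators(A: np.ndarray, u: np.ndarray, tau: float) -> np.ndarray:
    """exp(M*tau) for the augmented system M = [[A, u], [0, 0]], batched.

    The augmented form absorbs the constant forcing ``u`` so singular A
    (zero rate constants) needs no special casing.
    """
    K = A.shape[0]
    M = np.zeros((K, N_STATE + 1, N_STATE + 1))
    M[:, :N_STATE, :N_STATE] = A
    M[:, :N_STATE, N_STATE] = u
    return expm(M * tau)


def _predict_analytic(theta: np.ndarray, doses, times: np.ndarray) -> np.ndarray:
    A = _system_matrix(theta)
    K = theta.shape[0]
    t_max = float(times[-1]) if len(times) else 0.0
    breaks, forcing, bolus_map = _event_schedule(doses, t_max)

    out = np.empty((K, len(times)))
    # piece index of each observation time: events at t apply before an
    # observation at the same t
    piece_of = np.searchsorted(breaks, times, side="right") - 1

    state = np.zeros((K, N_STATE + 1))
    state[:, N_STATE] = 1.0  # homogeneous coordinate carrying the forcing
    for p, t0 in enumerate(breaks):
        if t0 in bolus_map:
            state[:, :N_STATE] += bolus_map[t0]
        sel = np.flatnonzero(piece_of == p)
        for j in sel:
            tau = times[j] - t0
            if tau == 0.0:
                x = state
            else:
                x = np.einsum(
                    "kij,kj->ki", _propagators(A, forcing[p], tau), state
                )
            out[:, j] = x[:, 1]
        if p + 1 < len(breaks):
            tau = breaks[p + 1] - t0
            if tau > 0:
                state = np.einsum(
                    "kij,kj->ki", _propagators(A, forcing[p], tau), state
                )
    V = theta[:, 0]
    return out / V[:, None]


def _predict_ode(theta_row: np.ndarray, doses, times: np.ndarray,
                 rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    A = _system_matrix(theta_row[None, :])[0]
    t_max = float(times[-1]) if len(times) else 0.0
    breaks, forcing, bolus_map = _event_schedule(doses, t_max)
    out = np.empty(len(times))
    piece_of = np.searchsorted(breaks, times, side="right") - 1

    x = np.zeros(N_STATE)
    for p, t0 in enumerate(breaks):
        if t0 in bolus_map:
            x = x + bolus_map[t0]
        u = forcing[p]
        t1 = breaks[p + 1] if p + 1 < len(breaks) else t_max
        sel = np.flatnonzero(piece_of == p)
        t_eval = times[sel]
        t_end = max(t1, t_eval[-1] if len(t_eval) else t0)
        if t_end > t0:
            sol = solve_ivp(
                lambda t, y: A @ y + u, (t0, t_end), x, method="LSODA",
                t_eval=np.unique(np.concatenate([t_eval, [t_end]])),
                rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            for j, tj in zip(sel, t_eval):
                x_at = sol.y[:, np.searchsorted(sol.t, tj)]
                out[j] = x_at[1]
            x = sol.y[:, -1]
        else:
            for j in sel:
                out[j] = x[1]
    return out / theta_row[0]


@dataclass(frozen=True)
class PKModelSpec:
    """Contract for a pluggable forward model.

    ``predict(theta, doses, obs_points)`` takes a (K, Q) batch of parameter
    vectors (columns ordered as ``parameter_names``), the dosing events and
    a sequence of (time, output_index) pairs, and returns a (K, n_obs)
    array of finite predictions.
    """

    name: str
    parameter_names: tuple[str, ...]
    n_outputs: int
    predict: Callable[[np.ndarray, Sequence[DoseEvent], Sequence[tuple]], np.ndarray]


def _three_comp_spec_predict(theta, doses, obs_points):
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    times = np.asarray([t for t, _ in obs_points], dtype=float)
    if any(j != 0 for _, j in obs_points):
        raise ValueError("three-compartment model has a single output")
    order = np.argsort(times, kind="stable")
    pred = _predict_analytic(theta, doses, times[order])
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return pred[:, inv]


ThreeCompartmentModel = PKModelSpec(
    name="threecomp",
    parameter_names=("V", "Ka", "Ke", "Kcp", "Kpc"),
    n_outputs=1,
    predict=_three_comp_spec_predict,
)


def three_comp_predict(
    params: PKParameters | np.ndarray,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    method: str = "analytic",
) -> np.ndarray:
    """Central-compartment concentration x2(t)/V at the requested times.

    ``method="analytic"`` uses exact piecewise matrix-exponential
    integration; ``method="ode"`` uses adaptive numerical integration and
    exists as an independent check of the analytic path.
    """
    if isinstance(params, PKParameters):
        theta = params.as_array()
    else:
        theta = np.asarray(params, dtype=float)
    if theta.ndim != 1 or theta.shape[0] != 5:
        raise ValueError("params must be PKParameters or a length-5 vector")
    if theta[0] <= 0 or np.any(theta[1:] < 0):
        raise ValueError("V must be > 0 and rate constants >= 0")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if method == "analytic":
        return _predict_analytic(theta[None, :], doses, times)[0]
    if method == "ode":
        return _predict_ode(theta, doses, times)
    raise ValueError(f"unknown method {method!r}")


_REGISTRY: dict[str, PKModelSpec] = {"threecomp": ThreeCompartmentModel}


def register_model(spec: PKModelSpec) -> None:
    """Register a plug-in model under ``spec.name``."""
    _REGISTRY[spec.name] = spec


def get_model(name: str) -> PKModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
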