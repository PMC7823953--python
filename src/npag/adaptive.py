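"""The adaptive-grid outer loop: expansion, condensation and stopping rules.

One cycle: solve the weight subproblem on the current (expanded) grid, drop
points whose weight falls below ``max(lam) * delta_lambda``, re-solve on
the surviving points (this second solve defines the cycle's log-likelihood
and, at exit, the final estimate), then surround each survivor with up to
2Q daughter points at distance ``eps * (b - a)`` along each axis.  When the
log-likelihood gain of a cycle drops below ``delta_L`` the perturbation
size ``eps`` is halved; once ``eps`` reaches ``delta_e`` the current
estimate is accepted if its log-likelihood moved less than ``delta_F``
since the last acceptance test, and otherwise ``eps`` resets and the search
continues.  Everything is deterministic: identical inputs give identical
traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Subject
from .domain import ParameterDomain
from .error_models import ErrorModel
from .likelihood import PredictionCache, psi_matrix
from .pdip import PDIPError, optimal_weights
from .pk import PKModelSpec

__all__ = ["ControlParams", "MixtureEstimate", "condense", "expand", "npag_fit"]

# Initialisation sentinels for the log-likelihood bookkeeping; any first
# cycle improves on them by construction.
_LOGLIKE_INIT = -1e30
_F0_INIT = 1e30


@dataclass(frozen=True)
class ControlParams:
    """Thresholds governing the outer loop.

    delta_L : log-likelihood gain below which eps is halved (primary test)
    delta_F : log-likelihood gain below which the estimate is accepted
              at minimum eps (secondary test)
    delta_e : floor of the eps schedule
    delta_D : minimum normalised-L1 distance between accepted grid points
    delta_lambda : condensation keeps weights above max(lam)*delta_lambda
    eps0 : initial (and reset) relative perturbation size
    """

    delta_L: float = 1e-4
    delta_F: float = 1e-2
    delta_e: float = 1e-4
    delta_D: float = 1e-4
    delta_lambda: float = 1e-3
    eps0: float = 0.2
    max_cycles: int = 1000
    pdip_tol: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("delta_L", "delta_F", "delta_e", "delta_D", "delta_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.eps0 < 1:
            raise ValueError("eps0 must be in (0, 1)")
        if self.max_cycles < 0:
            raise ValueError("max_cycles must be >= 0")


@dataclass
class MixtureEstimate:
    """A discrete mixing-distribution candidate: points, weights, fit state."""

    grid: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    cycle: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.grid = np.atleast_2d(np.asarray(self.grid, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.grid.shape[0],):
            raise ValueError("weights must match the number of grid points")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1) > 1e-8:
            raise ValueError("weights must be a probability vector")

    @property
    def n_support(self) -> int:
        return int(np.sum(self.weights > 1e-6))

    def support_dataframe(self, names: Sequence[str]) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, columns=list(names))
        df["weight"] = self.weights
        return df


def condense(grid: np.ndarray, weights: np.ndarray,
             delta_lambda: float) -> np.ndarray:
    """Keep the grid points whose weight exceeds ``max(weights)*delta_lambda``.

    Order is preserved; the maximum-weight point always survives, so the
    result is never empty for ``delta_lambda < 1``.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (grid.shape[0],):
        raise ValueError("weights must match the number of grid points")
    return grid[weights > weights.max() * delta_lambda]


def expand(grid: np.ndarray, eps: float, domain: ParameterDomain,
           delta_D: float) -> np.ndarray:
    """Add +/- eps*(b-a) daughters along each axis, with a proximity gate.

    The output starts with the input points.  For each parent and each
    dimension, the plus and then the minus daughter is appended if it stays
    inside the box and its minimum normalised-L1 distance to everything
    already accepted is at least ``delta_D``.  The order-dependence
    (earlier daughters can block later ones) is intentional and keeps the
    procedure deterministic.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if not (0 < eps < 1):
        raise ValueError("eps must be in (0, 1)")
    a, b = domain.lower, domain.upper
    span = domain.span
    step = eps * span
    out = list(grid)

    def min_norm_dist(p):
        arr = np.asarray(out)
        return np.min(np.sum(np.abs(p - arr) / span, axis=1))

    q = domain.ndim
    for parent in grid:
        for d in range(q):
            plus = parent.copy()
            plus[d] += step[d]
            if plus[d] <= b[d] and min_norm_dist(plus) >= delta_D:
                out.append(plus)
            minus = parent.copy()
            minus[d] -= step[d]
            if minus[d] >= a[d] and min_norm_dist(minus) >= delta_D:
                out.append(minus)
    return np.asarray(out)


def npag_fit(
    dataset: Sequence[Subject],
    model: PKModelSpec,
    error_model: ErrorModel,
    domain: ParameterDomain,
    controls: ControlParams,
    initial_grid: np.ndarray,
) -> tuple[MixtureEstimate, pd.DataFrame]:
    """Run the full adaptive-grid NPML estimation.

    Returns the final :class:`MixtureEstimate` and a per-cycle trace frame
    with columns ``cycle, K_expanded, K_condensed, log_likelihood, eps``.
    With ``max_cycles == 0`` the weights of the initial grid are returned
    unchanged (a pure weight solve); if the cycle cap is exceeded the last
    condensed estimate is returned with ``converged=False``.
    """
    phi = np.atleast_2d(np.asarray(initial_grid, dtype=float))
    if not np.all(domain.contains(phi)):
        raise ValueError("initial grid has points outside the domain")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")

    eps = controls.eps0
    log_like = _LOGLIKE_INIT
    f0 = _F0_INIT
    f1 = 2.0 * f0
    n_cycle = 0
    rows: list[dict] = []
    cache = PredictionCache(model)

    def solve(psi):
        # tolerate a solver that stalls a few digits short of the
        # certificate mid-run; the final estimate still reports its residual
        try:
            return optimal_weights(psi, tol=controls.pdip_tol)
        except PDIPError as exc:
            if exc.report is not None and exc.report.kkt_residual <= 1e-6:
                return exc.weights, exc.report
            raise

    while eps >= controls.delta_e or abs(f1 - f0) >= controls.delta_F:
        psi = psi_matrix(dataset, phi, model, error_model, cache=cache)
        lam, rep = solve(psi)
        if controls.max_cycles == 0:
            est = MixtureEstimate(phi, lam, rep.log_likelihood, 0, False)
            return est, pd.DataFrame(rows, columns=_TRACE_COLS)

        n_cycle += 1
        keep = lam > lam.max() * controls.delta_lambda
        phi_c = phi[keep]
        psi_c = psi.select_columns(keep)
        lam_c, rep_c = solve(psi_c)
        new_log_like = rep_c.log_likelihood
        rows.append({
            "cycle": n_cycle, "K_expanded": phi.shape[0],
            "K_condensed": phi_c.shape[0],
            "log_likelihood": new_log_like, "eps": eps,
        })

        if n_cycle > controls.max_cycles:
            est = MixtureEstimate(phi_c, lam_c, new_log_like, n_cycle, False)
            return est, pd.DataFrame(rows, columns=_TRACE_COLS)

        if abs(new_log_like - log_like) <= controls.delta_L and eps > controls.delta_e:
            eps = eps / 2.0

        if eps <= controls.delta_e:
            f1 = new_log_like
            if abs(f1 - f0) <= controls.delta_F:
                est = MixtureEstimate(phi_c, lam_c, f1, n_cycle, True)
                return est, pd.DataFrame(rows, columns=_TRACE_COLS)
            f0 = f1
            eps = controls.eps0

        phi = expand(phi_c, eps, domain, controls.delta_D)
        log_like = new_log_like

    # loop guard failed without an accept: return the last condensed state
    est = MixtureEstimate(phi_c, lam_c, new_log_like, n_cycle, True)
    return est, pd.DataFrame(rows, columns=_TRACE_COLS)


_TRACE_COLS = ["cycle", "K_expanded", "K_condensed", "log_likelihood", "eps"]
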