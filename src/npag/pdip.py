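"""Primal-dual interior-point solver for the NPML weight subproblem.

Given the Psi matrix on a fixed grid, the weights solve the convex problem

    maximize  sum_i log( (Psi @ lam)_i )   over the probability simplex.

The solver works on the equivalent unnormalised program

    minimize  N * sum(lam) - sum_i log((Psi @ lam)_i),   lam >= 0,

whose minimiser automatically satisfies ``sum(lam) == 1``: scaling lam by c
changes the objective by ``N*(c-1)*s - N*log(c)``, which is minimised at
``c = 1/s``.  Its KKT system is

    N*1 - Psi^T y - z = 0,   y_i = 1/(Psi lam)_i,
    lam >= 0, z >= 0, lam_k z_k = 0,

and dividing the first condition by N recovers the Lindsay first-order
characterisation of the NPML optimum: ``g_k = (1/N) sum_i Psi_ik / (Psi
lam)_i <= 1`` with equality on the support.  A damped (relaxed) Newton
method follows the central path ``lam_k z_k = mu`` with ``mu`` cut by 0.1
per iteration and a 0.99995 fraction-to-boundary rule; each step solves a
symmetric positive-definite system reduced to size min(K, N) (Woodbury
identity when the grid is larger than the population, which it always is
after expansion).  A fixed-active-set Newton polish runs after the
interior-point phase so the certificate reaches tight tolerances in double
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .likelihood import PsiMatrix

__all__ = ["optimal_weights", "mixture_loglik", "SolverReport", "PDIPError"]

_BOUNDARY_FRAC = 0.99995
_MU_SHRINK = 0.1


class PDIPError(RuntimeError):
    """Non-convergence; carries the last iterate and its residuals."""

    def __init__(self, msg, weights=None, report=None):
        super().__init__(msg)
        self.weights = weights
        self.report = report


@dataclass
class SolverReport:
    log_likelihood: float
    iterations: int
    kkt_residual: float
    duality_gap: float
    objective_trace: list[float] = field(default_factory=list)


def mixture_loglik(lam: np.ndarray, psi: PsiMatrix) -> float:
    """Log-likelihood sum_i log(sum_k lam_k Psi_ik), row-scale corrected."""
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (psi.n_points,):
        raise ValueError(
            f"weight length {lam.shape} does not match K={psi.n_points}"
        )
    mix = psi.values @ lam
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(mix)) + np.sum(psi.row_scale))


def _lindsay_residual(values: np.ndarray, lam: np.ndarray, tol: float) -> float:
    """max violation of g_k <= 1 (all k) and g_k >= 1 (k with lam_k > tol)."""
    n = values.shape[0]
    w = values @ lam
    g = values.T @ (1.0 / w) / n
    over = np.max(g) - 1.0
    on_support = lam > tol
    under = np.max(1.0 - g[on_support]) if np.any(on_support) else 0.0
    return max(over, under, 0.0)


def _solve_kkt(values, lam, z, y, rhs, jitter=0.0):
    """Solve (Psi^T diag(y^2) Psi + diag(z/lam)) dlam = rhs via min(K,N) side."""
    n, k = values.shape
    d = z / lam
    if k <= n:
        h = (values * (y * y)[:, None]).T @ values
        h[np.diag_indices_from(h)] += d + jitter
        return cho_solve(cho_factor(h, lower=True), rhs)
    dinv = lam / z
    b = values * dinv[None, :]
    s = b @ values.T
    s[np.diag_indices_from(s)] += (1.0 / y) ** 2 + jitter
    t = rhs * dinv
    u = values @ t
    v = cho_solve(cho_factor(s, lower=True), u)
    return t - dinv * (values.T @ v)


def _normalized_objective(values, lam):
    lam_hat = lam / lam.sum()
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(values @ lam_hat)))


def _polish(values: np.ndarray, lam: np.ndarray, tol: float) -> np.ndarray:
    """Active-set Newton refinement at mu = 0.

    Restricts to the detected support, takes damped Newton steps on the
    unnormalised program, and drops a support candidate whenever its
    weight is driven into the boundary; returns the iterate with the best
    full-problem Lindsay residual encountered.
    """
    n, _ = values.shape
    active = np.flatnonzero(lam > lam.max() * 1e-9)
    x = lam[active].copy()

    def embed(xa, act):
        out = np.zeros_like(lam)
        out[act] = np.maximum(xa, 0.0)
        s = out.sum()
        return out / s if s > 0 else out

    best_lam = embed(x, active)
    best_res = _lindsay_residual(values, best_lam, tol)
    for _ in range(60):
        if len(active) == 0:
            break
        sub = values[:, active]
        w = sub @ x
        if np.any(w <= 0):
            break
        y = 1.0 / w
        grad = n - sub.T @ y
        h = (sub * (y * y)[:, None]).T @ sub
        jitter = 1e-13 * max(h.diagonal().max(), 1.0)
        for _ in range(6):
            try:
                hj = h.copy()
                hj[np.diag_indices_from(hj)] += jitter
                step = cho_solve(cho_factor(hj, lower=True), grad)
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        else:
            break

        alpha, blocking = 1.0, None
        pos = step > 0  # x - alpha*step must stay > 0
        if np.any(pos):
            ratios = x[pos] / step[pos]
            jmin = np.argmin(ratios)
            if ratios[jmin] < alpha:
                alpha = 0.999 * ratios[jmin]
                blocking = np.flatnonzero(pos)[jmin]
        f0 = n * x.sum() - np.sum(np.log(w))
        accepted = False
        for _ in range(50):
            x_new = x - alpha * step
            w_new = sub @ x_new
            if np.all(x_new > 0) and np.all(w_new > 0):
                f_new = n * x_new.sum() - np.sum(np.log(w_new))
                if f_new <= f0 + 1e-12 * (1.0 + abs(f0)):
                    accepted = True
                    break
            alpha *= 0.5
        if not accepted:
            break
        x = x - alpha * step

        # retire candidates squeezed into the boundary
        floor = x.max() * 1e-14
        drop = x <= floor
        if blocking is not None:
            drop[blocking] = drop[blocking] or x[blocking] < x.max() * 1e-9
        if np.any(drop):
            active = active[~drop]
            x = x[~drop]

        cand = embed(x, active)
        res = _lindsay_residual(values, cand, tol)
        if res < best_res:
            best_res, best_lam = res, cand
        if best_res <= 0.1 * tol:
            break
        if np.max(np.abs(grad)) < 1e-14 * n:
            break
    return best_lam


def optimal_weights(
    psi: PsiMatrix,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, SolverReport]:
    """Optimal simplex weights for a fixed grid, with a Lindsay certificate.

    Returns ``(lam, report)`` where ``lam`` sums to one and satisfies
    ``g_k <= 1 + tol`` for every column and ``g_k >= 1 - tol`` on the
    support (``lam_k > tol``); ``report.log_likelihood`` is the row-scale
    corrected mixture log-likelihood at ``lam``.

    Raises :class:`PDIPError` (carrying the last iterate) if the
    certificate is not met within ``max_iter`` interior-point iterations
    plus the active-set polish.
    """
    values = psi.values
    n, k = values.shape
    if k == 0:
        raise ValueError("Psi matrix has no columns")
    if k == 1:
        lam = np.ones(1)
        ll = mixture_loglik(lam, psi)
        return lam, SolverReport(ll, 0, 0.0, 0.0, [ll])

    lam = np.full(k, 1.0 / k)
    w = values @ lam
    y = 1.0 / w
    z = np.maximum(n - values.T @ y, 0.1 * n)
    trace = [_normalized_objective(values, lam)]

    best = (np.inf, lam / lam.sum())
    it = 0
    for it in range(1, max_iter + 1):
        w = values @ lam
        y = 1.0 / w
        grad = n - values.T @ y

        lam_hat = lam / lam.sum()
        res = _lindsay_residual(values, lam_hat, tol)
        if res < best[0]:
            best = (res, lam_hat.copy())
        if res <= tol:
            break

        mu = _MU_SHRINK * float(lam @ z) / k
        rhs = -grad + mu / lam
        try:
            dlam = _solve_kkt(values, lam, z, y, rhs)
        except np.linalg.LinAlgError:
            dlam = _solve_kkt(values, lam, z, y, rhs,
                              jitter=1e-10 * (1.0 + float(np.max(z / lam))))
        dz = mu / lam - z - (z / lam) * dlam

        alpha_p, alpha_d = 1.0, 1.0
        neg = dlam < 0
        if np.any(neg):
            alpha_p = min(1.0, _BOUNDARY_FRAC * np.min(-lam[neg] / dlam[neg]))
        neg = dz < 0
        if np.any(neg):
            alpha_d = min(1.0, _BOUNDARY_FRAC * np.min(-z[neg] / dz[neg]))

        # damp the primal step so the merit of the unnormalised program
        # never increases (relaxed Newton)
        f0 = n * lam.sum() - np.sum(np.log(w))
        alpha = alpha_p
        for _ in range(50):
            lam_new = lam + alpha * dlam
            w_new = values @ lam_new
            if np.all(w_new > 0):
                f_new = n * lam_new.sum() - np.sum(np.log(w_new))
                if f_new <= f0 + 1e-10 * (1.0 + abs(f0)):
                    break
            alpha *= 0.5
        lam = lam + alpha * dlam
        z = np.maximum(z + alpha_d * dz, 1e-300)
        trace.append(_normalized_objective(values, lam))
    else:
        it = max_iter

    lam_hat = lam / lam.sum()
    res = _lindsay_residual(values, lam_hat, tol)
    if res < best[0]:
        best = (res, lam_hat)

    if best[0] > tol:
        polished = _polish(values, best[1], tol)
        res_p = _lindsay_residual(values, polished, tol)
        if res_p < best[0]:
            best = (res_p, polished)

    res, lam_hat = best
    gap = float(lam @ np.maximum(z, 0.0))
    ll = mixture_loglik(lam_hat, psi)
    trace.append(_normalized_objective(values, lam_hat))
    report = SolverReport(ll, it, res, gap, trace)
    if res > tol:
        raise PDIPError(
            f"PDIP did not reach the Lindsay certificate: residual {res:.3e} "
            f"> tol {tol:.1e} after {it} iterations (N={n}, K={k})",
            weights=lam_hat,
            report=report,
        )
    return lam_hat, report
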