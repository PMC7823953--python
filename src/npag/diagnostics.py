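"""Post-fit diagnostics for a discrete mixing-distribution estimate.

The central object is the directional (Gateaux) derivative of the
log-likelihood functional toward a point mass at theta,

    D(theta, F) = sum_i p(Y_i | theta) / p(Y_i | F)  -  N,

which is <= 0 everywhere on Theta exactly when F is the global NPML
optimum, equals 0 at every support point of the optimum, and whose maximum
over Theta bounds the log-likelihood shortfall of F from the optimum.
Evaluating it over a multistart search yields a practical global-optimality
certificate for a finished fit.

Also here: per-subject empirical-Bayes posteriors over the support points
(the discrete estimate acting as prior) and the two standard
predicted-vs-observed outputs — population predictions (weight-averaged
profiles) and Bayesian predictions (profile at the posterior-mean
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .adaptive import MixtureEstimate
from .data import Subject
from .domain import ParameterDomain
from .error_models import ErrorModel
from .faure import uniform_grid
from .likelihood import psi_matrix, subject_log_density
from .pk import PKModelSpec

__all__ = [
    "OptimalityReport",
    "directional_derivative",
    "optimality_check",
    "posterior_weights",
    "posterior_mean",
    "predictions",
    "prediction_table",
]


@dataclass(frozen=True)
class OptimalityReport:
    d_max: float
    argmax_theta: np.ndarray
    loglik_gap_bound: float
    n_starts: int

    def __post_init__(self) -> None:
        assert self.loglik_gap_bound == max(self.d_max, 0.0)


def _mixture_logdens(estimate, dataset, model, error_model) -> np.ndarray:
    """log p(Y_i | F) per subject, computed through the scaled Psi matrix."""
    psi = psi_matrix(dataset, estimate.grid, model, error_model)
    with np.errstate(divide="ignore"):
        mix = psi.values @ estimate.weights
    if np.any(mix <= 0):
        bad = [dataset[i].id for i in np.flatnonzero(mix <= 0)]
        raise ValueError(f"estimate assigns zero density to subjects {bad}")
    return np.log(mix) + psi.row_scale


def directional_derivative(
    theta: np.ndarray,
    estimate: MixtureEstimate,
    dataset: Sequence[Subject],
    model: PKModelSpec,
    error_model: ErrorModel,
    _log_p_mix: np.ndarray | None = None,
) -> float:
    """D(theta, F) = sum_i p(Y_i|theta)/p(Y_i|F) - N, evaluated in log space."""
    theta = np.asarray(theta, dtype=float)
    if _log_p_mix is None:
        _log_p_mix = _mixture_logdens(estimate, dataset, model, error_model)
    log_p_theta = np.array([
        subject_log_density(s, theta, model, error_model) for s in dataset
    ])
    # cap the log ratios so a grossly sub-optimal estimate yields a huge
    # finite D instead of overflowing (keeps numerical optimisers stable)
    ratios = np.exp(np.minimum(log_p_theta - _log_p_mix, 700.0 - np.log(len(dataset))))
    return float(np.sum(ratios) - len(dataset))


def optimality_check(
    estimate: MixtureEstimate,
    dataset: Sequence[Subject],
    model: PKModelSpec,
    error_model: ErrorModel,
    domain: ParameterDomain,
    n_starts: int = 50,
    seed: int = 0,
) -> OptimalityReport:
    """Multistart bounded maximisation of D(theta, F) over Theta.

    Starts are the current support points plus ``n_starts`` seeded uniform
    points; each runs a bounded quasi-Newton ascent.  ``d_max`` is the best
    value found and ``loglik_gap_bound = max(d_max, 0)`` bounds how far the
    estimate's log-likelihood can lie below the global NPML optimum.  With
    ``n_starts=0`` only the support points are evaluated (no search).
    """
    log_p_mix = _mixture_logdens(estimate, dataset, model, error_model)

    def neg_d(theta):
        if not np.all(np.isfinite(theta)):
            return np.inf
        return -directional_derivative(
            theta, estimate, dataset, model, error_model, _log_p_mix=log_p_mix
        )

    support_vals = [-neg_d(p) for p in estimate.grid]
    d_best = max(support_vals)
    theta_best = estimate.grid[int(np.argmax(support_vals))].copy()

    if n_starts > 0:
        starts = list(estimate.grid) + list(uniform_grid(n_starts, domain, seed))
        bounds = list(zip(domain.lower, domain.upper))
        for x0 in starts:
            res = minimize(neg_d, x0, method="L-BFGS-B", bounds=bounds)
            if -res.fun > d_best and np.all(domain.contains(res.x)):
                d_best = float(-res.fun)
                theta_best = res.x.copy()

    return OptimalityReport(
        d_max=float(d_best),
        argmax_theta=theta_best,
        loglik_gap_bound=max(float(d_best), 0.0),
        n_starts=n_starts,
    )


def posterior_weights(
    subject: Subject,
    estimate: MixtureEstimate,
    model: PKModelSpec,
    error_model: ErrorModel,
) -> np.ndarray:
    """Empirical-Bayes posterior over support points: w_k prop lam_k p(Y|phi_k)."""
    psi = psi_matrix([subject], estimate.grid, model, error_model)
    with np.errstate(divide="ignore"):
        log_w = np.log(estimate.weights) + np.log(psi.values[0])
    if np.all(np.isinf(log_w)):
        raise ValueError(f"subject {subject.id!r} unexplainable under the estimate")
    w = np.exp(log_w - logsumexp(log_w))
    return w / w.sum()


def posterior_mean(
    subject: Subject,
    estimate: MixtureEstimate,
    model: PKModelSpec,
    error_model: ErrorModel,
) -> np.ndarray:
    """Posterior-mean parameter vector sum_k w_k phi_k."""
    w = posterior_weights(subject, estimate, model, error_model)
    return w @ estimate.grid


def predictions(
    subject: Subject,
    estimate: MixtureEstimate,
    model: PKModelSpec,
    mode: str = "population",
    error_model: ErrorModel | None = None,
) -> np.ndarray:
    """Predicted concentrations at the subject's observation times.

    ``population``: the weight-averaged profile over all support points.
    ``bayesian``: the profile at the subject's posterior-mean parameters
    (requires ``error_model`` to form the posterior).
    """
    obs_points = [(o.time, o.output_index) for o in subject.observations]
    if mode == "population":
        per_point = np.asarray(model.predict(estimate.grid, subject.doses, obs_points))
        return estimate.weights @ per_point
    if mode == "bayesian":
        if error_model is None:
            raise ValueError("bayesian predictions require an error model")
        theta_bar = posterior_mean(subject, estimate, model, error_model)
        return np.asarray(
            model.predict(theta_bar[None, :], subject.doses, obs_points)
        )[0]
    raise ValueError(f"unknown mode {mode!r}")


def prediction_table(
    dataset: Sequence[Subject],
    estimate: MixtureEstimate,
    model: PKModelSpec,
    error_model: ErrorModel,
) -> pd.DataFrame:
    """Tidy predicted-vs-observed frame for every subject and observation."""
    rows = []
    for s in dataset:
        pop = predictions(s, estimate, model, "population")
        bay = predictions(s, estimate, model, "bayesian", error_model)
        for o, p, bp in zip(s.observations, pop, bay):
            rows.append({
                "id": s.id, "time": o.time, "output": o.output_index,
                "observed": o.value, "pred_population": p, "pred_bayesian": bp,
            })
    return pd.DataFrame(rows)
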