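"""Observation densities p(Y_i | theta) and the Psi matrix.

The Psi matrix is the N x K array of component likelihoods p(Y_i | phi_k)
— the only coupling between the pharmacokinetic layer and the mixture
optimizer.  Each subject's density is a product of independent Gaussian
residual terms over its observations, with the residual standard deviation
supplied by the error model.

Raw densities underflow double precision for realistic observation counts
(11 observations with sigma around 5 put log-densities near -40 per
subject, and far lower away from the optimum), so rows are stored scaled:
``values[i, k] = exp(logdensity(i, k) - row_scale[i])`` with the per-row
log constant kept alongside.  The NPML weight optimum is invariant to
positive per-row rescaling; the constants are added back to every reported
log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import Subject
from .error_models import ErrorModel, SigmaError
from .pk import PKModelSpec

__all__ = [
    "PsiMatrix",
    "PredictionCache",
    "subject_log_density",
    "psi_matrix",
    "EvaluationError",
    "UnexplainableSubjectError",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class EvaluationError(RuntimeError):
    """A model prediction or density evaluation failed for a subject."""


class UnexplainableSubjectError(RuntimeError):
    """A subject's density underflowed at every grid point."""


@dataclass(frozen=True)
class PsiMatrix:
    """Row-scaled component likelihoods.

    ``values`` is N x K nonnegative with each row's maximum equal to 1 (for
    rows scaled by their maximum); ``row_scale`` holds the log constants so
    the true log-density is ``log(values) + row_scale[:, None]``.
    """

    values: np.ndarray
    row_scale: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or self.row_scale.shape != (v.shape[0],):
            raise ValueError("values must be N x K with a length-N row_scale")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("Psi entries must be finite and nonnegative")
        if not np.all(v.max(axis=1) > 0):
            raise ValueError("every Psi row needs a positive entry")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def log_density(self) -> np.ndarray:
        """True per-entry log densities (rows can contain -inf)."""
        with np.errstate(divide="ignore"):
            return np.log(self.values) + self.row_scale[:, None]

    def select_columns(self, idx: np.ndarray) -> "PsiMatrix":
        sub = self.values[:, idx]
        # re-scale so the kept columns again have row maxima of 1
        m = sub.max(axis=1)
        if np.any(m <= 0):
            bad = np.flatnonzero(m <= 0)
            raise UnexplainableSubjectError(
                f"rows {bad.tolist()} lose all mass under column selection"
            )
        return PsiMatrix(sub / m[:, None], self.row_scale + np.log(m))


class PredictionCache:
    """Memoises forward-model predictions by (regimen, parameter vector).

    The adaptive grid revisits the same support points across many cycles
    (survivors are carried over and daughter positions repeat once eps
    stabilises), so caching prediction rows turns the per-cycle model cost
    into the cost of the genuinely new points only.
    """

    def __init__(self, model: PKModelSpec):
        self.model = model
        self._store: dict[tuple, dict[bytes, np.ndarray]] = {}

    def predict(self, grid: np.ndarray, doses, obs_points, regimen_key) -> np.ndarray:
        d = self._store.setdefault(regimen_key, {})
        keys = [np.ascontiguousarray(row).tobytes() for row in grid]
        missing = [i for i, k in enumerate(keys) if k not in d]
        if missing:
            fresh = np.asarray(
                self.model.predict(grid[missing], doses, obs_points)
            )
            for i, row in zip(missing, fresh):
                d[keys[i]] = row
        return np.array([d[k] for k in keys])


def _log_density_block(
    y: np.ndarray, preds: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Sum of Gaussian log terms over observations; preds/sigma (K, n_obs)."""
    z = (y[None, :] - preds) / sigma
    with np.errstate(over="ignore"):  # huge z**2 -> -inf log-density
        return np.sum(-0.5 * z * z - np.log(sigma) - 0.5 * _LOG2PI, axis=1)


def _subject_sigmas(
    subject: Subject, preds: np.ndarray, error_model: ErrorModel
) -> np.ndarray:
    """(K, n_obs) residual SDs for one subject given predictions."""
    n_obs = len(subject.observations)
    sigma = np.empty_like(preds)
    for j, obs in enumerate(subject.observations):
        coeffs = subject.coeffs_for(obs.output_index)
        try:
            sigma[:, j] = error_model.sigma(preds[:, j], obs.value, coeffs)
        except SigmaError as exc:
            raise SigmaError(
                f"subject {subject.id!r}, observation at t={obs.time}: {exc}"
            ) from exc
    assert sigma.shape == (preds.shape[0], n_obs)
    return sigma


def subject_log_density(
    subject: Subject,
    theta: np.ndarray,
    model: PKModelSpec,
    error_model: ErrorModel,
) -> float:
    """log p(Y_i | theta): independent diagonal-Gaussian residuals."""
    theta = np.asarray(theta, dtype=float)
    obs_points = [(o.time, o.output_index) for o in subject.observations]
    preds = np.asarray(model.predict(theta[None, :], subject.doses, obs_points))
    if not np.all(np.isfinite(preds)):
        raise EvaluationError(
            f"non-finite prediction for subject {subject.id!r} at theta={theta}"
        )
    y = np.array([o.value for o in subject.observations])
    sigma = _subject_sigmas(subject, preds, error_model)
    return float(_log_density_block(y, preds, sigma)[0])


def psi_matrix(
    dataset: Sequence[Subject],
    grid: np.ndarray,
    model: PKModelSpec,
    error_model: ErrorModel,
    cache: PredictionCache | None = None,
) -> PsiMatrix:
    """Assemble the N x K Psi matrix for a dataset on a support grid.

    Subjects sharing a dosing + sampling schedule are grouped so the
    forward model runs once per unique regimen per grid, which is the
    dominant cost at production grid sizes.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.shape[0] < 1:
        raise ValueError("grid must contain at least one point")
    n, k = len(dataset), grid.shape[0]
    if n == 0:
        raise ValueError("dataset is empty")

    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(dataset):
        groups.setdefault(s.regimen_key(), []).append(i)

    logdens = np.empty((n, k))
    for key, members in groups.items():
        rep = dataset[members[0]]
        obs_points = [(o.time, o.output_index) for o in rep.observations]
        if cache is not None:
            preds = cache.predict(grid, rep.doses, obs_points, key)
        else:
            preds = np.asarray(model.predict(grid, rep.doses, obs_points))
        if not np.all(np.isfinite(preds)):
            bad = np.flatnonzero(~np.all(np.isfinite(preds), axis=1))
            raise EvaluationError(
                f"non-finite predictions for subjects {[dataset[m].id for m in members]} "
                f"at grid rows {bad[:5].tolist()}"
            )
        for i in members:
            subj = dataset[i]
            y = np.array([o.value for o in subj.observations])
            sigma = _subject_sigmas(subj, preds, error_model)
            logdens[i] = _log_density_block(y, preds, sigma)

    row_scale = logdens.max(axis=1)
    dead = ~np.isfinite(row_scale)
    if np.any(dead):
        ids = [dataset[i].id for i in np.flatnonzero(dead)]
        raise UnexplainableSubjectError(
            f"subjects {ids} have zero likelihood at every grid point"
        )
    values = np.exp(logdens - row_scale[:, None])
    return PsiMatrix(values, row_scale)
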