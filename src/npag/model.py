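"""Model / Results interface over the adaptive-grid NPML machinery.

:class:`NPMLModel` bundles a dataset, a forward PK model, an error model
and the parameter search box; :meth:`NPMLModel.fit` runs the adaptive-grid
estimation and returns an :class:`NPMLResults` carrying the discrete
estimate, the per-cycle trace and the diagnostic methods (optimality
certificate, empirical-Bayes posteriors, predicted-vs-observed tables,
weighted marginals).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adaptive import ControlParams, MixtureEstimate, npag_fit
from .data import Subject, read_dataset
from .diagnostics import (
    OptimalityReport,
    optimality_check,
    posterior_mean,
    posterior_weights,
    prediction_table,
    predictions,
)
from .domain import ParameterDomain
from .error_models import ErrorModel
from .faure import faure_grid, uniform_grid
from .pk import PKModelSpec, ThreeCompartmentModel, get_model

__all__ = ["NPMLModel", "NPMLResults"]


class NPMLModel:
    """Nonparametric mixing-distribution model for a population PK dataset.

    Parameters
    ----------
    subjects : the dataset (dosing, observations, assay-error coefficients).
    domain : parameter hyper-rectangle; its names must match the forward
        model's parameter names.
    pk_model : forward model spec (default: built-in three-compartment).
    error_model : residual-error model (default: assay polynomial only).
    """

    def __init__(
        self,
        subjects: Sequence[Subject],
        domain: ParameterDomain,
        pk_model: PKModelSpec | str = ThreeCompartmentModel,
        error_model: ErrorModel = ErrorModel(),
    ):
        if isinstance(pk_model, str):
            pk_model = get_model(pk_model)
        if tuple(domain.names) != tuple(pk_model.parameter_names):
            raise ValueError(
                f"domain names {domain.names} must match model parameters "
                f"{pk_model.parameter_names}"
            )
        if not subjects:
            raise ValueError("dataset is empty")
        self.subjects = list(subjects)
        self.domain = domain
        self.pk_model = pk_model
        self.error_model = error_model

    @classmethod
    def from_csv(
        cls,
        path,
        domain: ParameterDomain,
        pk_model: PKModelSpec | str = ThreeCompartmentModel,
        error_model: ErrorModel = ErrorModel(),
    ) -> "NPMLModel":
        return cls(read_dataset(path), domain, pk_model, error_model)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def make_grid(self, n_points: int, kind: str = "faure",
                  seed: int = 0) -> np.ndarray:
        if kind == "faure":
            return faure_grid(n_points, self.domain)
        if kind == "uniform":
            return uniform_grid(n_points, self.domain, seed)
        raise ValueError(f"unknown grid kind {kind!r}")

    def fit(
        self,
        initial_grid: np.ndarray | int = 5003,
        grid_kind: str = "faure",
        grid_seed: int = 0,
        controls: ControlParams | None = None,
        error_model: ErrorModel | None = None,
    ) -> "NPMLResults":
        """Run the adaptive-grid estimation to convergence.

        ``initial_grid`` may be a point count (a grid of ``grid_kind`` is
        generated) or an explicit (K, Q) array, e.g. the support of a
        previous fit for warm starts.
        """
        if controls is None:
            controls = ControlParams()
        if np.isscalar(initial_grid):
            grid0 = self.make_grid(int(initial_grid), grid_kind, grid_seed)
        else:
            grid0 = np.atleast_2d(np.asarray(initial_grid, dtype=float))
        em = error_model if error_model is not None else self.error_model
        estimate, trace = npag_fit(
            self.subjects, self.pk_model, em, self.domain, controls, grid0
        )
        return NPMLResults(self, estimate, trace, controls, em)

    def fit_staged(
        self,
        stages: Sequence[ErrorModel],
        initial_grid: np.ndarray | int = 5003,
        grid_kind: str = "faure",
        grid_seed: int = 0,
        controls: ControlParams | None = None,
    ) -> "NPMLResults":
        """Sequential fits with a schedule of error models.

        Each stage's final support grid warm-starts the next stage — the
        standard model-development strategy of starting with an inflated
        assay error and stepping it down toward the believed truth.  The
        result of the last stage is returned with the concatenated trace.
        """
        if not stages:
            raise ValueError("need at least one stage")
        grid: np.ndarray | int = initial_grid
        traces = []
        res: NPMLResults | None = None
        for j, em in enumerate(stages):
            res = self.fit(grid, grid_kind, grid_seed, controls, error_model=em)
            t = res.trace.copy()
            t.insert(0, "stage", j + 1)
            traces.append(t)
            grid = res.estimate.grid
        res.trace = pd.concat(traces, ignore_index=True)
        return res


class NPMLResults:
    """Fitted discrete mixing distribution plus diagnostics.

    Attributes
    ----------
    estimate : the final support points, weights and log-likelihood.
    trace : per-cycle frame (cycle, K_expanded, K_condensed,
        log_likelihood, eps).
    """

    def __init__(self, model: NPMLModel, estimate: MixtureEstimate,
                 trace: pd.DataFrame, controls: ControlParams,
                 error_model: ErrorModel):
        self.model = model
        self.estimate = estimate
        self.trace = trace
        self.controls = controls
        self.error_model = error_model
        self._optimality: OptimalityReport | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def llf(self) -> float:
        """Final mixture log-likelihood."""
        return self.estimate.log_likelihood

    @property
    def weights(self) -> np.ndarray:
        return self.estimate.weights

    @property
    def support_points(self) -> np.ndarray:
        return self.estimate.grid

    @property
    def n_support(self) -> int:
        """Support points carrying weight above 1e-6."""
        return self.estimate.n_support

    @property
    def converged(self) -> bool:
        return self.estimate.converged

    @property
    def cycles(self) -> int:
        return self.estimate.cycle

    @property
    def support(self) -> pd.DataFrame:
        """Support points and weights as a tidy frame."""
        return self.estimate.support_dataframe(self.model.domain.names)

    # -- moments of the mixing distribution ------------------------------
    def mixture_mean(self) -> pd.Series:
        m = self.weights @ self.support_points
        return pd.Series(m, index=list(self.model.domain.names))

    def mixture_cov(self) -> pd.DataFrame:
        m = self.weights @ self.support_points
        c = self.support_points - m
        cov = (c * self.weights[:, None]).T @ c
        names = list(self.model.domain.names)
        return pd.DataFrame(cov, index=names, columns=names)

    def marginal(self, name: str, bins: int = 40) -> pd.DataFrame:
        """Weighted histogram of one parameter's marginal mixing density."""
        q = list(self.model.domain.names).index(name)
        lo, hi = self.model.domain.lower[q], self.model.domain.upper[q]
        hist, edges = np.histogram(
            self.support_points[:, q], bins=bins, range=(lo, hi),
            weights=self.weights,
        )
        widths = np.diff(edges)
        return pd.DataFrame({
            "left": edges[:-1], "right": edges[1:],
            "mass": hist, "density": hist / widths,
        })

    # -- diagnostics ------------------------------------------------------
    def check_optimality(self, n_starts: int = 50, seed: int = 0) -> OptimalityReport:
        """Directional-derivative global-optimality certificate."""
        self._optimality = optimality_check(
            self.estimate, self.model.subjects, self.model.pk_model,
            self.error_model, self.model.domain, n_starts, seed,
        )
        return self._optimality

    def posterior(self, subject: Subject | str) -> np.ndarray:
        return posterior_weights(
            self._subject(subject), self.estimate, self.model.pk_model,
            self.error_model,
        )

    def posterior_parameter_mean(self, subject: Subject | str) -> pd.Series:
        theta = posterior_mean(
            self._subject(subject), self.estimate, self.model.pk_model,
            self.error_model,
        )
        return pd.Series(theta, index=list(self.model.domain.names))

    def predict(self, subject: Subject | str, mode: str = "population") -> np.ndarray:
        return predictions(
            self._subject(subject), self.estimate, self.model.pk_model,
            mode, self.error_model,
        )

    def prediction_table(self) -> pd.DataFrame:
        return prediction_table(
            self.model.subjects, self.estimate, self.model.pk_model,
            self.error_model,
        )

    def _subject(self, subject: Subject | str) -> Subject:
        if isinstance(subject, Subject):
            return subject
        for s in self.model.subjects:
            if s.id == subject:
                return s
        raise KeyError(f"no subject with id {subject!r}")

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted mixing distribution."""
        names = list(self.model.domain.names)
        mean = self.mixture_mean()
        sd = np.sqrt(np.diag(self.mixture_cov().to_numpy()))
        lines = [
            "Nonparametric ML mixing distribution (adaptive grid)",
            "=" * 56,
            f"Subjects:             {self.model.n_subjects}",
            f"Support points:       {self.n_support}"
            f"  (grid rows: {len(self.weights)})",
            f"Log-likelihood:       {self.llf:.4f}",
            f"Cycles:               {self.cycles}",
            f"Converged:            {self.converged}",
            f"Error model:          {self.error_model.mode}"
            + (f" (gamma={self.error_model.gamma:g})"
               if self.error_model.mode != "polynomial_only" else ""),
            "-" * 56,
            f"{'parameter':<12}{'mean':>12}{'sd':>12}",
        ]
        for j, n in enumerate(names):
            lines.append(f"{n:<12}{mean.iloc[j]:>12.4f}{sd[j]:>12.4f}")
        if self._optimality is not None:
            lines += [
                "-" * 56,
                f"D(F) certificate:     d_max={self._optimality.d_max:.3e}, "
                f"gap bound={self._optimality.loglik_gap_bound:.3e}",
            ]
        lines.append("=" * 56)
        return "\n".join(lines)

    def save(self, directory, seed: int | None = None) -> None:
        """Write run artifacts: support CSV, trace CSV and a JSON summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.support.to_csv(
            directory / "support.csv", index=False, float_format="%.17g"
        )
        self.trace.to_csv(
            directory / "trace.csv", index=False, float_format="%.17g"
        )
        summary = {
            "log_likelihood": self.llf,
            "cycles": self.cycles,
            "converged": bool(self.converged),
            "n_support": self.n_support,
            "n_subjects": self.model.n_subjects,
            "controls": {
                "delta_L": self.controls.delta_L,
                "delta_F": self.controls.delta_F,
                "delta_e": self.controls.delta_e,
                "delta_D": self.controls.delta_D,
                "delta_lambda": self.controls.delta_lambda,
                "eps0": self.controls.eps0,
                "max_cycles": self.controls.max_cycles,
            },
            "error_model": {
                "mode": self.error_model.mode,
                "gamma": self.error_model.gamma,
                "alpha_source": self.error_model.alpha_source,
            },
        }
        if seed is not None:
            summary["seed"] = seed
        if self._optimality is not None:
            summary["d_max"] = self._optimality.d_max
            summary["loglik_gap_bound"] = self._optimality.loglik_gap_bound
        (directory / "summary.json").write_text(
            json.dumps(summary, indent=2) + "\n"
        )

    def __repr__(self) -> str:
        return (
            f"<NPMLResults: {self.n_support} support points, "
            f"llf={self.llf:.3f}, converged={self.converged}>"
        )
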