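"""Residual-error (assay noise) models.

The standard deviation of an observation's Gaussian residual is built from
the assay error polynomial

    alpha = c0 + c1*f + c2*f**2 + c3*f**3

evaluated at the model-predicted concentration f (default) or, optionally,
at the observed concentration — a stabilising approximation that trades
strict maximum-likelihood validity for robustness when c0 = 0.  Four modes
combine alpha with the scalar variance factor gamma:

    polynomial_only   sigma = alpha
    multiplicative    sigma = gamma * alpha
    additive          sigma = sqrt(alpha**2 + gamma**2)
    constant          sigma = gamma
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorModel", "error_sd", "SigmaError"]

_MODES = ("polynomial_only", "multiplicative", "additive", "constant")


class SigmaError(ValueError):
    """Raised when an error model yields sigma <= 0 (infinite likelihood)."""


@dataclass(frozen=True)
class ErrorModel:
    mode: str = "polynomial_only"
    gamma: float = 1.0
    alpha_source: str = "predicted"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.alpha_source not in ("predicted", "observed"):
            raise ValueError("alpha_source must be 'predicted' or 'observed'")
        if self.mode != "polynomial_only" and self.gamma <= 0:
            raise ValueError("gamma must be > 0 for this mode")

    def sigma(self, predicted, observed, coeffs) -> np.ndarray:
        """Vectorised sigma; raises :class:`SigmaError` on sigma <= 0."""
        c0, c1, c2, c3 = coeffs
        if self.mode == "constant":
            return np.broadcast_to(
                float(self.gamma), np.shape(predicted)
            ).copy() if np.ndim(predicted) else np.float64(self.gamma)
        f = np.asarray(observed if self.alpha_source == "observed" else predicted,
                       dtype=float)
        alpha = c0 + f * (c1 + f * (c2 + f * c3))
        if self.mode == "polynomial_only":
            sigma = alpha
        elif self.mode == "multiplicative":
            sigma = self.gamma * alpha
        else:  # additive
            sigma = np.sqrt(alpha**2 + self.gamma**2)
        if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
            raise SigmaError(
                f"error model {self.mode!r} produced sigma <= 0 (or non-finite); "
                f"check the assay polynomial {coeffs} against the "
                f"{self.alpha_source} concentrations"
            )
        return sigma


def error_sd(predicted: float, observed: float, error_model: ErrorModel,
             coeffs) -> float:
    """Scalar residual standard deviation for one observation."""
    s = error_model.sigma(np.float64(predicted), np.float64(observed), coeffs)
    return float(s)
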