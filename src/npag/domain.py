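"""The parameter search space: a bounded hyper-rectangle in R^Q."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParameterDomain"]


@dataclass(frozen=True)
class ParameterDomain:
    """Hyper-rectangle Theta = [a1,b1] x ... x [aQ,bQ] with named axes."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, names, lower, upper):
        names = tuple(names)
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if len(names) == 0:
            raise ValueError("domain needs at least one parameter")
        if lower.shape != (len(names),) or upper.shape != (len(names),):
            raise ValueError("bounds must match the number of names")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        lower.flags.writeable = False
        upper.flags.writeable = False

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of rows of ``points`` lying inside the box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all(
            (pts >= self.lower - atol) & (pts <= self.upper + atol), axis=1
        )

    def clip(self, points: np.ndarray) -> np.ndarray:
        return np.clip(points, self.lower, self.upper)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Affinely map points in [0,1]^Q onto the box."""
        return self.lower + np.asarray(u, dtype=float) * self.span

    @classmethod
    def from_dict(cls, bounds: dict[str, tuple[float, float]]) -> "ParameterDomain":
        names = list(bounds)
        lo = [bounds[n][0] for n in names]
        hi = [bounds[n][1] for n in names]
        return cls(names, lo, hi)
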