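"""Initial support grids: Faure low-discrepancy sequences and uniform draws.

The adaptive-grid search is seeded with a space-filling set of candidate
support points in the parameter box Theta.  The default is the Faure
sequence — a (0, s)-sequence in the smallest prime base >= Q — whose 1-D
projections are van der Corput sequences and which covers a hypercube far
more evenly than i.i.d. uniform points of the same size.  Seeded uniform
grids and user-supplied point files are the alternatives.
"""

from __future__ import annotations

import numpy as np

from .domain import ParameterDomain

__all__ = ["faure_grid", "uniform_grid", "FAURE_LADDER", "smallest_prime_geq"]

# Customary grid sizes, kept as named presets for convenience; any size works.
FAURE_LADDER = (2129, 5003, 10007, 20011, 40009, 80021)


def smallest_prime_geq(q: int) -> int:
    """Smallest prime >= q (>= 2); the Faure base for dimension q."""
    n = max(2, int(q))
    while True:
        if all(n % p for p in range(2, int(n**0.5) + 1)):
            return n
        n += 1


def _faure_unit(n_points: int, dim: int, skip: int) -> np.ndarray:
    """First ``n_points`` Faure points (after ``skip``) in [0,1)^dim.

    Point j uses the base-b digit expansion of the integer index
    ``skip + 1 + j``; dimension d applies the (d-1)-th power of the Pascal
    matrix mod b to the digit vector before the radical inverse.  Indexing
    starts at 1 so the points stay strictly inside the open cube.
    """
    base = smallest_prime_geq(dim)
    idx = np.arange(skip + 1, skip + n_points + 1, dtype=np.int64)
    n_digits = 1
    while base ** n_digits <= idx[-1]:
        n_digits += 1

    # digits[j, r] = r-th base-b digit (least significant first) of idx[j]
    digits = np.empty((n_points, n_digits), dtype=np.int64)
    rem = idx.copy()
    for r in range(n_digits):
        digits[:, r] = rem % base
        rem //= base

    # Pascal (upper-triangular binomial) matrix mod base: P[r, c] = C(c, r)
    pascal = np.zeros((n_digits, n_digits), dtype=np.int64)
    pascal[0, :] = 1
    for r in range(1, n_digits):
        for c in range(r, n_digits):
            pascal[r, c] = (pascal[r - 1, c - 1] + pascal[r, c - 1]) % base

    weights = base ** -(np.arange(1, n_digits + 1, dtype=float))
    out = np.empty((n_points, dim))
    d = digits
    for j in range(dim):
        out[:, j] = (d % base) @ weights
        if j < dim - 1:
            d = d @ pascal.T % base
    return out


def faure_grid(
    n_points: int,
    domain: ParameterDomain,
    skip: int | None = None,
) -> np.ndarray:
    """Faure low-discrepancy grid of ``n_points`` support points in Theta.

    Parameters
    ----------
    n_points : number of points (any positive integer; see ``FAURE_LADDER``
        for the customary sizes).
    domain : the parameter hyper-rectangle.
    skip : number of initial sequence terms to drop.  Default ``base**4 - 1``,
        the usual burn-in that avoids the degenerate early terms; pass 0 for
        the raw sequence.

    Returns
    -------
    (n_points, Q) array of points strictly inside the box.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    q = domain.ndim
    if skip is None:
        skip = smallest_prime_geq(q) ** 4 - 1
    return domain.from_unit(_faure_unit(n_points, q, skip))


def uniform_grid(n_points: int, domain: ParameterDomain, seed: int) -> np.ndarray:
    """Seeded i.i.d. uniform grid on Theta; reproducible by seed."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    return domain.from_unit(rng.random((n_points, domain.ndim)))
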