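"""Clamped B-spline bases for age-varying location and scale curves.

The aging-trajectory model represents both the location (median) and the
log-scale of a Laplace law as B-splines of age with a small number of
control points.  The basis here is clamped at the ends of the age domain,
so the basis functions are nonnegative and form a partition of unity at
every age inside the domain; a constant coefficient vector therefore
evaluates to that constant everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

#: default control-point anchor ages (years), equally spaced by 18
DEFAULT_CONTROL_AGES: tuple[float, ...] = (27.0, 45.0, 63.0, 81.0)

#: default age domain (years) — the cohort inclusion bounds
DEFAULT_AGE_DOMAIN: tuple[float, float] = (18.0, 90.0)


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped B-spline basis on an age domain.

    Attributes
    ----------
    degree : int
        Polynomial degree of the basis (cubic by default in the model).
    control_ages : tuple of float
        Anchor ages of the control points, strictly increasing.  One basis
        function (hence one coefficient) exists per control age.
    domain : (float, float)
        Age interval on which the basis is a nonnegative partition of unity.
    knots : numpy.ndarray
        Full clamped knot vector (endpoint multiplicity ``degree + 1``).
    """

    degree: int
    control_ages: tuple[float, ...]
    domain: tuple[float, float]
    knots: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.control_ages)

    def design_matrix(self, ages, *, extrapolate: bool = False) -> np.ndarray:
        """Evaluate all basis functions at ``ages``.

        Returns an ``(n_ages, n_basis)`` dense matrix whose rows sum to 1
        for ages inside the domain.
        """
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        if not extrapolate:
            lo, hi = self.domain
            if np.any(a < lo) or np.any(a > hi):
                raise ValueError(
                    f"ages outside basis domain [{lo}, {hi}]; "
                    "pass extrapolate=True to evaluate anyway"
                )
        return BSpline.design_matrix(
            a, self.knots, self.degree, extrapolate=True
        ).toarray()

    def evaluate(self, coefficients, ages, *, extrapolate: bool = False) -> np.ndarray:
        """Evaluate the spline with the given coefficient vector."""
        c = np.asarray(coefficients, dtype=float)
        if c.shape != (self.n_basis,):
            raise ValueError(
                f"expected {self.n_basis} coefficients, got shape {c.shape}"
            )
        return self.design_matrix(ages, extrapolate=extrapolate) @ c


def build_basis(
    control_ages=DEFAULT_CONTROL_AGES,
    degree: int = 3,
    domain: tuple[float, float] = DEFAULT_AGE_DOMAIN,
) -> BSplineBasis:
    """Construct a clamped basis with one function per control age.

    The knot vector is clamped at the domain ends with multiplicity
    ``degree + 1``.  The ``n - degree - 1`` interior knots are derived from
    the interior control ages: for ``degree >= 1``, interior knot *j* is the
    mean of ``degree`` consecutive control ages starting at ``j + 1`` (for
    degree 1 this places a knot at each interior control age); for degree 0
    the interior knots are the midpoints between consecutive control ages,
    so the basis reduces to bin indicators centred on the control ages.

    With the default four control points and a cubic degree there are no
    interior knots and the basis is the Bernstein basis on the domain; the
    control ages then act purely as anchors for interpreting coefficients.
    """
    ages = tuple(float(x) for x in control_ages)
    n = len(ages)
    if n < degree + 1:
        raise ValueError(
            f"need at least degree+1={degree + 1} control points, got {n}"
        )
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("control ages must be strictly increasing")
    lo, hi = float(domain[0]), float(domain[1])
    if not (lo < hi):
        raise ValueError("domain must be a nonempty interval")
    if ages[0] < lo or ages[-1] > hi:
        raise ValueError("domain must contain all control ages")

    n_interior = n - degree - 1
    if degree == 0:
        interior = [(a + b) / 2.0 for a, b in zip(ages, ages[1:])][:n_interior]
    else:
        interior = [
            float(np.mean(ages[j + 1 : j + 1 + degree])) for j in range(n_interior)
        ]
    knots = np.concatenate(
        [np.full(degree + 1, lo), np.asarray(interior, dtype=float), np.full(degree + 1, hi)]
    )
    return BSplineBasis(degree=degree, control_ages=ages, domain=(lo, hi), knots=knots)
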