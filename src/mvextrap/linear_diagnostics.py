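"""Classical single-model regression diagnostics.

Hat matrix, leverage, Cook's distance, Mahalanobis distance and independent
variable hull (IVH) membership for an ordinary linear model.  These serve two
roles: standalone outlier/extrapolation diagnostics that need only the design
matrix, and the building block for the leverage-informed predictive-variance
cutoff used downstream.

For a design ``X`` (l rows, p columns including the intercept) the hat matrix
is ``H = X (X'X)^{-1} X'``; its diagonal entries ``h_ii`` are the leverages.
With an intercept present, leverage and the squared Mahalanobis distance of
the covariate part of a row are monotonically related:

    h_ii = 1/l + MD_i^2 / (l - 1)

IVH membership of a new point ``x0`` is the quadratic-form test
``x0'(X'X)^{-1} x0 <= max_i h_ii``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from mvextrap._errors import DimensionError, SingularCovarianceError, SingularDesignError

# Relative singular-value threshold below which a design is declared rank deficient.
RANK_RTOL = 1e-10


@dataclass
class DesignMatrix:
    """A fully observed design matrix for l locations.

    Parameters
    ----------
    values
        Array of shape (l, p).  If ``has_intercept`` the first column must be
        all ones.
    has_intercept
        Whether the first column is a constant intercept column.
    column_names
        Optional names, length p (the intercept column included).
    """

    values: np.ndarray
    has_intercept: bool = True
    column_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("design must be a 2-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix may not contain missing/non-finite entries")
        if self.has_intercept and not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("has_intercept=True but first column is not all ones")
        if self.column_names is not None and len(self.column_names) != self.values.shape[1]:
            raise DimensionError("column_names length does not match column count")
        if self.column_names is None:
            q = self.values.shape[1] - (1 if self.has_intercept else 0)
            self.column_names = (["intercept"] if self.has_intercept else []) + [
                f"x{j + 1}" for j in range(q)
            ]

    @classmethod
    def from_covariates(
        cls, covariates: np.ndarray, column_names: Sequence[str] | None = None
    ) -> "DesignMatrix":
        """Prepend an intercept column to a raw covariate matrix."""
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        ones = np.ones((covariates.shape[0], 1))
        names = None
        if column_names is not None:
            names = ["intercept", *column_names]
        return cls(np.hstack([ones, covariates]), has_intercept=True, column_names=names)

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def covariates(self) -> np.ndarray:
        """The non-intercept columns."""
        return self.values[:, 1:] if self.has_intercept else self.values


@dataclass
class LeverageResult:
    """Leverages, their maximum, and squared Mahalanobis distances."""

    leverages: np.ndarray
    h_max: float
    mahalanobis_sq: np.ndarray | None


@dataclass
class CooksResult:
    """Cook's distances with the studentized residuals and residual variance."""

    distances: np.ndarray
    studentized_residuals: np.ndarray
    s_sq: float


def _check_shape(design: DesignMatrix) -> None:
    l, p = design.values.shape
    if l <= p:
        raise DimensionError(
            f"diagnostics need more rows than columns (got l={l}, p={p})"
        )


def _check_rank(design: DesignMatrix) -> None:
    """Raise SingularDesignError naming offending columns if X is rank deficient."""
    X = design.values
    sv = linalg.svdvals(X)
    rank = int(np.sum(sv > RANK_RTOL * sv[0]))
    if rank == X.shape[1]:
        return
    # pivoted QR: columns beyond the numerical rank are the dependent ones
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    bad = sorted(piv[rank:])
    names = [str(design.column_names[j]) for j in bad]
    raise SingularDesignError(
        f"design is rank deficient (rank {rank} < {X.shape[1]}); "
        f"linearly dependent columns: {names}"
    )


def _qr(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    _check_shape(design)
    _check_rank(design)
    Q, R = linalg.qr(design.values, mode="economic")
    return Q, R


def hat_matrix(design: DesignMatrix) -> np.ndarray:
    """Projection matrix H = X(X'X)^{-1}X', computed via a thin QR factorization.

    H is symmetric and idempotent with trace equal to the column count of X.
    """
    Q, _ = _qr(design)
    return Q @ Q.T


def leverages(design: DesignMatrix) -> LeverageResult:
    """Hat-matrix diagonal, its maximum, and squared Mahalanobis distances.

    Mahalanobis distances use the intercept-excluded covariate columns, the
    sample mean, and the sample covariance with denominator l-1; they are
    computed only when the design carries an intercept (``mahalanobis_sq`` is
    None otherwise).  With an intercept, ``h_ii = 1/l + MD_i^2/(l-1)``.
    """
    Q, _ = _qr(design)
    h = np.einsum("ij,ij->i", Q, Q)
    md2 = None
    if design.has_intercept:
        Z = design.covariates
        if Z.shape[1] > 0:
            centered = Z - Z.mean(axis=0)
            S = np.cov(Z, rowvar=False, ddof=1)
            S = np.atleast_2d(S)
            try:
                cf = linalg.cho_factor(S)
            except linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    "sample covariance of the covariates is singular"
                ) from exc
            md2 = np.einsum("ij,ij->i", centered, linalg.cho_solve(cf, centered.T).T)
        else:
            md2 = np.zeros(design.n_locations)
    return LeverageResult(leverages=h, h_max=float(h.max()), mahalanobis_sq=md2)


def cooks_distance(design: DesignMatrix, response: np.ndarray) -> CooksResult:
    """Cook's distance for each location of a univariate linear fit.

    Uses the leverage / studentized-residual form
    ``D_i = t_i^2 * h_ii / (p * (1 - h_ii))`` which equals the delete-one
    coefficient-shift form.  A location with leverage exactly 1 is reported
    with infinite distance rather than raising.
    """
    y = np.asarray(response, dtype=float).ravel()
    l, p = design.values.shape
    if y.shape[0] != l:
        raise DimensionError("response length does not match design rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("response may not contain missing values")
    Q, _ = _qr(design)
    h = np.einsum("ij,ij->i", Q, Q)
    fitted = Q @ (Q.T @ y)
    resid = y - fitted
    s_sq = float(resid @ resid / (l - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(s_sq * (1.0 - h))
        t = np.where(denom > 0, resid / denom, 0.0)
        d = t**2 * h / (p * (1.0 - h))
    at_one = h > 1.0 - 1e-12
    d = np.where(np.isclose(resid, 0.0) & ~at_one, 0.0, d)
    d = np.where(at_one, np.inf, d)
    return CooksResult(distances=d, studentized_residuals=t, s_sq=s_sq)


def ivh_contains(design: DesignMatrix, x0: np.ndarray) -> tuple[bool, float]:
    """Test membership of ``x0`` in the independent variable hull.

    Returns ``(contained, margin)`` where ``margin = h_max - x0'(X'X)^{-1}x0``
    and containment is ``margin >= 0`` (boundary points are inside).  ``x0``
    must include the intercept entry when the design does.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.shape[0] != design.n_columns:
        raise DimensionError(
            f"x0 has length {x0.shape[0]}, design has {design.n_columns} columns"
        )
    Q, R = _qr(design)
    h = np.einsum("ij,ij->i", Q, Q)
    # quadratic form x0'(X'X)^{-1}x0 = ||R^{-T} x0||^2
    w = linalg.solve_triangular(R, x0, trans="T")
    quad = float(w @ w)
    margin = float(h.max()) - quad
    return bool(margin >= -1e-12), margin


def diagnostics_table(design: DesignMatrix, response: np.ndarray | None = None,
                      location_ids: Sequence | None = None):
    """Per-location diagnostics as a pandas DataFrame.

    Columns: location id, leverage, squared Mahalanobis distance, Cook's D
    (if a response is given), and IVH margin of each design row.
    """
    import pandas as pd

    lev = leverages(design)
    ids = list(location_ids) if location_ids is not None else list(range(design.n_locations))
    Q, R = _qr(design)
    W = linalg.solve_triangular(R, design.values.T, trans="T")
    quad = np.einsum("ji,ji->i", W, W)
    out = pd.DataFrame(
        {
            "location_id": ids,
            "leverage": lev.leverages,
            "mahalanobis_sq": lev.mahalanobis_sq if lev.mahalanobis_sq is not None else np.nan,
            "ivh_margin": lev.h_max - quad,
        }
    )
    if response is not None:
        out["cooks_d"] = cooks_distance(design, response).distances
    return out
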