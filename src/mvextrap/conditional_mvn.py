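"""Conditional multivariate-normal machinery.

Covariance partitioning and conditional moments, shared by the conditional
predictive-variance measure (CMVPV) and by the Gibbs sampler's augmentation of
partially observed response vectors.

For ``y ~ N(mu, Sigma)`` split into a target block (1) and a conditioning
block (2), the conditional distribution given ``y_2 = a`` is normal with

    mu_bar    = mu_1 + S12 S22^{-1} (a - mu_2)
    sigma_bar = S11  - S12 S22^{-1} S21

(the Schur complement).  Conditioning never increases variance: the diagonal
of ``sigma_bar`` is bounded by that of ``S11``, with equality iff S12 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from mvextrap._errors import DimensionError, SingularCovarianceError


@dataclass
class SigmaPartition:
    """The four blocks of a covariance matrix under a target/conditioning split."""

    s11: np.ndarray  # (t, t)
    s12: np.ndarray  # (t, c)
    s21: np.ndarray  # (c, t)
    s22: np.ndarray  # (c, c)
    target_index: tuple[int, ...]
    cond_indices: tuple[int, ...]


@dataclass
class ConditionalMoments:
    """Conditional mean and covariance of the target block."""

    mu_bar: np.ndarray
    sigma_bar: np.ndarray


def _as_index_tuple(idx: Sequence[int] | int) -> tuple[int, ...]:
    if np.isscalar(idx):
        return (int(idx),)
    return tuple(int(i) for i in idx)


def partition_sigma(
    sigma: np.ndarray, target: Sequence[int] | int, cond: Sequence[int] | int
) -> SigmaPartition:
    """Compartmentalize ``sigma`` into target/conditioning blocks.

    ``target`` and ``cond`` are disjoint index sets into the rows/columns of
    ``sigma``; the blocks reassemble to the original matrix under the induced
    permutation.  ``cond`` may be empty.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise DimensionError("sigma must be square")
    t = _as_index_tuple(target)
    c = _as_index_tuple(cond) if cond is not None else ()
    if len(t) == 0:
        raise DimensionError("target index set must be nonempty")
    if set(t) & set(c):
        raise DimensionError(f"target and conditioning sets overlap: {set(t) & set(c)}")
    n = sigma.shape[0]
    for i in (*t, *c):
        if not 0 <= i < n:
            raise DimensionError(f"index {i} out of range for {n}x{n} sigma")
    ti = np.asarray(t, dtype=int)
    ci = np.asarray(c, dtype=int)
    return SigmaPartition(
        s11=sigma[np.ix_(ti, ti)],
        s12=sigma[np.ix_(ti, ci)],
        s21=sigma[np.ix_(ci, ti)],
        s22=sigma[np.ix_(ci, ci)],
        target_index=t,
        cond_indices=c,
    )


def conditional_coefficients(
    sigma: np.ndarray, target: Sequence[int] | int, cond: Sequence[int] | int
) -> tuple[np.ndarray, np.ndarray]:
    """Regression coefficients and Schur complement for a conditional MVN.

    Returns ``(C, sigma_bar)`` with ``C = S12 S22^{-1}`` (shape t x c) and
    ``sigma_bar = S11 - C S21``.  With an empty conditioning set, ``C`` has
    zero columns and ``sigma_bar = S11``.  The conditioning block is solved
    through a Cholesky factorization; a singular block raises
    SingularCovarianceError naming it.
    """
    part = partition_sigma(sigma, target, cond)
    if len(part.cond_indices) == 0:
        return np.zeros((len(part.target_index), 0)), part.s11.copy()
    try:
        cf = linalg.cho_factor(part.s22)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"conditioning block s22 (indices {part.cond_indices}) is singular"
        ) from exc
    C = linalg.cho_solve(cf, part.s21).T  # (t, c)
    sigma_bar = part.s11 - C @ part.s21
    return C, sigma_bar


def conditional_moments(
    mu: np.ndarray,
    sigma: np.ndarray,
    target: Sequence[int] | int,
    cond: Sequence[int] | int,
    a: np.ndarray | float | None = None,
) -> ConditionalMoments:
    """Moments of the target components given observed conditioning values ``a``.

    ``mu_bar`` is affine in ``a``; ``sigma_bar`` does not depend on ``a``.
    Conditioning on an empty set returns the marginal moments unchanged.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape[0] != sigma.shape[0]:
        raise DimensionError("mu length does not match sigma dimension")
    t = _as_index_tuple(target)
    c = _as_index_tuple(cond) if cond is not None else ()
    C, sigma_bar = conditional_coefficients(sigma, t, c)
    if len(c) == 0:
        return ConditionalMoments(mu_bar=mu[list(t)], sigma_bar=sigma_bar)
    a = np.atleast_1d(np.asarray(a, dtype=float)).ravel()
    if a.shape[0] != len(c):
        raise DimensionError("length of observed values does not match conditioning set")
    mu_bar = mu[list(t)] + C @ (a - mu[list(c)])
    return ConditionalMoments(mu_bar=mu_bar, sigma_bar=sigma_bar)
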