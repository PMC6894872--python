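"""Scalar extrapolation measures, cutoffs, and the extrapolation index.

A multivariate model yields a predictive *covariance matrix* per location
rather than the scalar variance the generalized independent variable hull is
defined from.  This module scalarizes those matrices:

* ``MVPV(tr)`` — trace of the predictive-mean covariance (A-optimality
  style; not scale-invariant);
* ``MVPV(D)`` — determinant (D-optimality style; rescaling every response by
  fixed positive constants multiplies all determinants by one common factor,
  so quantile/max-based identification is unchanged);
* ``CMVPV`` — predictive variance of a single target response conditioned on
  the location's other observed responses, with the residual-variance
  correction added uniformly so values are comparable across locations with
  different observation status.

A cutoff computed from observed-split values only (maximum,
leverage-informed maximum, or an empirical quantile — 0.99 and 0.95 are the
conventional levels) then classifies each prediction location: the binary
extrapolation index is ``e = 1`` iff the measure strictly exceeds the cutoff,
equivalently iff the relative measure ``R = v/k`` exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mvextrap._errors import DimensionError, MvextrapError
from mvextrap.conditional_mvn import conditional_coefficients
from mvextrap.linear_diagnostics import DesignMatrix, leverages
from mvextrap.mvn_gibbs import ModelData, PosteriorDraws, PredictiveVariance, predictive_variances

# Relative tolerance on negative eigenvalues before a matrix is declared indefinite.
PSD_RTOL = 1e-8


@dataclass
class MeasureVector:
    """Per-location scalar measure values with their observed/prediction split."""

    values: np.ndarray
    measure_kind: str  # mvpv_trace | mvpv_det | cmvpv
    split: np.ndarray  # per-location 'observed' / 'prediction'
    location_ids: list = field(default_factory=list)
    target_variable: int | None = None  # cmvpv only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.split = np.asarray(self.split, dtype=object)
        if self.values.shape != self.split.shape:
            raise DimensionError("values and split must have equal length")
        if np.any(self.values < -1e-12):
            raise ValueError("measure values must be non-negative")
        if not self.location_ids:
            self.location_ids = list(range(self.values.size))

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.split == "observed"]

    @property
    def prediction_values(self) -> np.ndarray:
        return self.values[self.split == "prediction"]


@dataclass
class Cutoff:
    """An extrapolation cutoff computed from observed-split measure values."""

    value: float
    rule: str  # max | leverage_max | quantile
    quantile_level: float | None = None
    removed_locations: list = field(default_factory=list)


@dataclass
class ExtrapolationReport:
    """Binary extrapolation index and relative measure for prediction locations."""

    location_ids: list
    values: np.ndarray
    cutoff: Cutoff
    index: np.ndarray  # 0/1
    relative: np.ndarray  # R = v / k
    measure_kind: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "location_id": self.location_ids,
                "measure_kind": self.measure_kind,
                "measure_value": self.values,
                "cutoff_rule": self.cutoff.rule,
                "cutoff_value": self.cutoff.value,
                "extrapolation_index": self.index,
                "relative_value": self.relative,
            }
        )


def _as_matrix(V: PredictiveVariance | np.ndarray) -> np.ndarray:
    M = V.V if isinstance(V, PredictiveVariance) else np.asarray(V, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError("predictive variance must be a square matrix")
    return M


def mvpv_trace(V: PredictiveVariance | np.ndarray) -> float:
    """Trace of the predictive-mean covariance matrix (sum of eigenvalues)."""
    M = _as_matrix(V)
    return float(np.trace(M))


def mvpv_det(V: PredictiveVariance | np.ndarray) -> float:
    """Determinant of the predictive-mean covariance matrix (product of eigenvalues).

    Computed from the eigendecomposition; eigenvalues within numerical noise
    of zero are clipped to zero, so a singular PSD matrix returns 0 exactly.
    A matrix indefinite beyond tolerance raises.
    """
    M = _as_matrix(V)
    eig = np.linalg.eigvalsh(0.5 * (M + M.T))
    scale = max(eig.max(), 0.0)
    if eig.min() < -PSD_RTOL * max(scale, 1e-300):
        raise MvextrapError(
            f"matrix is indefinite (min eigenvalue {eig.min():.3e}); not a covariance"
        )
    eig = np.clip(eig, 0.0, None)
    return float(np.prod(eig))


def cmvpv(
    draws: PosteriorDraws,
    x_i: np.ndarray,
    observed_values: np.ndarray,
    mask: np.ndarray,
    target: int,
) -> float:
    """Conditional predictive variance of one response at one location.

    Per retained draw a, the predictive mean ``mu = B^(a) x_i`` and covariance
    ``Sigma^(a)`` are partitioned on the target versus the location's observed
    companion variables; the conditional mean ``mu_bar`` and Schur complement
    ``sigma_bar`` are formed, and the measure is

        Var_a(mu_bar) + mean_a(sigma_bar)

    With an empty conditioning set this reduces to the marginal
    ``Var_a(mu_target) + mean_a(Sigma[target, target])`` — the second term is
    the residual-variance correction that keeps values comparable across
    locations regardless of how many companions were observed.
    """
    mask = np.asarray(mask, dtype=bool).ravel()
    observed_values = np.asarray(observed_values, dtype=float).ravel()
    n = draws.n_resp
    if mask.shape[0] != n or observed_values.shape[0] != n:
        raise DimensionError("observed_values/mask length must equal the response count")
    if not 0 <= target < n:
        raise DimensionError(f"target index {target} out of range")
    if mask[target]:
        raise MvextrapError("target variable is observed at this location; nothing to predict")
    cond = [j for j in range(n) if mask[j]]
    x_i = np.asarray(x_i, dtype=float).ravel()
    mu = draws.B_draws @ x_i  # (A, n)
    A = mu.shape[0]
    mu_bar = np.empty(A)
    sbar = np.empty(A)
    a_obs = observed_values[cond]
    for a in range(A):
        C, sb = conditional_coefficients(draws.Sigma_draws[a], [target], cond)
        sbar[a] = sb[0, 0]
        if cond:
            mu_bar[a] = mu[a, target] + C[0] @ (a_obs - mu[a, cond])
        else:
            mu_bar[a] = mu[a, target]
    return float(np.var(mu_bar, ddof=1) + sbar.mean())


def _cmvpv_all(draws: PosteriorDraws, data: ModelData, target: int) -> np.ndarray:
    """CMVPV for every location of ``data`` whose target response is unobserved.

    Vectorized over locations sharing a missingness pattern; locations where
    the target is itself observed are conditioned on their *other* observed
    companions (their CMVPV quantifies how predictable the target would be).
    Returns an array over all locations.
    """
    X = data.design.values
    n = data.n_resp
    A = draws.n_draws
    mu = np.einsum("anp,mp->man", draws.B_draws, X)  # (m, A, n)
    out = np.empty(data.n_locations)
    # conditioning set per row: observed companions excluding the target
    cond_mask = data.mask.copy()
    cond_mask[:, target] = False
    patterns: dict[tuple[bool, ...], list[int]] = {}
    for i, row in enumerate(cond_mask):
        patterns.setdefault(tuple(bool(v) for v in row), []).append(i)
    for key, rows in patterns.items():
        rows = np.asarray(rows, dtype=int)
        cond = [j for j, v in enumerate(key) if v]
        Cs = np.empty((A, len(cond)))
        sb = np.empty(A)
        for a in range(A):
            C, s = conditional_coefficients(draws.Sigma_draws[a], [target], cond)
            Cs[a] = C[0]
            sb[a] = s[0, 0]
        mu_t = mu[rows][:, :, target]  # (m, A)
        if cond:
            dev = data.responses[np.ix_(rows, cond)][:, None, :] - mu[rows][:, :, cond]
            mu_bar = mu_t + np.einsum("mac,ac->ma", dev, Cs)
        else:
            mu_bar = mu_t
        out[rows] = mu_bar.var(axis=1, ddof=1) + sb.mean()
    return out


def compute_measures(
    draws: PosteriorDraws,
    data: ModelData,
    kind: str = "mvpv_det",
    target: int | None = None,
) -> MeasureVector:
    """Per-location scalar measure over all locations of ``data``.

    ``kind`` is one of ``mvpv_trace``, ``mvpv_det``, ``cmvpv`` (the latter
    requires ``target``, the index of the response variable of interest).
    """
    split = data.split
    if kind in ("mvpv_trace", "mvpv_det"):
        Vs = predictive_variances(draws, data.design.values)
        if kind == "mvpv_trace":
            vals = np.trace(Vs, axis1=1, axis2=2)
        else:
            eig = np.linalg.eigvalsh(0.5 * (Vs + np.transpose(Vs, (0, 2, 1))))
            vals = np.prod(np.clip(eig, 0.0, None), axis=1)
        return MeasureVector(values=vals, measure_kind=kind, split=split,
                             location_ids=list(data.location_ids))
    if kind == "cmvpv":
        if target is None:
            raise ValueError("cmvpv requires a target response index")
        vals = _cmvpv_all(draws, data, target)
        # for a single-variable measure the split is target-driven: locations
        # where the target was sampled form the cutoff pool, every location
        # missing it is a prediction to classify
        split = np.where(data.mask[:, target], "observed", "prediction").astype(object)
        return MeasureVector(values=vals, measure_kind=kind, split=split,
                             location_ids=list(data.location_ids), target_variable=target)
    raise ValueError(f"unknown measure kind: {kind!r}")


def cutoff_max(observed_values: MeasureVector) -> Cutoff:
    """Maximum of the observed-split measure values (the classical hull boundary)."""
    v = observed_values.observed_values
    if v.size == 0:
        raise MvextrapError("observed split is empty; cannot form a cutoff")
    return Cutoff(value=float(v.max()), rule="max")


def cutoff_leverage(
    observed_values: MeasureVector,
    design: DesignMatrix,
    leverage_multiplier: float = 2.0,
) -> Cutoff:
    """Maximum over observed values after dropping high-leverage locations.

    A location is deemed potentially influential — from the covariates alone —
    when its leverage exceeds ``leverage_multiplier * p / l`` (the classical
    rule of thumb with multiplier 2).  The design rows must align with the
    observed-split locations.
    """
    v = observed_values.observed_values
    obs_ids = [i for i, s in zip(observed_values.location_ids, observed_values.split)
               if s == "observed"]
    if design.n_locations != v.size:
        raise DimensionError("design rows must align with the observed-split locations")
    lev = leverages(design)
    l, p = design.values.shape
    thresh = leverage_multiplier * p / l
    keep = lev.leverages <= thresh
    if not keep.any():
        raise MvextrapError("leverage rule removed every observed location")
    removed = [obs_ids[i] for i in np.flatnonzero(~keep)]
    return Cutoff(value=float(v[keep].max()), rule="leverage_max", removed_locations=removed)


def cutoff_quantile(observed_values: MeasureVector, r: float) -> Cutoff:
    """Empirical quantile of the observed-split values at level ``r``.

    Uses linear interpolation on the sorted values with plotting position
    ``h = (l - 1) r + 1`` (the default convention of mainstream statistical
    environments).
    """
    if not 0.0 < r < 1.0:
        raise ValueError("quantile level must lie strictly in (0, 1)")
    v = observed_values.observed_values
    if v.size == 0:
        raise MvextrapError("observed split is empty; cannot form a cutoff")
    return Cutoff(value=float(np.quantile(v, r)), rule="quantile", quantile_level=r)


def extrapolation_index(prediction_values: MeasureVector, cutoff: Cutoff) -> ExtrapolationReport:
    """Classify prediction-split locations against a cutoff.

    ``e = 1`` iff the measure strictly exceeds the cutoff; ``R = v / k`` grades
    how far beyond the hull a flagged location lies (``e = 1`` iff ``R > 1``;
    a location exactly at the boundary is not an extrapolation).
    """
    if cutoff.value <= 0:
        raise ValueError("cutoff value must be positive")
    sel = prediction_values.split == "prediction"
    v = prediction_values.values[sel]
    ids = [i for i, keep in zip(prediction_values.location_ids, sel) if keep]
    relative = v / cutoff.value
    index = (v > cutoff.value).astype(int)
    return ExtrapolationReport(
        location_ids=ids,
        values=v,
        cutoff=cutoff,
        index=index,
        relative=relative,
        measure_kind=prediction_values.measure_kind,
    )
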