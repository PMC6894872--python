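"""Variance masking near constrained supports, and the delta-method variance.

For models whose mean is bounded (binary, Poisson, beta, ...) the predictive
variance of the mean can *shrink* as predictions move toward the edge of the
support: in the Bernoulli/logit case var(y|p) = p(1-p) -> 0 as the linear
predictor grows, so a point far outside the design range may carry a tiny
delta-method variance even though its covariates make it a blatant
extrapolation.  Predictive-variance hulls are blind to such points, while the
quadratic-form hull test (which uses only the design) still flags them — the
basis for preferring the design-based hull over predictive variance under
bounded-mean models.

Only the logit/Bernoulli case is shipped (plus the identity link as a
degenerate reference); the ``GlmSpec`` container admits other links.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from mvextrap.linear_diagnostics import DesignMatrix, ivh_contains


@dataclass
class GlmSpec:
    """A link's inverse (mean function) and its exact derivative.

    ``derivative`` must be the analytic derivative of ``inverse_link`` with
    respect to the linear predictor (finite-difference checked in tests).
    """

    link_name: str
    inverse_link: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def logit_spec() -> GlmSpec:
    """Bernoulli mean function: g^{-1}(eta) = 1/(1+e^{-eta})."""
    return GlmSpec(
        link_name="logit",
        inverse_link=_expit,
        derivative=lambda eta: _expit(eta) * (1.0 - _expit(eta)),
    )


def identity_spec() -> GlmSpec:
    return GlmSpec(
        link_name="identity",
        inverse_link=lambda eta: np.asarray(eta, dtype=float),
        derivative=lambda eta: np.ones_like(np.asarray(eta, dtype=float)),
    )


def delta_method_variance(
    spec: GlmSpec, linear_pred_mean: float, linear_pred_var: float
) -> float:
    """First-order variance of the mean: (dg^{-1}/deta)^2 * var(eta_hat)."""
    if linear_pred_var < 0:
        raise ValueError("linear predictor variance must be non-negative")
    d = float(np.asarray(spec.derivative(linear_pred_mean)))
    return d * d * float(linear_pred_var)


def masking_demo(
    beta0: float,
    beta1: float,
    x_grid: np.ndarray,
    design_x: np.ndarray | None = None,
    sigma2: float = 1.0,
):
    """Bernoulli variance and delta-method predictive variance along a grid.

    With ``p = logistic(beta0 + beta1 x)``, the Bernoulli variance ``p(1-p)``
    is maximal (0.25) at p = 0.5 and vanishes in both tails — the masking
    phenomenon.  If ``design_x`` (the observed design points) is supplied, the
    table also carries the linear-predictor variance
    ``sigma2 * x0'(X'X)^{-1} x0``, the delta-method predictive variance, and
    the hull quadratic-form membership of each grid point, so masked
    extrapolations (small delta variance, outside the hull) are visible.

    Returns a pandas DataFrame with columns x, p, bernoulli_variance, delta_pv
    (plus ivh_margin / in_ivh when a design is given).
    """
    import pandas as pd

    x_grid = np.asarray(x_grid, dtype=float).ravel()
    if x_grid.size == 0:
        raise ValueError("x_grid must be nonempty")
    spec = logit_spec()
    eta = beta0 + beta1 * x_grid
    p = spec.inverse_link(eta)
    bern = p * (1.0 - p)
    out = {"x": x_grid, "p": p, "bernoulli_variance": bern}
    if design_x is None:
        out["delta_pv"] = np.array(
            [delta_method_variance(spec, e, sigma2) for e in eta]
        )
    else:
        design = DesignMatrix.from_covariates(np.asarray(design_x, float).reshape(-1, 1))
        lin_var = np.empty(x_grid.size)
        margin = np.empty(x_grid.size)
        inside = np.empty(x_grid.size, dtype=bool)
        lev_max = None
        for i, xv in enumerate(x_grid):
            x0 = np.array([1.0, xv])
            ok, m = ivh_contains(design, x0)
            inside[i] = ok
            margin[i] = m
            # quadratic form recovered from the margin: q = h_max - margin
            if lev_max is None:
                from mvextrap.linear_diagnostics import leverages

                lev_max = leverages(design).h_max
            lin_var[i] = sigma2 * (lev_max - m)
        out["linear_pred_var"] = lin_var
        out["delta_pv"] = np.array(
            [delta_method_variance(spec, e, v) for e, v in zip(eta, lin_var)]
        )
        out["ivh_margin"] = margin
        out["in_ivh"] = inside
    return pd.DataFrame(out)
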