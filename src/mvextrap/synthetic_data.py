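"""Synthetic multi-response lake-like datasets with known truth.

Emulates the structure of a large lake water-quality compilation: four jointly
normal (log-scale) response variables — total nitrogen, total phosphorus,
chlorophyll a, Secchi depth — regressed on ~9 landscape/lake covariates, with
row-wise partial missingness (some lakes fully sampled, some partially, some
with covariates only) and a prediction split that can contain planted
covariate-space outliers at controlled Mahalanobis distances.

Generative model: covariates are drawn from a correlated multivariate normal;
responses follow ``y_i = B_true x_i + eps_i`` with ``eps_i ~ N(0, Sigma_true)``;
missingness is completely at random by default (an optional covariate-dependent
mode mimics geographically informative undersampling for demonstration only).
Default missingness probabilities leave the first response (the TN analogue)
the most undersampled, as in real monitoring compilations where nitrogen is
sampled less than phosphorus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from mvextrap._errors import DataError, DimensionError
from mvextrap.linear_diagnostics import DesignMatrix
from mvextrap.mvn_gibbs import ModelData

RESPONSE_NAMES_4 = ["tn", "tp", "chla", "secchi"]

# Log-scale residual covariance used when n_resp = 4: strong TP-Chl a coupling,
# Secchi negatively related to the nutrient/productivity block.
_DEFAULT_CORR_4 = np.array(
    [
        [1.00, 0.60, 0.50, -0.50],
        [0.60, 1.00, 0.70, -0.60],
        [0.50, 0.70, 1.00, -0.65],
        [-0.50, -0.60, -0.65, 1.00],
    ]
)
_DEFAULT_SD_4 = np.array([0.65, 0.75, 0.95, 0.60])


def _default_sigma(n_resp: int) -> np.ndarray:
    if n_resp == 4:
        return _DEFAULT_CORR_4 * np.outer(_DEFAULT_SD_4, _DEFAULT_SD_4)
    corr = np.full((n_resp, n_resp), 0.5)
    np.fill_diagonal(corr, 1.0)
    sd = np.full(n_resp, 0.7)
    return corr * np.outer(sd, sd)


def _default_miss_probs(n_resp: int) -> np.ndarray:
    if n_resp == 4:
        # TN undersampled relative to TP / Chl a / Secchi
        return np.array([0.5, 0.2, 0.25, 0.15])
    return np.full(n_resp, 0.2)


@dataclass
class SimulationConfig:
    """Configuration of one synthetic dataset.

    ``outlier_spec`` lists target squared Mahalanobis distances (relative to
    the observed covariate cloud) at which prediction-split points are
    planted.  ``fully_missing_fraction`` forces that share of the observed
    block to lose all responses (those rows join the prediction split).
    """

    l_observed: int = 2000
    l_prediction: int = 500
    q_covariates: int = 9
    n_resp: int = 4
    B_true: np.ndarray | None = None
    Sigma_true: np.ndarray | None = None
    miss_probs: np.ndarray | None = None
    fully_missing_fraction: float = 0.0
    outlier_spec: Sequence[float] = field(default_factory=tuple)
    covariate_corr: float = 0.3
    covariate_dependent_missingness: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.l_observed < 2 or self.l_prediction < 0:
            raise DataError("need at least 2 observed locations")
        if not 0.0 <= self.fully_missing_fraction < 1.0:
            raise DataError("fully_missing_fraction must lie in [0, 1)")
        probs = self.miss_probs if self.miss_probs is not None else _default_miss_probs(self.n_resp)
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (self.n_resp,) or np.any((probs < 0) | (probs > 1)):
            raise DataError("miss_probs must be n_resp probabilities in [0, 1]")
        if np.any(np.asarray(self.outlier_spec, dtype=float) <= 0):
            raise DataError("planted Mahalanobis distances must be positive")
        sigma = self.Sigma_true if self.Sigma_true is not None else _default_sigma(self.n_resp)
        if np.linalg.eigvalsh(np.asarray(sigma, float)).min() <= 0:
            raise DataError("Sigma_true must be symmetric positive definite")


@dataclass
class SyntheticDataset:
    """Generated data plus the truth that produced it."""

    data: ModelData
    B_true: np.ndarray
    Sigma_true: np.ndarray
    planted_ids: list
    planted_md2: dict
    latent_responses: np.ndarray  # complete responses before masking


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset under ``config``; reproducible given ``config.seed``.

    Planted outliers are constructed along random directions from the observed
    covariate mean, scaled so their squared Mahalanobis distance against the
    observed cloud hits the target exactly (realized values are recomputed and
    recorded).  Planted points appear only in the prediction split.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    q, n = config.q_covariates, config.n_resp
    l_obs, l_pred = config.l_observed, config.l_prediction
    n_plant = len(config.outlier_spec)

    # correlated covariates (exchangeable correlation)
    corr = np.full((q, q), config.covariate_corr)
    np.fill_diagonal(corr, 1.0)
    Lc = np.linalg.cholesky(corr)
    Z_obs = rng.standard_normal((l_obs, q)) @ Lc.T
    Z_pred = rng.standard_normal((l_pred, q)) @ Lc.T

    # planted covariate-space outliers, relative to the observed cloud
    xbar = Z_obs.mean(axis=0)
    S = np.cov(Z_obs, rowvar=False, ddof=1)
    cf = linalg.cho_factor(S)
    planted = []
    planted_md2 = {}
    for k, target in enumerate(config.outlier_spec):
        u = rng.standard_normal(q)
        u /= np.linalg.norm(u)
        quad = float(u @ linalg.cho_solve(cf, u))
        x = xbar + np.sqrt(target / quad) * u
        planted.append(x)
        d = x - xbar
        planted_md2[f"planted{k}"] = float(d @ linalg.cho_solve(cf, d))
    Z_plant = np.asarray(planted).reshape(n_plant, q)

    Z = np.vstack([Z_obs, Z_pred, Z_plant]) if (l_pred or n_plant) else Z_obs
    design = DesignMatrix.from_covariates(Z, column_names=[f"x{j+1}" for j in range(q)])

    B = config.B_true
    if B is None:
        B = np.hstack([rng.normal(0.0, 1.0, size=(n, 1)), rng.normal(0.0, 0.5, size=(n, q))])
    B = np.asarray(B, dtype=float)
    if B.shape != (n, q + 1):
        raise DimensionError(f"B_true must have shape ({n}, {q + 1}) including the intercept column")
    Sigma = np.asarray(
        config.Sigma_true if config.Sigma_true is not None else _default_sigma(n), dtype=float
    )

    eps = rng.multivariate_normal(np.zeros(n), Sigma, size=design.n_locations,
                                  method="cholesky")
    Y_latent = design.values @ B.T + eps

    # missingness: MCAR per variable on the observed block only
    probs = np.asarray(
        config.miss_probs if config.miss_probs is not None else _default_miss_probs(n), float
    )
    mask = np.zeros((design.n_locations, n), dtype=bool)
    if config.covariate_dependent_missingness:
        # demonstration mode: first response undersampled where the first
        # covariate is high (mimicking geographically informative sampling)
        base = rng.random((l_obs, n)) >= probs[None, :]
        penal = 1.0 / (1.0 + np.exp(-Z_obs[:, 0]))
        drop = rng.random(l_obs) < 0.5 * penal
        base[drop, 0] = False
        mask[:l_obs] = base
    else:
        mask[:l_obs] = rng.random((l_obs, n)) >= probs[None, :]
    if config.fully_missing_fraction > 0:
        k = int(round(config.fully_missing_fraction * l_obs))
        wipe = rng.choice(l_obs, size=k, replace=False)
        mask[wipe] = False

    responses = np.where(mask, Y_latent, np.nan)
    ids = (
        [f"obs{i}" for i in range(l_obs)]
        + [f"pred{i}" for i in range(l_pred)]
        + [f"planted{k}" for k in range(n_plant)]
    )
    names = RESPONSE_NAMES_4 if n == 4 else [f"y{j+1}" for j in range(n)]
    data = ModelData(design=design, responses=responses, mask=mask,
                     location_ids=ids, response_names=names)
    return SyntheticDataset(
        data=data,
        B_true=B,
        Sigma_true=Sigma,
        planted_ids=list(planted_md2.keys()),
        planted_md2=planted_md2,
        latent_responses=Y_latent,
    )


FIXTURES: dict[str, SimulationConfig] = {
    "tiny": SimulationConfig(
        l_observed=30, l_prediction=6, q_covariates=2, n_resp=2,
        miss_probs=np.array([0.2, 0.1]), outlier_spec=(), seed=11,
    ),
    "small": SimulationConfig(
        l_observed=300, l_prediction=60, q_covariates=4, n_resp=3,
        miss_probs=np.array([0.3, 0.15, 0.1]), outlier_spec=(40.0,), seed=22,
    ),
    "lagos-like": SimulationConfig(
        l_observed=2000, l_prediction=500, q_covariates=9, n_resp=4,
        outlier_spec=(60.0, 80.0, 100.0, 120.0, 150.0), seed=33,
    ),
}


def make_fixture(name: str) -> SyntheticDataset:
    """Deterministic named datasets: tiny / small / lagos-like."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return generate(FIXTURES[name])
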