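"""Bayesian multivariate-normal linear regression fitted by Gibbs sampling.

Model: each location i carries a response vector y_i (length n_resp) and a
covariate vector x_i (length p, intercept included),

    y_i = B x_i + eps_i,    eps_i ~ iid N(0, Sigma)

with independent N(coef_mean, coef_variance) priors on the entries of the
coefficient matrix B (n_resp x p) and an inverse-Wishart prior on Sigma.
Response vectors may be fully observed, partially observed, or fully missing.
Missing entries of partially observed rows are treated as latent variables Z
and updated by data augmentation from their conditional MVN given the row's
observed entries and the current (B, Sigma); fully missing rows carry no
likelihood information and are held out of the fit as prediction locations.

All three blocks (B, Sigma, Z) have closed-form full conditionals, so the
sampler is a pure Gibbs scheme:

* vec(B) | Sigma, Y  is normal with precision
  ``Sigma^{-1} (x) X'X + I/coef_variance`` (Kronecker product, row-major
  stacking of B) and mean solving that system against
  ``vec(Sigma^{-1} Y'X) + coef_mean/coef_variance``;
* Sigma | B, Y  is inverse-Wishart with scale ``iw_scale + E'E`` and
  degrees of freedom ``iw_df + l`` where E are the current residuals;
* each missing block of a row is drawn from the conditional MVN supplied by
  :mod:`mvextrap.conditional_mvn`, vectorized over rows sharing a
  missingness pattern.

The predictive variance at a covariate vector x is the covariance, across
retained draws, of the predictive mean ``B^(a) x`` — the quantity the
generalized independent variable hull is defined from.  The residual Sigma is
deliberately not added here; it enters only the conditional measure's
comparability correction (see :mod:`mvextrap.extrapolation_measures`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from mvextrap import conditional_mvn
from mvextrap._errors import DataError, DimensionError
from mvextrap.linear_diagnostics import DesignMatrix

RHAT_WARN = 1.05


@dataclass
class ModelData:
    """Design matrix plus multi-response matrix with a missingness mask.

    ``responses`` is (l, n_resp) with NaN at unobserved entries; ``mask`` is
    boolean, True where observed.  A row may be fully observed, partially
    observed, or fully missing; fully missing rows form the prediction split.
    """

    design: DesignMatrix
    responses: np.ndarray
    mask: np.ndarray | None = None
    location_ids: Sequence | None = None
    response_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise DimensionError("responses must be 2-d (locations x response variables)")
        if self.responses.shape[0] != self.design.n_locations:
            raise DimensionError("responses rows do not match design rows")
        if self.mask is None:
            self.mask = np.isfinite(self.responses)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.responses.shape:
            raise DimensionError("mask shape must equal responses shape")
        if np.any(~np.isfinite(self.responses[self.mask])):
            raise DataError("masked-observed entries must carry finite values")
        self.responses = np.where(self.mask, self.responses, np.nan)
        if self.location_ids is None:
            self.location_ids = [f"loc{i}" for i in range(self.responses.shape[0])]
        self.location_ids = list(self.location_ids)
        if len(self.location_ids) != self.responses.shape[0]:
            raise DimensionError("location_ids length does not match rows")
        if self.response_names is None:
            self.response_names = [f"y{j + 1}" for j in range(self.responses.shape[1])]
        self.response_names = list(self.response_names)
        if len(self.response_names) != self.responses.shape[1]:
            raise DimensionError("response_names length does not match response columns")

    @property
    def n_resp(self) -> int:
        return self.responses.shape[1]

    @property
    def n_locations(self) -> int:
        return self.responses.shape[0]

    @property
    def observed_rows(self) -> np.ndarray:
        """Indices of rows with at least one observed response (the fit set L_O)."""
        return np.flatnonzero(self.mask.any(axis=1))

    @property
    def prediction_rows(self) -> np.ndarray:
        """Indices of fully missing rows (the prediction set L_P)."""
        return np.flatnonzero(~self.mask.any(axis=1))

    @property
    def split(self) -> np.ndarray:
        """Per-row tag: 'observed' or 'prediction'."""
        out = np.where(self.mask.any(axis=1), "observed", "prediction")
        return out.astype(object)


@dataclass
class Priors:
    """Priors for the coefficient matrix and response covariance.

    Coefficients get independent N(coef_mean, coef_variance) priors
    (coef_variance is a variance); Sigma gets an inverse-Wishart prior with
    scale ``iw_scale`` (default identity) and ``iw_df`` degrees of freedom
    (default n_resp + 1, the smallest integer df giving a proper prior).
    """

    coef_mean: float = 0.0
    coef_variance: float = 100.0
    iw_scale: np.ndarray | None = None
    iw_df: float | None = None

    def resolve(self, n_resp: int) -> tuple[float, float, np.ndarray, float]:
        if self.coef_variance <= 0:
            raise ValueError("coef_variance must be positive")
        scale = np.eye(n_resp) if self.iw_scale is None else np.asarray(self.iw_scale, float)
        if scale.shape != (n_resp, n_resp):
            raise DimensionError("iw_scale dimension must equal the response count")
        if not np.allclose(scale, scale.T):
            raise ValueError("iw_scale must be symmetric")
        if np.linalg.eigvalsh(scale).min() <= 0:
            raise ValueError("iw_scale must be positive definite")
        df = float(n_resp + 1) if self.iw_df is None else float(self.iw_df)
        if df <= n_resp - 1:
            raise ValueError("iw_df must exceed n_resp - 1")
        return self.coef_mean, self.coef_variance, scale, df


@dataclass
class McmcSettings:
    """Chain length and reproducibility settings.

    Defaults: 20,000 iterations with the first half discarded as burn-in,
    no thinning, one chain.
    """

    iterations: int = 20000
    burn_in: int | None = None
    thin: int = 1
    seed: int = 0
    chains: int = 1

    def resolve(self) -> tuple[int, int, int, int, int]:
        burn = self.iterations // 2 if self.burn_in is None else self.burn_in
        if not 0 <= burn < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        return self.iterations, burn, self.thin, int(self.seed), self.chains


@dataclass
class PredictiveVariance:
    """Covariance matrix of the predictive mean response vector at one location."""

    V: np.ndarray
    location_id: object = None
    n_draws_used: int = 0


@dataclass
class PosteriorDraws:
    """Retained posterior samples and convergence summaries.

    ``B_draws`` has shape (A_total, n_resp, p); ``Sigma_draws`` shape
    (A_total, n_resp, n_resp); draws from multiple chains are concatenated and
    labelled in ``chain_ids``.  ``z_mean``/``z_var`` summarize the imputation
    draws for each missing cell of a partially observed row (NaN elsewhere).
    ``diagnostics`` is a DataFrame with per-parameter effective sample size
    and split-chain potential-scale-reduction.
    """

    B_draws: np.ndarray
    Sigma_draws: np.ndarray
    chain_ids: np.ndarray
    z_mean: np.ndarray
    z_var: np.ndarray
    diagnostics: object = None
    settings: McmcSettings | None = None
    priors: Priors | None = None
    response_names: Sequence[str] | None = None
    coef_names: Sequence[str] | None = None

    @property
    def n_draws(self) -> int:
        return self.B_draws.shape[0]

    @property
    def n_resp(self) -> int:
        return self.B_draws.shape[1]


def _split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction on split chains; x has shape (chains, draws)."""
    m, n = x.shape
    half = n // 2
    if half < 2:
        return np.nan
    segs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    m, n = x.shape
    if n < 4:
        return float(m * n)
    acfs = []
    for row in x:
        row = row - row.mean()
        var = row @ row / n
        if var <= 0:
            acfs.append(np.zeros(n))
            continue
        full = np.correlate(row, row, mode="full")[n - 1 :] / (n * var)
        acfs.append(full)
    rho = np.mean(acfs, axis=0)
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / max(tau, 1.0))


def _pattern_groups(mask: np.ndarray) -> dict[tuple[bool, ...], np.ndarray]:
    """Group row indices by missingness pattern (excluding fully observed rows)."""
    groups: dict[tuple[bool, ...], list[int]] = {}
    for i, row in enumerate(mask):
        key = tuple(bool(v) for v in row)
        if all(key):
            continue
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in groups.items()}


def fit(data: ModelData, priors: Priors | None = None, settings: McmcSettings | None = None) -> PosteriorDraws:
    """Draw from the joint posterior of (B, Sigma, Z) by Gibbs sampling.

    Fully missing response rows are excluded from the likelihood (they are
    prediction locations); partially observed rows have their missing entries
    augmented each sweep.  Raises if some response variable is never observed.
    Reproducible given ``settings.seed``.  Chains with split-chain scale
    reduction above 1.05 trigger a warning (diagnostics stay attached).
    """
    priors = priors or Priors()
    settings = settings or McmcSettings()
    iterations, burn, thin, seed, n_chains = settings.resolve()

    fit_rows = data.observed_rows
    if fit_rows.size == 0:
        raise DataError("no rows with observed responses; nothing to fit")
    X = data.design.values[fit_rows]
    mask = data.mask[fit_rows]
    Yobs = data.responses[fit_rows]
    l, p = X.shape
    n = data.n_resp
    never = np.flatnonzero(~mask.any(axis=0))
    if never.size:
        names = [data.response_names[j] for j in never]
        raise DataError(f"response variable(s) never observed: {names}")

    mu0, tau, S0, nu0 = priors.resolve(n)
    XtX = X.T @ X
    groups = _pattern_groups(mask)
    col_means = np.array([np.nanmean(Yobs[:, j]) for j in range(n)])

    all_B, all_S, all_chain = [], [], []
    z_sum = np.zeros_like(Yobs)
    z_sumsq = np.zeros_like(Yobs)
    z_count = 0

    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        Y = np.where(mask, Yobs, col_means[None, :])
        # overdispersed-ish start: least squares B, residual covariance Sigma
        B = np.linalg.lstsq(X, Y, rcond=None)[0].T  # (n, p)
        E = Y - X @ B.T
        Sigma = E.T @ E / max(l - p, 1) + 1e-6 * np.eye(n)

        keep_B = []
        keep_S = []
        for it in range(iterations):
            # --- B | Sigma, Y ---
            Sigma_inv = linalg.cho_solve(linalg.cho_factor(Sigma), np.eye(n))
            P = np.kron(Sigma_inv, XtX)
            P[np.diag_indices_from(P)] += 1.0 / tau
            rhs = (Sigma_inv @ (Y.T @ X)).reshape(-1) + mu0 / tau
            L = np.linalg.cholesky(P)
            mean = linalg.cho_solve((L, True), rhs)
            z = rng.standard_normal(n * p)
            b = mean + linalg.solve_triangular(L.T, z, lower=False)
            B = b.reshape(n, p)

            # --- Sigma | B, Y ---
            E = Y - X @ B.T
            Sigma = stats.invwishart.rvs(df=nu0 + l, scale=S0 + E.T @ E, random_state=rng)
            Sigma = np.atleast_2d(Sigma)

            # --- Z | B, Sigma, Yobs (by missingness pattern) ---
            if groups:
                Mu = X @ B.T
                for key, rows in groups.items():
                    obs = [j for j, v in enumerate(key) if v]
                    mis = [j for j, v in enumerate(key) if not v]
                    C, sbar = conditional_mvn.conditional_coefficients(Sigma, mis, obs)
                    mu_m = Mu[np.ix_(rows, mis)]
                    if obs:
                        dev = Yobs[np.ix_(rows, obs)] - Mu[np.ix_(rows, obs)]
                        mu_m = mu_m + dev @ C.T
                    Ls = np.linalg.cholesky(sbar + 1e-12 * np.eye(len(mis)))
                    draw = mu_m + rng.standard_normal((rows.size, len(mis))) @ Ls.T
                    Y[np.ix_(rows, mis)] = draw

            if it >= burn and (it - burn) % thin == 0:
                keep_B.append(B.copy())
                keep_S.append(Sigma.copy())
                z_sum += np.where(mask, 0.0, Y)
                z_sumsq += np.where(mask, 0.0, Y**2)
                z_count += 1

        all_B.append(np.asarray(keep_B))
        all_S.append(np.asarray(keep_S))
        all_chain.append(np.full(len(keep_B), chain))

    B_draws = np.concatenate(all_B)
    Sigma_draws = np.concatenate(all_S)
    chain_ids = np.concatenate(all_chain)

    if z_count:
        z_mean = np.where(mask, np.nan, z_sum / z_count)
        z_var = np.where(mask, np.nan, z_sumsq / z_count - (z_sum / z_count) ** 2)
    else:  # pragma: no cover - resolve() guarantees retained draws
        z_mean = np.full_like(Yobs, np.nan)
        z_var = np.full_like(Yobs, np.nan)
    # expand imputation summaries back to full row indexing
    full_mean = np.full_like(data.responses, np.nan)
    full_var = np.full_like(data.responses, np.nan)
    full_mean[fit_rows] = z_mean
    full_var[fit_rows] = z_var

    diagnostics = _diagnostics_frame(all_B, all_S, data, p)
    bad = diagnostics.loc[diagnostics["rhat"] > RHAT_WARN, "parameter"].tolist()
    if bad:
        warnings.warn(
            f"split-chain scale reduction > {RHAT_WARN} for {len(bad)} parameter(s), "
            f"e.g. {bad[:5]}; consider more iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    coef_names = [str(c) for c in data.design.column_names]
    return PosteriorDraws(
        B_draws=B_draws,
        Sigma_draws=Sigma_draws,
        chain_ids=chain_ids,
        z_mean=full_mean,
        z_var=full_var,
        diagnostics=diagnostics,
        settings=settings,
        priors=priors,
        response_names=list(data.response_names),
        coef_names=coef_names,
    )


def _diagnostics_frame(all_B: list, all_S: list, data: ModelData, p: int):
    import pandas as pd

    n = data.n_resp
    rows = []
    B_chains = np.stack(all_B)  # (chains, A, n, p)
    S_chains = np.stack(all_S)
    for r in range(n):
        for c in range(p):
            trace = B_chains[:, :, r, c]
            rows.append((f"b[{data.response_names[r]},{data.design.column_names[c]}]",
                         _ess(trace), _split_rhat(trace)))
    for r in range(n):
        for c in range(r, n):
            trace = S_chains[:, :, r, c]
            rows.append((f"sigma[{data.response_names[r]},{data.response_names[c]}]",
                         _ess(trace), _split_rhat(trace)))
    return pd.DataFrame(rows, columns=["parameter", "ess", "rhat"])


def predictive_mean_draws(draws: PosteriorDraws, x_p: np.ndarray) -> np.ndarray:
    """Per-draw predictive means ``B^(a) x_p``; shape (A, n_resp)."""
    x_p = np.asarray(x_p, dtype=float).ravel()
    if x_p.shape[0] != draws.B_draws.shape[2]:
        raise DimensionError(
            f"x_p has length {x_p.shape[0]}, coefficient matrix has {draws.B_draws.shape[2]} columns"
        )
    return draws.B_draws @ x_p


def predictive_variance(draws: PosteriorDraws, x_p: np.ndarray, min_draws: int = 100) -> PredictiveVariance:
    """Sample covariance across draws of the predictive mean at ``x_p``.

    This is the Monte-Carlo estimate of var(B x | Y) — the variance of the
    predictive mean, excluding the residual Sigma.
    """
    if draws.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, have {draws.n_draws}")
    mu = predictive_mean_draws(draws, x_p)
    V = np.cov(mu, rowvar=False, ddof=1)
    V = np.atleast_2d(V)
    return PredictiveVariance(V=V, n_draws_used=draws.n_draws)


def predictive_variances(draws: PosteriorDraws, X_pred: np.ndarray) -> np.ndarray:
    """Vectorized predictive-mean covariance matrices for many locations.

    ``X_pred`` is (m, p); returns an (m, n_resp, n_resp) array where slice i is
    the covariance across draws of ``B^(a) x_i``.
    """
    X_pred = np.atleast_2d(np.asarray(X_pred, dtype=float))
    mu = np.einsum("anp,mp->man", draws.B_draws, X_pred)  # (m, A, n)
    dev = mu - mu.mean(axis=1, keepdims=True)
    A = mu.shape[1]
    return np.einsum("man,mak->mnk", dev, dev) / (A - 1)


def save_draws_csv(draws: PosteriorDraws, draws_path, metadata_path=None) -> None:
    """Persist retained draws to a flat CSV (one row per draw) plus a metadata file."""
    import pandas as pd

    A, n, p = draws.B_draws.shape
    cols = {"chain": draws.chain_ids}
    rnames = draws.response_names or [f"y{j+1}" for j in range(n)]
    cnames = draws.coef_names or [f"c{j}" for j in range(p)]
    for r in range(n):
        for c in range(p):
            cols[f"b_{rnames[r]}_{cnames[c]}"] = draws.B_draws[:, r, c]
    for r in range(n):
        for c in range(r, n):
            cols[f"sigma_{rnames[r]}_{rnames[c]}"] = draws.Sigma_draws[:, r, c]
    pd.DataFrame(cols).to_csv(draws_path, index=False)
    if metadata_path is not None and draws.settings is not None:
        s, pr = draws.settings, draws.priors or Priors()
        lines = [
            f"seed = {s.seed}",
            f"iterations = {s.iterations}",
            f"burn_in = {s.iterations // 2 if s.burn_in is None else s.burn_in}",
            f"thin = {s.thin}",
            f"chains = {s.chains}",
            f"coef_mean = {pr.coef_mean}",
            f"coef_variance = {pr.coef_variance}",
            f"iw_df = {'n_resp+1' if pr.iw_df is None else pr.iw_df}",
        ]
        with open(metadata_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
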