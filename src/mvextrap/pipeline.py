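"""End-to-end orchestration: read data, fit, measure, classify, characterize.

The workflow mirrors how the measures are meant to be used in practice:

1. fit the joint multivariate regression to all locations with at least one
   observed response;
2. compute a scalar predictive-variance measure at every location;
3. form one or more cutoffs from the observed-split values (maximum,
   leverage-informed maximum, empirical quantiles);
4. classify each prediction-split location against each cutoff;
5. characterize the flagged covariate space with a classification tree.

All artifacts are plain CSV/text; the run log records the seed, settings, and
per-cutoff extrapolation counts in decreasing-cutoff order (counts are
non-decreasing down that list because smaller cutoffs flag supersets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mvextrap import cart_characterization as cart
from mvextrap import extrapolation_measures as em
from mvextrap import mvn_gibbs
from mvextrap._errors import DataError
from mvextrap.linear_diagnostics import DesignMatrix
from mvextrap.mvn_gibbs import McmcSettings, ModelData, Priors
from mvextrap.synthetic_data import SyntheticDataset

MISSING_TOKENS = {"", "na", "nan"}


@dataclass
class RunConfig:
    """Settings of one end-to-end run."""

    design_path: str | Path = ""
    response_path: str | Path = ""
    output_dir: str | Path = "mvextrap_run"
    measure_kind: str = "mvpv_det"
    cmvpv_target: str | None = None
    cutoff_rules: Sequence[str] = ("max", "leverage_max", "quantile")
    quantile_levels: Sequence[float] = (0.99, 0.95)
    leverage_multiplier: float = 2.0
    iterations: int = 2000
    burn_in: int | None = None
    thin: int = 1
    chains: int = 1
    coef_variance: float = 100.0
    iw_df: float | None = None
    cart_max_depth: int = 4
    cart_min_leaf: int = 5
    cart_class_weight: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.cutoff_rules:
            raise DataError("at least one cutoff rule is required")
        for r in self.quantile_levels:
            if not 0.0 < float(r) < 1.0:
                raise DataError("quantile levels must lie in (0, 1)")
        if self.measure_kind == "cmvpv" and not self.cmvpv_target:
            raise DataError("cmvpv measure requires cmvpv_target (a response name)")


def parse_config(path: str | Path) -> RunConfig:
    """Parse a plain-text ``key = value`` config file (``#`` starts a comment)."""
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DataError(f"config line is not key = value: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val
    cfg = RunConfig()
    for key, val in kv.items():
        if not hasattr(cfg, key):
            raise DataError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if key in ("cutoff_rules",):
            setattr(cfg, key, tuple(s.strip() for s in val.split(",") if s.strip()))
        elif key in ("quantile_levels",):
            setattr(cfg, key, tuple(float(s) for s in val.split(",") if s.strip()))
        elif key in ("burn_in", "iw_df", "cmvpv_target", "cart_class_weight"):
            setattr(cfg, key, None if val.lower() == "none" else type_cast(key, val))
        elif isinstance(current, bool):
            setattr(cfg, key, val.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(val))
        elif isinstance(current, float):
            setattr(cfg, key, float(val))
        else:
            setattr(cfg, key, val)
    return cfg


def type_cast(key: str, val: str):
    if key == "burn_in":
        return int(val)
    if key == "iw_df":
        return float(val)
    return val


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected an id column plus at least one value column")
    idcol = df.columns[0]
    if df[idcol].duplicated().any():
        dupes = df[idcol][df[idcol].duplicated()].tolist()
        raise DataError(f"{path}: duplicate location ids {dupes[:5]}")
    return df.set_index(idcol)


def _to_numeric(df: pd.DataFrame, path, allow_missing: bool) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            token = str(cell).strip()
            if token.lower() in MISSING_TOKENS:
                if not allow_missing:
                    raise DataError(f"{path}: missing value at row {df.index[i]!r}, column {col!r}")
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(token)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell {token!r} at row {df.index[i]!r}, column {col!r}"
                ) from None
    return out


def read_model_data(design_path: str | Path, response_path: str | Path) -> ModelData:
    """Load aligned design/response CSVs into a ModelData.

    Both files carry a header row with the location id in the first column.
    Empty cells and the tokens NA/NaN (case-insensitive) mark missing
    responses.  Locations present in the design but absent from the response
    file become fully missing prediction locations; a response row without a
    design row is an error.
    """
    ddf = _read_table(design_path)
    rdf = _read_table(response_path)
    extra = [i for i in rdf.index if i not in set(ddf.index)]
    if extra:
        raise DataError(f"response rows without matching design rows: {extra[:5]}")
    X = _to_numeric(ddf, design_path, allow_missing=False)
    design = DesignMatrix.from_covariates(X, column_names=list(ddf.columns))
    n_resp = rdf.shape[1]
    responses = np.full((ddf.shape[0], n_resp), np.nan)
    rvals = _to_numeric(rdf, response_path, allow_missing=True)
    pos = {loc: i for i, loc in enumerate(ddf.index)}
    for k, loc in enumerate(rdf.index):
        responses[pos[loc]] = rvals[k]
    return ModelData(
        design=design,
        responses=responses,
        location_ids=list(ddf.index),
        response_names=list(rdf.columns),
    )


def write_model_data(
    data: ModelData | SyntheticDataset,
    design_path: str | Path,
    response_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the shared CSV formats (empty cells for missing responses)."""
    truth = None
    if isinstance(data, SyntheticDataset):
        truth = (data.B_true, data.Sigma_true)
        data = data.data
    ddf = pd.DataFrame(
        data.design.covariates,
        columns=[str(c) for c in data.design.column_names[1:]] if data.design.has_intercept
        else [str(c) for c in data.design.column_names],
        index=pd.Index(data.location_ids, name="location_id"),
    )
    ddf.to_csv(design_path, float_format="%.12g")
    rdf = pd.DataFrame(
        data.responses,
        columns=list(data.response_names),
        index=pd.Index(data.location_ids, name="location_id"),
    )
    rdf.to_csv(response_path, float_format="%.12g", na_rep="")
    if truth is not None and truth_path is not None:
        B, Sigma = truth
        with open(truth_path, "w") as fh:
            fh.write("# B_true rows are response variables, columns are intercept+covariates\n")
            for r, name in enumerate(data.response_names):
                fh.write(f"B[{name}] = " + ",".join(f"{v:.12g}" for v in B[r]) + "\n")
            for r, name in enumerate(data.response_names):
                fh.write(f"Sigma[{name}] = " + ",".join(f"{v:.12g}" for v in Sigma[r]) + "\n")


def _cutoffs_for(config: RunConfig, measures: em.MeasureVector, data: ModelData) -> list[em.Cutoff]:
    cutoffs: list[em.Cutoff] = []
    obs_rows = np.flatnonzero(measures.split == "observed")
    obs_design = DesignMatrix(
        data.design.values[obs_rows],
        has_intercept=data.design.has_intercept,
        column_names=data.design.column_names,
    )
    for rule in config.cutoff_rules:
        if rule == "max":
            cutoffs.append(em.cutoff_max(measures))
        elif rule == "leverage_max":
            cutoffs.append(em.cutoff_leverage(measures, obs_design, config.leverage_multiplier))
        elif rule == "quantile":
            for r in config.quantile_levels:
                cutoffs.append(em.cutoff_quantile(measures, float(r)))
        else:
            raise DataError(f"unknown cutoff rule {rule!r}")
    return cutoffs


def _cutoff_label(c: em.Cutoff) -> str:
    if c.rule == "quantile":
        return f"quantile_{c.quantile_level:g}"
    return c.rule


def run(config: RunConfig, data: ModelData | None = None) -> dict:
    """Execute the full workflow; returns the in-memory artifacts.

    ``data`` may be supplied directly; otherwise it is read from the config's
    design/response paths.  On disk the run produces the posterior draw CSV
    and metadata, a per-location measure CSV, one extrapolation report CSV per
    cutoff, a classification-tree text summary, and a log.
    """
    config.validate()
    if data is None:
        data = read_model_data(config.design_path, config.response_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed = {config.seed}", f"measure_kind = {config.measure_kind}"]

    settings = McmcSettings(
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        chains=config.chains,
        seed=config.seed,
    )
    priors = Priors(coef_variance=config.coef_variance, iw_df=config.iw_df)
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        draws = mvn_gibbs.fit(data, priors, settings)
    for w in caught:
        log_lines.append(f"warning: {w.message}")
    mvn_gibbs.save_draws_csv(draws, outdir / "draws.csv", outdir / "draws_metadata.txt")
    log_lines.append(
        f"iterations = {settings.iterations}, retained draws = {draws.n_draws}, "
        f"chains = {settings.chains}"
    )

    target_idx = None
    if config.measure_kind == "cmvpv":
        if config.cmvpv_target not in data.response_names:
            raise DataError(
                f"cmvpv_target {config.cmvpv_target!r} not among responses {data.response_names}"
            )
        target_idx = data.response_names.index(config.cmvpv_target)
    measures = em.compute_measures(draws, data, kind=config.measure_kind, target=target_idx)
    mdf = pd.DataFrame(
        {
            "location_id": measures.location_ids,
            "split": measures.split,
            "measure_kind": measures.measure_kind,
            "measure_value": measures.values,
        }
    )
    mdf.to_csv(outdir / "measures.csv", index=False)

    cutoffs = _cutoffs_for(config, measures, data)
    order = np.argsort([-c.value for c in cutoffs], kind="stable")
    reports: dict[str, em.ExtrapolationReport] = {}
    counts: list[tuple[str, float, int]] = []
    for k in order:
        c = cutoffs[k]
        rep = em.extrapolation_index(measures, c)
        label = _cutoff_label(c)
        reports[label] = rep
        rep.to_dataframe().to_csv(outdir / f"report_{label}.csv", index=False)
        counts.append((label, c.value, int(rep.index.sum())))
    log_lines.append("extrapolation counts (decreasing cutoff order):")
    for label, value, cnt in counts:
        log_lines.append(f"  {label}: cutoff = {value:.6g}, extrapolations = {cnt}")

    # characterize with a classification tree on the prediction split,
    # using the smallest cutoff (most inclusive index)
    tree = None
    smallest = counts[-1][0]
    rep = reports[smallest]
    pos = {loc: i for i, loc in enumerate(data.location_ids)}
    pred_rows = np.array([pos[i] for i in rep.location_ids], dtype=int)
    if pred_rows.size and rep.index.size:
        covs = data.design.covariates[pred_rows]
        names = [str(c) for c in data.design.column_names[1:]]
        tree = cart.fit_tree(
            covs,
            rep.index,
            max_depth=config.cart_max_depth,
            min_leaf=config.cart_min_leaf,
            class_weight=config.cart_class_weight,
            column_names=names,
        )
        text = cart.render_tree(tree)
        (outdir / "cart.txt").write_text(text + "\n")
        ranking = cart.tree_summary(tree)
        log_lines.append("cart variable importance: " + (
            ", ".join(f"{v}={imp:.4g}" for v, imp in ranking) if ranking else "(leaf only)"
        ))

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "draws": draws,
        "measures": measures,
        "cutoffs": {_cutoff_label(c): c for c in cutoffs},
        "reports": reports,
        "counts": counts,
        "tree": tree,
        "log": log_lines,
    }
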