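"""Synthetic ageing-cohort generator.

Generates participant tables with the dependence structure the downstream
analysis assumes:

* a latent childhood-advantage variable ``U ~ N(0, 1)`` induces positive
  correlations among early-life factors (ordered-threshold draws on
  ``loading * U + noise``);
* current socioeconomic covariates additionally depend on the early-life
  dummies through a latent SES propensity (the mediation path);
* a continuous family-economic-status (wealth) variable drives the wealth
  quintiles and the socioeconomic ranking used by the concentration index;
* the latent overall capacity is ``X beta + eps`` with planted effects
  ``beta`` and standard-normal noise; subdomain latents add their own
  planted effects plus a share of the common noise; the 12 observed
  indicators follow the second-order measurement model.

Latent truth columns are carried with a ``latent_`` prefix and are excluded
from every analysis path; they exist so that recovery experiments can be run
against known ground truth.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    ConfigurationError,
    CovariateSpec,
    FactorStructure,
    GeneratorConfig,
)

LATENT_PREFIX = "latent_"
ID_COLUMN = "pid"


def is_latent(column: str) -> bool:
    return column.startswith(LATENT_PREFIX)


def analysis_columns(cohort: pd.DataFrame) -> list[str]:
    """Observable columns (latent truth columns removed)."""
    return [c for c in cohort.columns if not is_latent(c)]


def _level_counts(n: int, marginal: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of n rows to levels."""
    exact = np.asarray(marginal, dtype=float) * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:short]] += 1
    return counts


def _threshold_assign(index: np.ndarray, spec: CovariateSpec) -> pd.Categorical:
    """Assign ordered levels by empirical quantiles of a latent index.

    The lowest block of the index receives the first (least advantaged)
    level and so on; block sizes follow the configured marginal exactly
    (largest-remainder rounding), which also makes quintile-type covariates
    hold n/5 +- 1 rows by construction.
    """
    n = index.shape[0]
    counts = _level_counts(n, spec.marginal)
    order = np.argsort(index, kind="stable")
    codes = np.empty(n, dtype=int)
    codes[order] = np.repeat(np.arange(len(spec.levels)), counts)
    return pd.Categorical.from_codes(codes, categories=list(spec.levels))


def _dummies(cohort: pd.DataFrame, spec: CovariateSpec) -> dict[str, np.ndarray]:
    col = cohort[spec.name]
    return {
        lvl: (col == lvl).to_numpy(dtype=float)
        for lvl in spec.nonreference_levels
    }


def _planted_linear_predictor(
    cohort: pd.DataFrame, config: GeneratorConfig, outcome: str
) -> np.ndarray:
    lp = np.zeros(len(cohort))
    for spec in config.covariates:
        for lvl in spec.nonreference_levels:
            beta = spec.effect(lvl, outcome)
            if beta != 0.0:
                lp += beta * (cohort[spec.name] == lvl).to_numpy(dtype=float)
    return lp


def _mediation_index(cohort: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    m = np.zeros(len(cohort))
    for cov, coefs in config.mediation_coefs.items():
        col = cohort[cov]
        for lvl, coef in coefs.items():
            m += coef * (col == lvl).to_numpy(dtype=float)
    return m


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort.

    Returns a DataFrame with one row per participant: ``pid``, categorical
    covariates, continuous ``wealth``, a unit ``weight`` column, the capacity
    indicators, and hidden ``latent_*`` truth columns.  Identical configs
    produce identical cohorts.
    """
    n = config.n
    ss = np.random.SeedSequence(config.seed)
    keys = ["advantage", "covariates", "ses", "wealth", "capacity", "indicators"]
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    cohort = pd.DataFrame({ID_COLUMN: np.arange(1, n + 1)})
    u = rngs["advantage"].standard_normal(n)

    # early-life, demographic, lifestyle covariates: thresholds on loading*U + e
    rng_cov = rngs["covariates"]
    ses_specs: list[CovariateSpec] = []
    for spec in config.covariates:
        if spec.category == "current_ses":
            ses_specs.append(spec)
            continue
        index = spec.advantage_loading * u + rng_cov.standard_normal(n)
        cohort[spec.name] = _threshold_assign(index, spec)

    # mediation path: early-life dummies -> latent current-SES propensity
    m = _mediation_index(cohort, config)

    rng_ses = rngs["ses"]
    wm = config.wealth_model
    wealth_z = (
        wm.advantage_loading * u
        + wm.mediation_loading * m
        + wm.noise_sd * rngs["wealth"].standard_normal(n)
    )
    for spec in ses_specs:
        if spec.group == "family_economic_status":
            cohort[spec.name] = _threshold_assign(wealth_z, spec)
        else:
            index = spec.advantage_loading * u + m + rng_ses.standard_normal(n)
            cohort[spec.name] = _threshold_assign(index, spec)
    cohort["wealth"] = np.exp(wm.log_mean + wm.log_scale * wealth_z)
    cohort["weight"] = 1.0

    # latent capacities: overall eta = X beta + eps, subdomains add their own
    # planted effects plus lambda_d * eps and a disturbance
    rng_cap = rngs["capacity"]
    eps = rng_cap.standard_normal(n)
    eta = _planted_linear_predictor(cohort, config, "overall") + eps
    cohort[LATENT_PREFIX + "advantage"] = u
    cohort[LATENT_PREFIX + "ses_propensity"] = m
    cohort[LATENT_PREFIX + "wealth_z"] = wealth_z
    cohort[LATENT_PREFIX + "overall"] = eta

    fs = config.factor_structure
    if fs is not None:
        rng_ind = rngs["indicators"]
        for d in fs.subdomains:
            lam = fs.second_order_loadings[d]
            psi = fs.disturbances[d]
            eta_d = (
                _planted_linear_predictor(cohort, config, d)
                + lam * eps
                + np.sqrt(psi) * rng_cap.standard_normal(n)
            )
            cohort[LATENT_PREFIX + d] = eta_d
            for ind in fs.indicator_map[d]:
                theta = fs.uniquenesses[ind]
                cohort[ind] = fs.loadings[ind] * eta_d + np.sqrt(
                    theta
                ) * rng_ind.standard_normal(n)

    if config.missing_rates:
        cohort = inject_missingness(
            cohort, config.missing_rates, seed=ss.spawn(1)[0]
        )
    return cohort


def simulate_factor_data(
    structure: FactorStructure,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    overall_variance: float = 1.0,
) -> pd.DataFrame:
    """Simulate indicators from the pure second-order factor model.

    Unlike :func:`generate_cohort` there are no covariate effects: the
    overall latent is drawn N(0, overall_variance), subdomain latents are
    ``lambda_d * eta + delta_d`` and indicators follow the measurement
    model.  Latent truths are included with the ``latent_`` prefix.
    """
    rng = np.random.default_rng(seed)
    eta = np.sqrt(overall_variance) * rng.standard_normal(n)
    out = {LATENT_PREFIX + "overall": eta}
    for d in structure.subdomains:
        eta_d = structure.second_order_loadings[d] * eta + np.sqrt(
            structure.disturbances[d]
        ) * rng.standard_normal(n)
        out[LATENT_PREFIX + d] = eta_d
        for ind in structure.indicator_map[d]:
            out[ind] = structure.loadings[ind] * eta_d + np.sqrt(
                structure.uniquenesses[ind]
            ) * rng.standard_normal(n)
    return pd.DataFrame(out)


def inject_missingness(
    cohort: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Set cells missing completely at random at per-column rates.

    Latent truth columns and the id column are never masked.
    """
    for col, rate in rates.items():
        if col not in cohort.columns:
            raise ConfigurationError(f"missing rate for unknown column {col!r}")
        if not 0.0 <= float(rate) <= 1.0:
            raise ConfigurationError(f"rate for {col!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col, rate in rates.items():
        if is_latent(col) or col == ID_COLUMN or rate == 0.0:
            continue
        mask = rng.random(len(out)) < float(rate)
        if isinstance(out[col].dtype, pd.CategoricalDtype):
            codes = out[col].cat.codes.to_numpy().copy()
            codes[mask] = -1
            out[col] = pd.Categorical.from_codes(
                codes, categories=out[col].cat.categories
            )
        else:
            vals = out[col].to_numpy(dtype=float).copy()
            vals[mask] = np.nan
            out[col] = vals
    return out


def _selection_design(
    cohort: pd.DataFrame, selection_model: Mapping[str, float]
) -> np.ndarray:
    """Linear probit index; categorical columns enter via level codes."""
    z = np.full(len(cohort), float(selection_model.get("intercept", 0.0)))
    for col, coef in selection_model.items():
        if col == "intercept":
            continue
        name = col
        if name not in cohort.columns and LATENT_PREFIX + name in cohort.columns:
            name = LATENT_PREFIX + name
        if name not in cohort.columns:
            raise ConfigurationError(f"selection model references unknown column {col!r}")
        series = cohort[name]
        if isinstance(series.dtype, pd.CategoricalDtype):
            vals = series.cat.codes.to_numpy(dtype=float)
        else:
            vals = series.to_numpy(dtype=float)
        z += float(coef) * vals
    return z


def apply_selection(
    cohort: pd.DataFrame,
    selection_model: Mapping[str, float],
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw probit-form inclusion and return (retained rows, indicator).

    The indicator covers the full cohort so a selection equation can be fit
    on everyone, included or not.
    """
    z = _selection_design(cohort, selection_model)
    p = stats.norm.cdf(z)
    rng = np.random.default_rng(seed)
    included = rng.random(len(cohort)) < p
    return cohort.loc[included].reset_index(drop=True), included


# ---------------------------------------------------------------------------
# CSV + JSON sidecar schema interchange


def write_cohort(cohort: pd.DataFrame, csv_path: str, schema_path: str) -> None:
    """Write a cohort as CSV plus a JSON sidecar naming column types."""
    schema: dict[str, dict] = {}
    for col in cohort.columns:
        s = cohort[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            schema[col] = {
                "type": "categorical",
                "levels": [str(x) for x in s.cat.categories],
            }
        elif col == ID_COLUMN:
            schema[col] = {"type": "integer"}
        else:
            schema[col] = {"type": "numeric", "latent": is_latent(col)}
    cohort.to_csv(csv_path, index=False)
    with open(schema_path, "w") as fh:
        json.dump({"columns": schema}, fh, indent=1)


def read_cohort(csv_path: str, schema_path: str) -> pd.DataFrame:
    with open(schema_path) as fh:
        schema = json.load(fh)["columns"]
    df = pd.read_csv(csv_path)
    for col, meta in schema.items():
        if col not in df.columns:
            raise ConfigurationError(f"schema column {col!r} absent from CSV")
        if meta["type"] == "categorical":
            df[col] = pd.Categorical(
                df[col].astype("string").astype(object), categories=meta["levels"]
            )
        elif meta["type"] == "numeric":
            df[col] = df[col].astype(float)
    return df
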