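"""Sensitivity machinery: selection correction, multiple imputation and
subgroup heterogeneity.

* :func:`heckman_adjust` fits a probit inclusion equation on the full
  cohort, computes the inverse Mills ratio for the included rows and adds it
  to the outcome regression (incidental-truncation / two-step correction).
* :func:`chained_imputation` produces ``m`` completed datasets by chained
  equations (predictive mean matching via statsmodels' MICE engine) and
  :func:`rubin_pool` combines per-imputation estimates with Rubin's rules
  (total variance = within-mean + (1 + 1/m) * between).
* :func:`subgroup_contrast` reruns the regression/index/decomposition
  pipeline on each side of a sample split and tabulates the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.imputation.mice import MICEData

from .cohort import ID_COLUMN, is_latent
from .decompose import (
    DecompositionResults,
    InequalityDecomposition,
    LinearModelFit,
    build_design,
    fit_ols,
)


def inverse_mills(z: np.ndarray) -> np.ndarray:
    """phi(z) / Phi(z), computed on the log scale for stability.

    Strictly positive, strictly decreasing in z, -> 0 as z -> inf.
    """
    z = np.asarray(z, dtype=float)
    return np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))


@dataclass
class SelectionModel:
    """Fitted probit inclusion equation with inverse Mills ratios."""

    gamma: pd.Series
    index: np.ndarray  # z*gamma for every row of the full cohort
    mills: np.ndarray  # inverse Mills ratio, full cohort
    converged: bool
    separation_flag: bool


@dataclass
class HeckmanResults:
    """Outcome model augmented with the inverse Mills ratio."""

    selection: SelectionModel
    outcome_fit: LinearModelFit
    mills_coef: float
    mills_se: float
    mills_ci: tuple[float, float]
    mills_t: float
    exclusion_restriction: bool


def fit_selection_probit(
    full_cohort: pd.DataFrame,
    inclusion: np.ndarray,
    selection_covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> SelectionModel:
    """ML probit of the inclusion indicator on the full cohort."""
    incl = np.asarray(inclusion).astype(float)
    if incl.shape[0] != len(full_cohort):
        raise ValueError("inclusion indicator must cover the full cohort")
    Z, _ = build_design(full_cohort, selection_covariates, references)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Probit(incl, Z).fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            warnings.simplefilter("default")
            res = sm.Probit(incl, Z).fit(
                disp=0, maxiter=200, method="bfgs"
            )
    fitted_p = np.asarray(res.predict(Z))
    if np.any(fitted_p > 1 - 1e-10) or np.any(fitted_p < 1e-10):
        separation = True
        warnings.warn("possible perfect separation in the selection probit")
    z = np.asarray(Z.to_numpy() @ res.params)
    return SelectionModel(
        gamma=res.params,
        index=z,
        mills=inverse_mills(z),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation,
    )


def heckman_adjust(
    full_cohort: pd.DataFrame,
    inclusion: np.ndarray,
    selection_covariates: Sequence[str],
    outcome: str | np.ndarray,
    outcome_covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> HeckmanResults:
    """Incidental-truncation correction for the capacity regression.

    The probit inclusion model is fitted on the whole cohort; the inverse
    Mills ratio evaluated at each included row is appended to the outcome
    design.  A Mills coefficient indistinguishable from zero indicates no
    detectable selection on unobservables.  When the selection covariates
    add nothing beyond the outcome covariates, identification rests on the
    probit's functional form only, and a warning is logged.
    """
    sel = fit_selection_probit(
        full_cohort, inclusion, selection_covariates, references
    )
    exclusion = bool(set(selection_covariates) - set(outcome_covariates))
    if not exclusion:
        warnings.warn(
            "no exclusion restriction: selection covariates are a subset of "
            "the outcome covariates; the correction is identified only by "
            "functional form"
        )
    incl = np.asarray(inclusion).astype(bool)
    sub = full_cohort.loc[incl].reset_index(drop=True).copy()
    sub["_mills"] = sel.mills[incl]
    if isinstance(outcome, str):
        y: str | np.ndarray = outcome
    else:
        y = np.asarray(outcome, dtype=float)[incl]
    fit = fit_ols(sub, y, list(outcome_covariates) + ["_mills"], references)
    term = "_mills"
    coef = float(fit.params[term])
    se = float(fit.bse[term])
    ci = (float(fit.conf_int.loc[term, 0]), float(fit.conf_int.loc[term, 1]))
    return HeckmanResults(
        selection=sel,
        outcome_fit=fit,
        mills_coef=coef,
        mills_se=se,
        mills_ci=ci,
        mills_t=coef / se if se > 0 else np.inf,
        exclusion_restriction=exclusion,
    )


# ---------------------------------------------------------------------------
# multiple imputation


def chained_imputation(
    cohort: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    iterations: int = 10,
) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations.

    Column-wise conditional models are cycled ``iterations`` times between
    retained datasets; continuous and categorical (level-coded) columns are
    imputed by predictive mean matching, so imputed categorical cells stay
    inside the observed level set.  Identifier and latent truth columns are
    passed through untouched.  Deterministic given ``seed``.
    """
    if m < 2:
        raise ValueError("m must be >= 2 for multiple imputation")
    passthrough = [
        c for c in cohort.columns if is_latent(c) or c == ID_COLUMN
    ]
    work_cols = [c for c in cohort.columns if c not in passthrough]
    fully_missing = [
        c for c in work_cols if cohort[c].isna().all() and len(cohort) > 0
    ]
    if fully_missing:
        raise ValueError(f"columns with no observed values: {fully_missing}")

    num = pd.DataFrame(index=cohort.index)
    cat_levels: dict[str, pd.Index] = {}
    for c in work_cols:
        s = cohort[c]
        if isinstance(s.dtype, pd.CategoricalDtype):
            codes = s.cat.codes.to_numpy(dtype=float)
            codes[codes < 0] = np.nan
            num[c] = codes
            cat_levels[c] = s.cat.categories
        else:
            num[c] = s.to_numpy(dtype=float)

    any_missing = bool(num.isna().to_numpy().any())
    out: list[pd.DataFrame] = []
    if not any_missing:
        return [cohort.copy() for _ in range(m)]

    state = np.random.get_state()
    try:
        np.random.seed(int(np.random.SeedSequence(seed).generate_state(1)[0]) % (2**31))
        md = MICEData(num)
        for _ in range(m):
            md.update_all(iterations)
            completed = md.data.copy()
            df = cohort.copy()
            for c in work_cols:
                if c in cat_levels:
                    codes = completed[c].to_numpy()
                    codes = np.clip(np.round(codes), 0, len(cat_levels[c]) - 1)
                    df[c] = pd.Categorical.from_codes(
                        codes.astype(int), categories=cat_levels[c]
                    )
                else:
                    df[c] = completed[c].to_numpy()
            out.append(df)
    finally:
        np.random.set_state(state)
    return out


@dataclass
class PooledEstimate:
    """Rubin-combined estimate across imputations."""

    m: int
    estimates: np.ndarray
    variances: np.ndarray
    qbar: float
    within: float
    between: float
    total: float
    df: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        if np.isinf(self.df):
            t = stats.norm.ppf(0.5 + level / 2.0)
        else:
            t = stats.t.ppf(0.5 + level / 2.0, self.df)
        return (self.qbar - t * self.se, self.qbar + t * self.se)


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    df_complete: float | None = None,
) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    ``T = Wbar + (1 + 1/m) B`` with Barnard-Rubin small-sample degrees of
    freedom when a complete-data df is supplied, otherwise the classic
    large-sample df.
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = q.size
    if m < 2:
        raise ValueError("need at least two imputations to pool")
    if np.any(v < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    wbar = float(v.mean())
    b = 0.0 if np.all(q == q[0]) else float(q.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = np.inf
    else:
        r = (1.0 + 1.0 / m) * b / wbar if wbar > 0 else np.inf
        df_large = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else m - 1.0
        if df_complete is not None and np.isfinite(df_large):
            gamma = (1.0 + 1.0 / m) * b / total
            df_obs = (
                (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - gamma)
            )
            df = 1.0 / (1.0 / df_large + 1.0 / df_obs)
        else:
            df = df_large
    return PooledEstimate(
        m=m, estimates=q, variances=v, qbar=qbar, within=wbar, between=b,
        total=total, df=float(df),
    )


def pool_fits(fits: Sequence[LinearModelFit], term: str) -> PooledEstimate:
    """Rubin-pool one coefficient across imputed-data fits."""
    est = [float(f.params[term]) for f in fits]
    var = [float(f.bse[term]) ** 2 for f in fits]
    return rubin_pool(est, var, df_complete=fits[0].df_resid)


# ---------------------------------------------------------------------------
# subgroup heterogeneity


@dataclass
class SubgroupSpec:
    """A two-way sample split: by threshold on a numeric column or by a
    level set of a categorical column."""

    name: str
    column: str
    threshold: float | None = None
    levels: Sequence[str] | None = None

    def split(self, cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if self.column not in cohort.columns:
            raise KeyError(f"split column {self.column!r} not in cohort")
        s = cohort[self.column]
        if self.threshold is not None:
            vals = s.to_numpy(dtype=float)
            a = vals < self.threshold
        elif self.levels is not None:
            a = s.isin(list(self.levels)).to_numpy()
        else:
            raise ValueError("SubgroupSpec needs a threshold or a level set")
        b = ~a
        if not a.any() or not b.any():
            raise ValueError(f"subgroup split {self.name!r} leaves an empty group")
        return a, b


@dataclass
class SubgroupContrast:
    name: str
    group_a: DecompositionResults
    group_b: DecompositionResults
    coefficient_table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"Subgroup contrast {self.name!r}: "
            f"n_a={self.group_a.ols.n}, n_b={self.group_b.ols.n}",
            f"C_a={self.group_a.concentration_index:.5f}, "
            f"C_b={self.group_b.concentration_index:.5f}",
        ]
        return "\n".join(lines)


def subgroup_contrast(
    cohort: pd.DataFrame,
    spec: SubgroupSpec,
    outcome: str,
    covariates: Sequence[str],
    ranking: str = "wealth",
    references: Mapping[str, str] | None = None,
    category_map: Mapping[str, str] | None = None,
    variant: str = "shifted_minmax",
) -> SubgroupContrast:
    """Run the fit/index/decomposition pipeline on both sides of a split.

    Covariates constant within a subgroup (e.g. the splitting variable) are
    dropped from that subgroup's model.  The coefficient table reports both
    groups side by side with the difference and its large-sample z value.
    """
    mask_a, mask_b = spec.split(cohort)
    results = []
    raw_fits = []
    for mask in (mask_a, mask_b):
        sub = cohort.loc[mask].reset_index(drop=True)
        usable = [
            c for c in covariates
            if c != spec.column and sub[c].nunique(dropna=True) > 1
        ]
        res = InequalityDecomposition(
            sub, outcome, usable, ranking=ranking, references=references,
            category_map=category_map, variant=variant,
        ).fit()
        results.append(res)
        # coefficients for the side-by-side table are on the original
        # outcome scale (the index variant only rescales within-group)
        raw_fits.append(fit_ols(sub, outcome, usable, references))
    a, b = results
    ta = raw_fits[0].marginal_effects()[["effect", "se"]].rename(
        columns={"effect": "effect_a", "se": "se_a"}
    )
    tb = raw_fits[1].marginal_effects()[["effect", "se"]].rename(
        columns={"effect": "effect_b", "se": "se_b"}
    )
    tab = ta.join(tb, how="outer")
    tab["difference"] = tab["effect_a"] - tab["effect_b"]
    tab["z"] = tab["difference"] / np.sqrt(tab["se_a"] ** 2 + tab["se_b"] ** 2)
    return SubgroupContrast(
        name=spec.name, group_a=a, group_b=b, coefficient_table=tab
    )
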