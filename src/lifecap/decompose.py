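"""Regression-based decomposition of concentration-index inequality.

For a linear model ``y = sum_k beta_k x_k + eps`` fitted with an intercept,
the concentration index of ``y`` splits algebraically into per-determinant
terms plus a residual:

    C = sum_k (beta_k xbar_k / mu) C_k + GC_eps / mu

where ``C_k`` is the concentration index of determinant ``x_k`` against the
same socioeconomic ranks and ``GC_eps = 2 cov_w(eps, r)`` is the generalized
concentration index of the residual.  Determinants are dummy-coded levels of
categorical life-course factors; a factor's contribution is the sum over its
levels and contributions roll up into the four life-course categories
(early-life, current socioeconomic, demographic, lifestyle).

The mediation contrast re-runs the decomposition without the hypothesized
mediators (current socioeconomic factors): the early-life share in the full
model is the *direct* share, the share in the reduced model the *total*
share, and their difference the share mediated through adult socioeconomic
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .concentration import (
    ConcentrationResult,
    _check_weights,
    _weighted_cov,
    concentration_index,
    fractional_rank,
    minmax_scale,
)

ADDITIVITY_TOL = 1e-10


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


# ---------------------------------------------------------------------------
# design construction and OLS


def build_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dummy-coded design matrix with intercept.

    Categorical covariates are expanded into one column per non-reference
    level, named ``covariate[level]``.  Numeric covariates enter as-is.
    Returns ``(X, info)`` where ``info`` maps each design column to its
    covariate and level.
    """
    references = dict(references or {})
    cols: dict[str, np.ndarray] = {"const": np.ones(len(cohort))}
    info_rows = [{"term": "const", "covariate": "const", "level": ""}]
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate {cov!r} not in cohort")
        s = cohort[cov]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            cat = s.astype("category")
            levels = list(cat.cat.categories)
            ref = references.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {cov!r}")
            for lvl in levels:
                if lvl == ref:
                    continue
                term = f"{cov}[{lvl}]"
                cols[term] = (s == lvl).to_numpy(dtype=float)
                info_rows.append({"term": term, "covariate": cov, "level": lvl})
        else:
            cols[cov] = s.to_numpy(dtype=float)
            info_rows.append({"term": cov, "covariate": cov, "level": ""})
    X = pd.DataFrame(cols, index=cohort.index)
    info = pd.DataFrame(info_rows).set_index("term")
    return X, info


@dataclass
class LinearModelFit:
    """A fitted linear capacity model with what the decomposition needs."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    conf_int: pd.DataFrame
    resid: np.ndarray
    X: pd.DataFrame
    info: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    outcome: str
    n: int
    rsquared: float
    df_resid: float

    @property
    def mu(self) -> float:
        return float(np.dot(self.weights, self.y) / self.weights.sum())

    @property
    def xbar(self) -> pd.Series:
        w = self.weights / self.weights.sum()
        return pd.Series(w @ self.X.to_numpy(), index=self.X.columns)

    def marginal_effects(self) -> pd.DataFrame:
        """Marginal effects at covariate means.

        For a linear model on dummy-coded covariates these coincide with
        the coefficients; the table is shaped like a published regression
        table (effect, 95% CI, raw p, Holm-adjusted p).
        """
        adj = holm_adjust(self.pvalues.drop("const").to_numpy())
        out = pd.DataFrame(
            {
                "covariate": self.info["covariate"],
                "level": self.info["level"],
                "effect": self.params,
                "se": self.bse,
                "ci_low": self.conf_int[0],
                "ci_high": self.conf_int[1],
                "p": self.pvalues,
            }
        ).drop(index="const")
        out["p_holm"] = adj.adjusted
        out["significant_holm"] = adj.reject
        return out

    def summary(self) -> str:
        me = self.marginal_effects()
        lines = [
            f"Linear capacity model: outcome={self.outcome!r}, n={self.n}, "
            f"R2={self.rsquared:.4f} (HC1 robust SEs)",
            f"{'term':<38}{'effect':>9}{'ci_low':>9}{'ci_high':>9}{'p_holm':>9}",
        ]
        for term, row in me.iterrows():
            lines.append(
                f"{term:<38}{row.effect:>9.3f}{row.ci_low:>9.3f}"
                f"{row.ci_high:>9.3f}{row.p_holm:>9.3g}"
            )
        return "\n".join(lines)


def fit_ols(
    cohort: pd.DataFrame,
    outcome: str | np.ndarray,
    covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
    weights: np.ndarray | None = None,
    cov_type: str = "HC1",
) -> LinearModelFit:
    """Weighted least squares of an outcome on dummy-coded covariates.

    Standard errors are heteroskedasticity-robust (HC1) by default;
    ``cov_type='nonrobust'`` gives the exact homoskedastic intervals
    appropriate for recovery experiments on the generator's errors.  An
    empty covariate list gives the intercept-only model.  Rank deficiency
    raises :class:`RankDeficientError` naming the collinear columns.
    """
    if isinstance(outcome, str):
        y = cohort[outcome].to_numpy(dtype=float)
        yname = outcome
    else:
        y = np.asarray(outcome, dtype=float)
        yname = "y"
    X, info = build_design(cohort, covariates, references)
    if np.isnan(y).any() or X.isna().to_numpy().any():
        raise ValueError("missing values in outcome or design; complete cases required")
    w = np.ones(len(y)) if weights is None else _check_weights(weights)

    Xm = X.to_numpy()
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        keep = list(range(Xm.shape[1]))
        for j in range(Xm.shape[1] - 1, 0, -1):
            trial = [k for k in keep if k != j]
            if np.linalg.matrix_rank(Xm[:, trial]) == rank:
                keep = trial
                bad.append(X.columns[j])
                if len(keep) == rank:
                    break
        raise RankDeficientError(
            f"design matrix rank deficient; collinear columns: {sorted(bad)}"
        )

    res = sm.WLS(y, X, weights=w).fit(
        cov_type=cov_type, use_t=cov_type == "nonrobust"
    )
    ci = res.conf_int()
    return LinearModelFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        cov_params=res.cov_params(),
        conf_int=pd.DataFrame(np.asarray(ci), index=X.columns),
        resid=np.asarray(res.resid, dtype=float),
        X=X,
        info=info,
        y=y,
        weights=w,
        outcome=yname,
        n=len(y),
        rsquared=float(res.rsquared),
        df_resid=float(res.df_resid),
    )


# ---------------------------------------------------------------------------
# decomposition


@dataclass
class DecompositionResult:
    """Per-determinant contributions to the concentration index."""

    table: pd.DataFrame  # one row per design column (minus intercept)
    total: float
    mu: float
    variant: str
    residual_contribution: float
    n: int
    category_map: dict[str, str] = field(default_factory=dict)

    @property
    def residual_share(self) -> float:
        return 100.0 * self.residual_contribution / self.total

    def contribution_of(self, covariates: Sequence[str]) -> float:
        mask = self.table["covariate"].isin(list(covariates))
        return float(self.table.loc[mask, "contribution"].sum())

    def share_of(self, covariates: Sequence[str]) -> float:
        return 100.0 * self.contribution_of(covariates) / self.total

    def category_shares(
        self, category_map: Mapping[str, str] | None = None
    ) -> pd.Series:
        """Percent share of C per life-course category (signed)."""
        cmap = dict(category_map or self.category_map)
        if not cmap:
            raise ValueError("no category map available")
        unmapped = set(self.table["covariate"]) - set(cmap)
        if unmapped:
            raise KeyError(f"determinants without category: {sorted(unmapped)}")
        cats = self.table["covariate"].map(cmap)
        shares = self.table.groupby(cats, sort=False)["share"].sum()
        shares.index.name = "category"
        return shares

    def summary(self) -> str:
        lines = [
            f"Concentration index decomposition (variant={self.variant!r}, "
            f"n={self.n})",
            f"total C = {self.total:.6f}, mu = {self.mu:.6f}, "
            f"residual share = {self.residual_share:.2f}%",
        ]
        if self.category_map:
            for cat, s in self.category_shares().items():
                lines.append(f"  {cat:<16} share = {s:7.2f}%")
        return "\n".join(lines)


def decompose(
    fit: LinearModelFit,
    ranks: np.ndarray,
    weights: np.ndarray | None = None,
    variant: str = "standard",
    category_map: Mapping[str, str] | None = None,
) -> DecompositionResult:
    """Wagstaff-style decomposition of the concentration index of the
    fitted outcome.

    The outcome in ``fit`` must already be on the scale the index is wanted
    on (for standardized scores, fit the model on the min-max scaled score
    and pass ``variant='shifted_minmax'`` as a label).  The additivity
    identity ``sum_k ctr_k + GC_eps/mu = C`` is asserted to 1e-10 before
    returning.
    """
    r = np.asarray(ranks, dtype=float)
    if r.shape[0] != fit.n:
        raise ValueError("ranks and fit cover different rows")
    w = fit.weights if weights is None else _check_weights(weights)
    mu = fit.mu
    if mu <= 0:
        raise ValueError(
            "outcome mean must be positive for the decomposition; rescale the "
            "outcome (shifted_minmax) first"
        )

    total = 2.0 * _weighted_cov(fit.y, r, w) / mu
    rows = []
    for term in fit.X.columns:
        if term == "const":
            continue
        x = fit.X[term].to_numpy()
        beta = float(fit.params[term])
        xbar = float(np.dot(w, x) / w.sum())
        cov_xr = _weighted_cov(x, r, w)
        ctr = 2.0 * beta * cov_xr / mu
        ck = 2.0 * cov_xr / xbar if xbar != 0 else np.nan
        rows.append(
            {
                "term": term,
                "covariate": fit.info.loc[term, "covariate"],
                "level": fit.info.loc[term, "level"],
                "beta": beta,
                "xbar": xbar,
                "elasticity": beta * xbar / mu,
                "determinant_index": ck,
                "contribution": ctr,
                "share": 100.0 * ctr / total if total != 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=[
            "covariate", "level", "beta", "xbar", "elasticity",
            "determinant_index", "contribution", "share",
        ]
    )
    residual = 2.0 * _weighted_cov(fit.resid, r, w) / mu
    gap = abs(float(table["contribution"].sum() if len(table) else 0.0) + residual - total)
    scale = max(1.0, abs(total))
    if gap > ADDITIVITY_TOL * scale * 100:
        raise AssertionError(
            f"decomposition additivity violated: |sum + residual - C| = {gap:g}"
        )
    return DecompositionResult(
        table=table,
        total=total,
        mu=mu,
        variant=variant,
        residual_contribution=residual,
        n=fit.n,
        category_map=dict(category_map or {}),
    )


def rollup_categories(
    result: DecompositionResult, category_map: Mapping[str, str]
) -> pd.Series:
    """Sum percent shares within each life-course category."""
    return result.category_shares(category_map)


# ---------------------------------------------------------------------------
# model-object facade


class InequalityDecomposition:
    """Decomposition of capacity inequality into life-course determinants.

    A statsmodels-style model object: construct from a cohort table, call
    :meth:`fit` to obtain a :class:`DecompositionResults` with the fitted
    regression, the concentration index and its decomposition.

    Parameters
    ----------
    cohort : DataFrame
        Participant table (complete cases on the used columns).
    outcome : str
        Column holding the capacity score to analyse.
    covariates : sequence of str
        Categorical determinants entering the regression.
    ranking : str
        Column used to build socioeconomic fractional ranks
        (default ``wealth``).
    references : mapping, optional
        Reference level per covariate (default: first category).
    category_map : mapping, optional
        Covariate -> life-course category for roll-ups.
    variant : str
        ``shifted_minmax`` (default; outcome min-max scaled to [0, 1] before
        fitting), ``standard`` (requires positive-mean outcome) or
        ``erreygers``.
    weights : str or array, optional
        Sampling weights.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        outcome: str,
        covariates: Sequence[str],
        ranking: str = "wealth",
        references: Mapping[str, str] | None = None,
        category_map: Mapping[str, str] | None = None,
        variant: str = "shifted_minmax",
        weights: str | np.ndarray | None = None,
    ) -> None:
        self.cohort = cohort
        self.outcome = outcome
        self.covariates = list(covariates)
        self.ranking = ranking
        self.references = dict(references or {})
        self.category_map = dict(category_map or {})
        self.variant = variant
        if isinstance(weights, str):
            self.weights = cohort[weights].to_numpy(dtype=float)
        elif weights is None:
            self.weights = np.ones(len(cohort))
        else:
            self.weights = _check_weights(weights)

    def _transformed_outcome(self) -> np.ndarray:
        y = self.cohort[self.outcome].to_numpy(dtype=float)
        if self.variant in ("shifted_minmax", "erreygers"):
            return minmax_scale(y)
        return y

    def fit(self) -> "DecompositionResults":
        yv = self._transformed_outcome()
        ranks = fractional_rank(
            self.cohort[self.ranking].to_numpy(dtype=float), self.weights
        )
        ols = fit_ols(
            self.cohort, yv, self.covariates, self.references, self.weights
        )
        ols.outcome = self.outcome
        dec = decompose(
            ols, ranks, self.weights, variant=self.variant,
            category_map=self.category_map,
        )
        if self.variant == "erreygers":
            # rescale all contributions by 4*mu so they sum to the
            # Erreygers corrected index
            f = 4.0 * dec.mu
            dec.table[["contribution", "share"]] = dec.table[
                ["contribution", "share"]
            ].to_numpy() * np.array([f, 1.0])
            dec.total *= f
            dec.residual_contribution *= f
        index = concentration_index(
            self.cohort[self.outcome].to_numpy(dtype=float), ranks,
            self.weights, self.variant,
        )
        return DecompositionResults(self, ols, dec, index, ranks)


class DecompositionResults:
    """Results of :class:`InequalityDecomposition.fit`."""

    def __init__(
        self,
        model: InequalityDecomposition,
        ols: LinearModelFit,
        decomposition: DecompositionResult,
        index: ConcentrationResult,
        ranks: np.ndarray,
    ) -> None:
        self.model = model
        self.ols = ols
        self.decomposition = decomposition
        self.index = index
        self.ranks = ranks

    @property
    def concentration_index(self) -> float:
        return self.index.value

    def marginal_effects(self) -> pd.DataFrame:
        return self.ols.marginal_effects()

    def category_shares(self) -> pd.Series:
        return self.decomposition.category_shares()

    def summary(self) -> str:
        return "\n".join(
            [
                self.ols.summary(),
                "",
                self.decomposition.summary(),
            ]
        )


# ---------------------------------------------------------------------------
# mediation by model exclusion


@dataclass
class MediationResult:
    """Direct vs total early-life shares of capacity inequality.

    ``direct_share`` is the early-life category share under the full model;
    ``total_share`` the share when the mediators (current socioeconomic
    factors) are excluded; ``indirect_share`` their difference, i.e. the
    part of early-life inequality operating through adult socioeconomic
    position.
    """

    direct_share: float
    total_share: float
    direct_ci: tuple[float, float] | None = None
    total_ci: tuple[float, float] | None = None
    indirect_ci: tuple[float, float] | None = None
    B: int | None = None

    @property
    def indirect_share(self) -> float:
        return self.total_share - self.direct_share

    def summary(self) -> str:
        def fmt(v, ci):
            s = f"{v:7.2f}%"
            if ci is not None:
                s += f"  (95% CI {ci[0]:.2f} to {ci[1]:.2f})"
            return s

        return "\n".join(
            [
                "Mediation of early-life inequality through current SES",
                f"  direct share   {fmt(self.direct_share, self.direct_ci)}",
                f"  total share    {fmt(self.total_share, self.total_ci)}",
                f"  indirect share {fmt(self.indirect_share, self.indirect_ci)}",
            ]
        )


def _early_life_share(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    group_covariates: Sequence[str],
    ranking: str,
    references: Mapping[str, str] | None,
    variant: str,
    weights: np.ndarray | None,
) -> float:
    res = InequalityDecomposition(
        cohort, outcome, covariates, ranking=ranking, references=references,
        variant=variant, weights=weights,
    ).fit()
    return res.decomposition.share_of(
        [c for c in group_covariates if c in covariates]
    )


def mediation_contrast(
    cohort: pd.DataFrame,
    outcome: str,
    full_covariates: Sequence[str],
    mediators: Sequence[str],
    group_covariates: Sequence[str],
    ranking: str = "wealth",
    references: Mapping[str, str] | None = None,
    variant: str = "shifted_minmax",
    weights: np.ndarray | None = None,
    B: int = 0,
    seed: int = 0,
) -> MediationResult:
    """Mediation analysis by model exclusion.

    Runs the decomposition with the full covariate set and again with the
    ``mediators`` removed, on identical rows, and contrasts the share of
    inequality attributed to ``group_covariates`` (the early-life factors).
    With ``B > 0`` a paired participant-level bootstrap resamples once per
    replicate and reruns both models, so direct and total shares are
    correlated within replicate.
    """
    full = list(full_covariates)
    meds = list(mediators)
    missing = [m for m in meds if m not in full]
    if missing:
        raise ValueError(f"mediators not in covariate set: {missing}")
    reduced = [c for c in full if c not in meds]

    warr = None if weights is None else _check_weights(weights)

    def both(df: pd.DataFrame, w: np.ndarray | None) -> tuple[float, float]:
        direct = _early_life_share(
            df, outcome, full, group_covariates, ranking, references, variant, w
        )
        total = _early_life_share(
            df, outcome, reduced, group_covariates, ranking, references, variant, w
        )
        return direct, total

    direct, total = both(cohort, warr)
    result = MediationResult(direct_share=direct, total_share=total)
    if B > 0:
        rng = np.random.default_rng(seed)
        n = len(cohort)
        d = np.empty(B)
        t = np.empty(B)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                d[b], t[b] = both(
                    cohort.iloc[idx].reset_index(drop=True),
                    None if warr is None else warr[idx],
                )
            except (RankDeficientError, ValueError):
                d[b] = t[b] = np.nan
        ok = np.isfinite(d) & np.isfinite(t)
        q = lambda v: tuple(np.quantile(v[ok], [0.025, 0.975]))
        result.direct_ci = q(d)
        result.total_ci = q(t)
        result.indirect_ci = q(t - d)
        result.B = B
    return result


# ---------------------------------------------------------------------------
# multiplicity adjustment and bivariate screening


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_adjust(pvalues: Sequence[float], alpha: float = 0.05) -> AdjustedPValues:
    """Holm-Bonferroni step-down adjustment.

    Sorted ascending, adjusted ``p_(i) = max_{j<=i} (m - j + 1) p_(j)``
    capped at 1; hypotheses are rejected while the adjusted p stays at or
    below alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return AdjustedPValues(raw=p, adjusted=adjusted, reject=reject, alpha=alpha)


def spearman_matrix(
    cohort: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Pairwise Spearman correlations between ordinal-codable columns.

    Categorical columns enter via their (ordered) level codes.  Constant
    columns give NaN entries and a warning-carrying matrix rather than a
    silent zero.
    """
    import warnings

    mat = np.empty((len(cohort), len(columns)))
    for j, col in enumerate(columns):
        s = cohort[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            mat[:, j] = s.cat.codes.to_numpy(dtype=float)
        else:
            mat[:, j] = s.to_numpy(dtype=float)
    k = len(columns)
    out = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            if np.all(mat[:, a] == mat[0, a]) or np.all(mat[:, b] == mat[0, b]):
                warnings.warn(
                    f"constant column in Spearman pair ({columns[a]!r}, "
                    f"{columns[b]!r}); correlation undefined"
                )
                rho = np.nan
            else:
                rho = sps.spearmanr(mat[:, a], mat[:, b]).statistic
            out[a, b] = out[b, a] = rho
    return pd.DataFrame(out, index=list(columns), columns=list(columns))
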