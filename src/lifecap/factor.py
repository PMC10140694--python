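"""Second-order confirmatory factor model for intrinsic capacity.

The measurement model has five correlated subdomain factors (locomotion,
cognitive, vitality, sensory, psychological), each measured by its block of
indicators, and a single overall capacity factor loading on the subdomains:

    x = Lambda eta_sub + e,        e ~ N(0, Theta) diagonal
    eta_sub = lambda eta + delta,  delta ~ N(0, Psi) diagonal
    eta ~ N(0, phi)

so the implied indicator covariance is

    Sigma(theta) = Lambda (phi lambda lambda' + Psi) Lambda' + Theta.

Parameters are estimated by minimizing the maximum-likelihood discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p

with the first indicator of each subdomain as the marker (loading fixed at
1), the first subdomain as the marker of the overall factor, and the overall
factor variance free.  Variances are optimized on the log scale with an
analytic gradient and a small fixed multi-start.

Participants are scored with regression (Thurstone) factor scores and the
scores standardized to mean 0 and standard deviation 1 on the scored
sample, larger values meaning greater capacity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .config import FactorStructure

_LOGV_LO, _LOGV_HI = -12.0, 6.0


class FactorModelError(RuntimeError):
    pass


def _sample_cov(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    return xc.T @ xc / x.shape[0]


class _Parameterization:
    """Packs/unpacks the free parameter vector.

    Order: free first-order loadings (non-marker indicators), free
    second-order loadings (all but the first subdomain), log overall
    variance, log disturbances (5), log uniquenesses (p).
    """

    def __init__(self, structure: FactorStructure):
        self.structure = structure
        self.indicators = list(structure.indicators)
        self.subdomains = list(structure.subdomains)
        self.p = len(self.indicators)
        self.d = len(self.subdomains)
        self.sub_of = np.array(
            [self.subdomains.index(structure.subdomain_of(i)) for i in self.indicators]
        )
        self.markers = [structure.marker(s) for s in self.subdomains]
        self.free_load_idx = [
            j for j, ind in enumerate(self.indicators) if ind not in self.markers
        ]
        self.n_free_load = len(self.free_load_idx)
        self.n_free_lam = self.d - 1
        self.n_params = self.n_free_load + self.n_free_lam + 1 + self.d + self.p

    def unpack(self, theta: np.ndarray):
        k = 0
        L = np.zeros((self.p, self.d))
        for j in range(self.p):
            L[j, self.sub_of[j]] = 1.0
        for j in self.free_load_idx:
            L[j, self.sub_of[j]] = theta[k]
            k += 1
        lam = np.ones(self.d)
        lam[1:] = theta[k : k + self.n_free_lam]
        k += self.n_free_lam
        phi = np.exp(theta[k])
        k += 1
        psi = np.exp(theta[k : k + self.d])
        k += self.d
        th = np.exp(theta[k : k + self.p])
        return L, lam, phi, psi, th

    def start(self, structure: FactorStructure, s_diag: np.ndarray) -> np.ndarray:
        x0 = []
        for j in self.free_load_idx:
            x0.append(0.8)
        x0.extend([0.8] * self.n_free_lam)
        x0.append(0.0)  # log phi
        x0.extend([np.log(0.5)] * self.d)
        x0.extend(list(np.log(np.clip(s_diag / 2.0, 1e-3, None))))
        return np.array(x0)


def _implied(L, lam, phi, psi, th):
    Phi = phi * np.outer(lam, lam) + np.diag(psi)
    return L @ Phi @ L.T + np.diag(th), Phi


def _discrepancy_and_grad(theta, par: _Parameterization, S, logdet_S):
    L, lam, phi, psi, th = par.unpack(theta)
    Sigma, Phi = _implied(L, lam, phi, psi, th)
    try:
        cf = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    logdet = 2.0 * np.sum(np.log(np.diag(cf)))
    Sinv = np.linalg.inv(Sigma)
    F = logdet + np.trace(S @ Sinv) - logdet_S - par.p

    # dF = tr(A dSigma), A = Sigma^-1 (Sigma - S) Sigma^-1
    A = Sinv @ (Sigma - S) @ Sinv
    grad = np.empty_like(theta)
    k = 0
    ALPhi = A @ L @ Phi
    for j in par.free_load_idx:
        grad[k] = 2.0 * ALPhi[j, par.sub_of[j]]
        k += 1
    LtAL = L.T @ A @ L
    glam = 2.0 * phi * (LtAL @ lam)
    grad[k : k + par.n_free_lam] = glam[1:]
    k += par.n_free_lam
    grad[k] = phi * float(lam @ LtAL @ lam)  # d/d log phi
    k += 1
    grad[k : k + par.d] = np.diag(LtAL) * psi
    k += par.d
    grad[k : k + par.p] = np.diag(A) * th
    return F, grad


@dataclass
class FittedFactorModel:
    """Estimated second-order measurement model."""

    structure: FactorStructure
    loadings: pd.Series  # first-order, indexed by indicator
    second_order: pd.Series  # indexed by subdomain
    overall_variance: float
    disturbances: pd.Series
    uniquenesses: pd.Series
    discrepancy: float
    converged: bool
    n: int
    mean_: np.ndarray  # indicator means of the fitting sample

    def implied_covariance(self) -> np.ndarray:
        par = _Parameterization(self.structure)
        L = np.zeros((par.p, par.d))
        for j, ind in enumerate(par.indicators):
            L[j, par.sub_of[j]] = self.loadings[ind]
        Sigma, _ = _implied(
            L,
            self.second_order.to_numpy(),
            self.overall_variance,
            self.disturbances.to_numpy(),
            self.uniquenesses.to_numpy(),
        )
        return Sigma

    def to_json(self, path: str) -> None:
        payload = {
            "structure": self.structure.to_dict(),
            "loadings": self.loadings.to_dict(),
            "second_order": self.second_order.to_dict(),
            "overall_variance": self.overall_variance,
            "disturbances": self.disturbances.to_dict(),
            "uniquenesses": self.uniquenesses.to_dict(),
            "discrepancy": self.discrepancy,
            "converged": self.converged,
            "n": self.n,
            "mean": list(self.mean_),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FittedFactorModel":
        with open(path) as fh:
            d = json.load(fh)
        fs = FactorStructure.from_dict(d["structure"])
        return cls(
            structure=fs,
            loadings=pd.Series(d["loadings"]).loc[list(fs.indicators)],
            second_order=pd.Series(d["second_order"]).loc[list(fs.subdomains)],
            overall_variance=float(d["overall_variance"]),
            disturbances=pd.Series(d["disturbances"]).loc[list(fs.subdomains)],
            uniquenesses=pd.Series(d["uniquenesses"]).loc[list(fs.indicators)],
            discrepancy=float(d["discrepancy"]),
            converged=bool(d["converged"]),
            n=int(d["n"]),
            mean_=np.asarray(d["mean"], dtype=float),
        )


class CapacityFactorModel:
    """Second-order CFA of capacity indicators, statsmodels-style.

    Parameters
    ----------
    data : DataFrame
        Participant table containing all indicator columns (numeric,
        complete cases, coded so larger = better).
    structure : FactorStructure
        Subdomain/indicator assignment.
    """

    def __init__(self, data: pd.DataFrame, structure: FactorStructure):
        missing = [c for c in structure.indicators if c not in data.columns]
        if missing:
            raise KeyError(f"indicator columns absent from data: {missing}")
        self.structure = structure
        self.x = data[list(structure.indicators)].to_numpy(dtype=float)
        if np.isnan(self.x).any():
            raise ValueError(
                "missing values among indicators; supply complete cases or "
                "impute first"
            )
        variances = self.x.var(axis=0)
        dead = [
            structure.indicators[j] for j in np.flatnonzero(variances <= 0)
        ]
        if dead:
            raise ValueError(f"indicators with zero variance: {dead}")
        self.S = _sample_cov(self.x)
        sign, logdet_S = np.linalg.slogdet(self.S)
        if sign <= 0 or not np.isfinite(logdet_S):
            raise FactorModelError(
                "sample covariance of the indicators is not positive definite"
            )
        self.logdet_S = logdet_S

    def fit(self, n_starts: int = 3, seed: int = 0) -> "CapacityFactorResults":
        """Minimize the ML discrepancy; fixed-seed multi-start L-BFGS."""
        par = _Parameterization(self.structure)
        x0 = par.start(self.structure, np.diag(self.S))
        rng = np.random.default_rng(seed)
        bounds = (
            [(-10.0, 10.0)] * (par.n_free_load + par.n_free_lam)
            + [(_LOGV_LO, _LOGV_HI)] * (1 + par.d + par.p)
        )
        best = None
        for s in range(max(1, n_starts)):
            start = x0 if s == 0 else x0 + 0.3 * rng.standard_normal(x0.size)
            res = optimize.minimize(
                _discrepancy_and_grad,
                start,
                args=(par, self.S, self.logdet_S),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        L, lam, phi, psi, th = par.unpack(best.x)
        converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-5)
        fitted = FittedFactorModel(
            structure=self.structure,
            loadings=pd.Series(
                L[np.arange(par.p), par.sub_of], index=par.indicators
            ),
            second_order=pd.Series(lam, index=par.subdomains),
            overall_variance=float(phi),
            disturbances=pd.Series(psi, index=par.subdomains),
            uniquenesses=pd.Series(th, index=par.indicators),
            discrepancy=float(best.fun),
            converged=converged,
            n=self.x.shape[0],
            mean_=self.x.mean(axis=0),
        )
        return CapacityFactorResults(self, fitted)


class CapacityFactorResults:
    """Results of :meth:`CapacityFactorModel.fit`."""

    def __init__(self, model: CapacityFactorModel, fitted: FittedFactorModel):
        self.model = model
        self.fitted = fitted

    @property
    def discrepancy(self) -> float:
        return self.fitted.discrepancy

    @property
    def converged(self) -> bool:
        return self.fitted.converged

    def scores(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        return score_participants(self.fitted, data) if data is not None else (
            score_participants(
                self.fitted,
                pd.DataFrame(
                    self.model.x, columns=list(self.fitted.structure.indicators)
                ),
            )
        )

    def summary(self) -> str:
        f = self.fitted
        lines = [
            f"Second-order capacity factor model (n={f.n}, "
            f"discrepancy={f.discrepancy:.6f}, converged={f.converged})",
            f"{'indicator':<26}{'subdomain':<15}{'loading':>8}{'unique':>8}",
        ]
        for ind in f.structure.indicators:
            lines.append(
                f"{ind:<26}{f.structure.subdomain_of(ind):<15}"
                f"{f.loadings[ind]:>8.3f}{f.uniquenesses[ind]:>8.3f}"
            )
        lines.append(
            f"{'subdomain':<26}{'2nd-order':>9}{'disturb':>9}"
            f"   (overall var {f.overall_variance:.3f})"
        )
        for d in f.structure.subdomains:
            lines.append(
                f"{d:<26}{f.second_order[d]:>9.3f}{f.disturbances[d]:>9.3f}"
            )
        return "\n".join(lines)


def fit_cfa(
    cohort: pd.DataFrame,
    structure: FactorStructure,
    n_starts: int = 3,
    seed: int = 0,
) -> FittedFactorModel:
    """Fit the second-order capacity model; functional facade."""
    return CapacityFactorModel(cohort, structure).fit(n_starts, seed).fitted


def score_participants(
    model: FittedFactorModel, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Regression (Thurstone) factor scores, standardized per column.

    Returns a DataFrame with an ``overall`` column and one column per
    subdomain; each has sample mean 0 and standard deviation 1.
    """
    if not model.converged:
        raise FactorModelError("cannot score from a non-converged model")
    fs = model.structure
    x = cohort[list(fs.indicators)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing indicator values; complete cases required")
    par = _Parameterization(fs)
    L = np.zeros((par.p, par.d))
    for j in range(par.p):
        L[j, par.sub_of[j]] = model.loadings[par.indicators[j]]
    lam = model.second_order.to_numpy()
    phi = model.overall_variance
    Phi = phi * np.outer(lam, lam) + np.diag(model.disturbances.to_numpy())
    Sigma = L @ Phi @ L.T + np.diag(model.uniquenesses.to_numpy())
    # Cov(x, f) for f = (overall, subdomains): indicators relate to the
    # factors only through their subdomain latents
    C = np.empty((par.d, par.d + 1))
    C[:, 0] = phi * lam
    C[:, 1:] = Phi
    cov_xf = L @ C
    xc = x - x.mean(axis=0)
    raw = xc @ np.linalg.solve(Sigma, cov_xf)
    sd = raw.std(axis=0)
    if np.any(sd <= 0):
        raise FactorModelError("degenerate factor scores (zero variance)")
    scores = (raw - raw.mean(axis=0)) / sd
    return pd.DataFrame(
        scores, columns=["overall"] + list(fs.subdomains), index=cohort.index
    )
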