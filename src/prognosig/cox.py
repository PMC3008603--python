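"""Cox proportional-hazards regression: partial-likelihood Newton fit and
Wald inference.

This is the workhorse behind probe screening, the two-metagene model and
the multivariate risk-group reports.  The model is the standard
semiparametric proportional-hazards regression

    h(t | x) = h0(t) * exp(x' beta),

fit by maximizing the partial likelihood with either the Efron (default)
or Breslow treatment of tied event times.  Estimator conventions follow
``lifelines``/``survival``: hazard ratio = exp(beta), 95% CI =
exp(beta +/- 1.96 se), two-sided Wald p from beta/se against the standard
normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _coxkernels as _k
from .containers import SurvivalData
from .exceptions import ConvergenceError

Z975 = 1.959963984540054  # standard-normal 97.5th percentile


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit."""

    coefficients: pd.Series
    standard_errors: pd.Series
    log_partial_likelihood: float
    converged: bool
    ties_method: str
    n: int
    n_events: int
    n_iter: int
    covariance: pd.DataFrame

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("hazard_ratio")

    @property
    def ci95(self) -> pd.DataFrame:
        lo = np.exp(self.coefficients - Z975 * self.standard_errors)
        hi = np.exp(self.coefficients + Z975 * self.standard_errors)
        return pd.DataFrame({"low": lo, "high": hi})

    @property
    def wald_p(self) -> pd.Series:
        z = self.coefficients / self.standard_errors
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(z)), index=self.coefficients.index, name="p"
        )

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "hazard_ratio": self.hazard_ratios,
                "hr_ci_low": ci["low"],
                "hr_ci_high": ci["high"],
                "p": self.wald_p,
            }
        )


def _prepare(data: SurvivalData):
    if data.n_events < 1:
        raise ValueError("Cox fit requires at least one event")
    X = data.covariates.to_numpy(dtype=float)
    for name in data.covariates.columns:
        col = data.covariates[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"constant covariate {name!r}")
    order = np.argsort(data.times, kind="stable")
    return (
        np.ascontiguousarray(X[order]),
        np.ascontiguousarray(data.times[order]),
        np.ascontiguousarray(data.events[order].astype(np.int64)),
    )


def fit_cox(
    data: SurvivalData,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
    initial_beta: np.ndarray | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    data
        Times, 0/1 event indicators and a named covariate matrix.
    ties
        ``"efron"`` (default) or ``"breslow"`` handling of tied event
        times; identical when there are no ties.
    tol
        Convergence tolerance on the maximum coefficient change.

    Raises
    ------
    ConvergenceError
        On monotone separation (a coefficient diverging), naming the
        offending covariate.
    ValueError
        For a constant covariate or a dataset without events.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    names = list(data.covariates.columns)
    p = len(names)
    X, t, e = _prepare(data)
    if p >= data.n_events:
        warnings.warn(
            f"{p} covariates with only {data.n_events} events; "
            "estimates may be unstable",
            stacklevel=2,
        )
    beta0 = np.zeros(p) if initial_beta is None else np.asarray(initial_beta, float)
    beta, ll, info, code, n_iter = _k.newton_cox(
        X, t, e, beta0, ties == "efron", max_iter, tol
    )
    if code == 2:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"Cox fit diverged (monotone separation suspected) on covariate {worst!r}"
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        coefficients=pd.Series(beta, index=names, name="coef"),
        standard_errors=pd.Series(se, index=names, name="se"),
        log_partial_likelihood=float(ll),
        converged=(code == 0),
        ties_method=ties,
        n=data.n,
        n_events=data.n_events,
        n_iter=int(n_iter),
        covariance=pd.DataFrame(cov, index=names, columns=names),
    )


def wald_test(fit: CoxFit, covariate: str) -> float:
    """Two-sided Wald p-value for one covariate of a converged fit."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    se = fit.standard_errors[covariate]
    if se == 0:
        raise ValueError(f"zero standard error for covariate {covariate!r}")
    z = fit.coefficients[covariate] / se
    return float(2.0 * stats.norm.sf(abs(z)))


def score_test_chi2(data: SurvivalData, ties: str = "efron") -> float:
    """Score-test chi-square at beta = 0 (log-rank equivalent for one
    binary covariate without ties)."""
    X, t, e = _prepare(data)
    return float(_k.cox_score_test(X, t, e, ties == "efron"))
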