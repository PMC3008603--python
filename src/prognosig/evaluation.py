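"""Survival evaluation of risk-group predictions: Kaplan-Meier curves,
log-rank tests, stratified risk-group tables and multivariate Cox
reports.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
``lifelines``; hazard ratios are computed with the package's own Cox
fitter (a one-covariate unadjusted fit for the HR printed beside a
log-rank p, the full multivariate fit for the adjusted report).  The
"5-year" horizon is 60 months: subjects still event-free beyond it are
censored at 60 for horizon summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import ClinicalTable, SurvivalData
from .cox import CoxFit, fit_cox
from .exceptions import ConvergenceError

DEFAULT_HORIZON_MONTHS = 60.0


def truncate_follow_up(times, events, horizon: float):
    """Censor at the horizon: times beyond it become (horizon, censored)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, e)


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S-hat at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events, horizon_months: float | None = None) -> KMCurve:
    """Kaplan-Meier estimate, optionally truncated at a horizon."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if horizon_months is not None:
        t, e = truncate_follow_up(t, e, horizon_months)
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table
    tab = tab[tab["removed"] > 0]  # drop lifelines' synthetic baseline row
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        event_times=tab.index.to_numpy(float),
        survival=surv.reindex(tab.index).to_numpy(float),
        at_risk=tab["at_risk"].to_numpy(int),
        events=tab["observed"].to_numpy(int),
        n=len(t),
    )


@dataclass
class GroupComparison:
    """Two-group log-rank result with the companion unadjusted HR."""

    chi_square: float
    p_value: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    group_sizes: dict
    survival_at_horizon: dict
    horizon: float | None


def logrank_test(
    times, events, group_labels, horizon_months: float | None = None,
    levels=None,
) -> GroupComparison:
    """Two-group log-rank chi-square (1 df) plus an unadjusted Cox HR.

    The hazard ratio is for the second group level relative to the
    first (``levels`` defaults to sorted order; pass e.g.
    ``("low", "high")`` for the high-vs-low HR), from a one-covariate
    Cox fit on group membership - the standard pairing of a log-rank p
    with an HR and CI on a Kaplan-Meier panel.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    if levels is None:
        levels = sorted(pd.unique(g).tolist())
    else:
        levels = list(levels)
        if set(levels) != set(pd.unique(g).tolist()):
            raise ValueError("levels must name exactly the observed groups")
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {levels}")
    if e.sum() < 1:
        raise ValueError("log-rank needs at least one event")
    if horizon_months is not None:
        t, e = truncate_follow_up(t, e, horizon_months)
    m0, m1 = (g == levels[0]), (g == levels[1])
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    indicator = (g == levels[1]).astype(float)
    try:
        fit = fit_cox(SurvivalData(t, e, pd.DataFrame({"group": indicator})))
        hr = float(fit.hazard_ratios["group"])
        ci = fit.ci95.loc["group"]
        hr_ci = (float(ci["low"]), float(ci["high"]))
    except ConvergenceError:
        # e.g. one group without any event: the HR is not estimable,
        # though the log-rank p remains valid
        hr, hr_ci = float("nan"), (float("nan"), float("nan"))
    return GroupComparison(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        hazard_ratio=hr,
        hr_ci95=hr_ci,
        group_sizes={lv: int(m.sum()) for lv, m in zip(levels, (m0, m1))},
        survival_at_horizon={
            lv: kaplan_meier(t[m], e[m]).survival_at(
                horizon_months if horizon_months is not None else t.max()
            )
            for lv, m in zip(levels, (m0, m1))
        },
        horizon=horizon_months,
    )


def logrank_chi2(times, events, mask_group1) -> float:
    """Closed-form two-group log-rank chi-square (tie-corrected
    hypergeometric variance).

    A compact implementation used where many statistics must be computed
    quickly (e.g. permutation nulls); cross-checked against lifelines.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(mask_group1, bool)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    obs_minus_exp = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        at_risk = n - i
        at_risk1 = int(g[i:].sum())
        d = int(e[i: j + 1].sum())
        d1 = int(e[i: j + 1][g[i: j + 1]].sum())
        if d > 0:
            exp1 = d * at_risk1 / at_risk
            obs_minus_exp += d1 - exp1
            if at_risk > 1:
                var += (
                    d * (at_risk1 / at_risk)
                    * (1 - at_risk1 / at_risk)
                    * (at_risk - d) / (at_risk - 1)
                )
        i = j + 1
    return float(obs_minus_exp ** 2 / var) if var > 0 else 0.0


def risk_group_table(
    predictions,
    clinical: ClinicalTable,
    strata: str = "stage",
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
) -> pd.DataFrame:
    """Per-stratum, per-risk-group survival summary.

    One row per (stratum, risk group): group size, percent of the whole
    series, Kaplan-Meier survival at the horizon (percent) and number of
    events; the within-stratum two-group log-rank p is repeated on both
    of the stratum's rows (NaN when the stratum contains one group only).
    """
    pred = pd.DataFrame([p.as_row() for p in predictions]).set_index("sample_id")
    clin = clinical.subset(pred.index.tolist())
    df = pred.join(clin.data[["time_months", "event"] +
                             ([strata] if strata else [])])
    total = len(df)
    rows = []
    strat_values = sorted(df[strata].dropna().unique()) if strata else [None]
    for sv in strat_values:
        sub = df if sv is None else df[df[strata] == sv]
        groups = sorted(sub["risk_group"].unique())
        if len(groups) == 2:
            cmp_ = logrank_test(
                sub["time_months"], sub["event"], sub["risk_group"],
                horizon_months=horizon_months,
            )
            p = cmp_.p_value
        else:
            p = np.nan
        for rg in groups:
            gsub = sub[sub["risk_group"] == rg]
            t, e = truncate_follow_up(
                gsub["time_months"], gsub["event"], horizon_months
            )
            km = kaplan_meier(t, e)
            rows.append(
                {
                    strata or "stratum": sv,
                    "risk_group": rg,
                    "n": len(gsub),
                    "percent_of_series": 100.0 * len(gsub) / total,
                    f"survival_{int(horizon_months)}m_pct":
                        100.0 * km.survival_at(horizon_months),
                    "events": int(e.sum()),
                    "logrank_p": p,
                }
            )
    return pd.DataFrame(rows)


def multivariate_report(
    clinical: ClinicalTable,
    predictions,
    covariates=("age_years", "gender", "grade", "stage",
                "adj_chemo", "adj_radio"),
    ties: str = "efron",
) -> tuple[pd.DataFrame, CoxFit]:
    """Adjusted Cox report: clinical covariates plus the risk group.

    Builds one multivariate Cox fit with the requested covariates (those
    present and varying; gender is coded male=1) and the binary risk
    group (high=1), returning the per-covariate p / HR / CI table.
    Collinear covariate pairs raise an error naming the pair.
    """
    pred = pd.DataFrame([p.as_row() for p in predictions]).set_index("sample_id")
    clin = clinical.subset(pred.index.tolist())
    design = {}
    for cov in covariates:
        if cov not in clin.data.columns:
            continue
        col = clin.data[cov]
        if cov == "gender":
            if col.isin(["unknown"]).all():
                continue
            design["gender_male"] = (col == "male").astype(float)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            if vals.isna().all():
                continue
            design[cov] = vals
    design["risk_group_high"] = (pred["risk_group"] == "high").astype(float)
    X = pd.DataFrame(design, index=clin.data.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {bad}")
    varying = X.columns[X.nunique() > 1]
    X = X[varying]
    corr = X.corr().to_numpy()
    p = corr.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValueError(
                    f"collinear covariates: {X.columns[i]!r} and {X.columns[j]!r}"
                )
    fit = fit_cox(SurvivalData(clin.times, clin.events, X), ties=ties)
    return fit.summary(), fit
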