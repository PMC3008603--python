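"""Numba kernels for the Cox partial-likelihood Newton-Raphson fitter.

The probe screen refits a small multivariate Cox model once per probe and
once per leave-one-out round (~10^5 fits on a realistic cohort), so the
inner loop is JIT-compiled.  All kernels expect rows already sorted by
ascending follow-up time; tied times form Efron/Breslow groups discovered
on the fly by scanning for equal adjacent times.

Return codes from :func:`newton_cox`:

* 0 - converged (max coefficient change below ``tol``)
* 1 - hit ``max_iter`` without meeting the tolerance
* 2 - divergence / monotone separation (|beta| > 20 or non-finite
  likelihood that step-halving could not rescue)
"""

from __future__ import annotations

import numpy as np
from numba import njit

SEPARATION_BETA = 20.0


@njit(cache=True)
def cox_stats(X, time, event, beta, efron):
    """Log partial likelihood, score vector and information matrix.

    One backward pass over the (time-ascending) data accumulates the
    risk-set sums S0, S1, S2; tied event times are handled with the Efron
    correction (``efron=True``) or Breslow (``efron=False``).  With no
    ties the two coincide.
    """
    n, p = X.shape
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for k in range(p):
            s += X[i, k] * beta[k]
        eta[i] = s
    # the partial likelihood is invariant to a common shift of eta;
    # shift by the max to keep exp() finite
    m = eta[0]
    for i in range(1, n):
        if eta[i] > m:
            m = eta[i]
    w = np.exp(eta - m)

    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    tS1 = np.zeros(p)
    tS2 = np.zeros((p, p))
    sum_x_ev = np.zeros(p)

    i = n - 1
    while i >= 0:
        j = i
        while j - 1 >= 0 and time[j - 1] == time[i]:
            j -= 1
        # add the whole tie group [j, i] to the risk set, collecting the
        # event members' contributions for the Efron correction
        tS0 = 0.0
        for a in range(p):
            tS1[a] = 0.0
            sum_x_ev[a] = 0.0
            for b in range(p):
                tS2[a, b] = 0.0
        d = 0
        sum_eta_ev = 0.0
        for k in range(j, i + 1):
            wk = w[k]
            S0 += wk
            for a in range(p):
                S1[a] += wk * X[k, a]
                for b in range(p):
                    S2[a, b] += wk * X[k, a] * X[k, b]
            if event[k] == 1:
                d += 1
                sum_eta_ev += eta[k] - m
                tS0 += wk
                for a in range(p):
                    tS1[a] += wk * X[k, a]
                    sum_x_ev[a] += X[k, a]
                    for b in range(p):
                        tS2[a, b] += wk * X[k, a] * X[k, b]
        if d > 0:
            ll += sum_eta_ev
            for a in range(p):
                U[a] += sum_x_ev[a]
            for l in range(d):
                f = l / d if efron else 0.0
                denom = S0 - f * tS0
                ll -= np.log(denom)
                for a in range(p):
                    xb_a = (S1[a] - f * tS1[a]) / denom
                    U[a] -= xb_a
                    for b in range(p):
                        xb_b = (S1[b] - f * tS1[b]) / denom
                        I[a, b] += (S2[a, b] - f * tS2[a, b]) / denom - xb_a * xb_b
        i = j - 1
    return ll, U, I


@njit(cache=True)
def newton_cox(X, time, event, beta0, efron, max_iter, tol):
    """Maximize the Cox partial likelihood by safeguarded Newton-Raphson.

    Step-halving keeps the log partial likelihood monotone non-decreasing
    across accepted steps.  Returns
    ``(beta, loglik, information, code, n_iter)``.
    """
    p = X.shape[1]
    beta = beta0.copy()
    ll, U, I = cox_stats(X, time, event, beta, efron)
    if not np.isfinite(ll):
        beta = np.zeros(p)
        ll, U, I = cox_stats(X, time, event, beta, efron)
    code = 1
    it = 0
    for it in range(1, max_iter + 1):
        delta = np.linalg.solve(I, U)
        step = 1.0
        accepted = False
        for _ in range(40):
            cand = beta + step * delta
            ll_new, U_new, I_new = cox_stats(X, time, event, cand, efron)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            code = 2
            break
        beta = cand
        ll, U, I = ll_new, U_new, I_new
        bmax = 0.0
        dmax = 0.0
        for a in range(p):
            if abs(beta[a]) > bmax:
                bmax = abs(beta[a])
            if abs(step * delta[a]) > dmax:
                dmax = abs(step * delta[a])
        if bmax > SEPARATION_BETA or not np.isfinite(ll):
            code = 2
            break
        if dmax < tol:
            code = 0
            break
    return beta, ll, I, code, it


@njit(cache=True)
def screen_kernel(expr, X_clin, time, event, beta_clin, efron, max_iter, tol):
    """Fit one Cox model per probe: {probe expression} + clinical covariates.

    ``expr`` is (n_samples, n_probes) sorted by ascending time along axis
    0, ``X_clin`` the shared clinical covariates.  Each fit warm-starts
    from the clinical-only solution ``beta_clin`` with the probe term at
    zero.  Returns per-probe coefficient, standard error, convergence
    code and iteration count.
    """
    n, G = expr.shape
    q = X_clin.shape[1]
    p = q + 1
    betas = np.full(G, np.nan)
    ses = np.full(G, np.nan)
    codes = np.zeros(G, dtype=np.int64)
    iters = np.zeros(G, dtype=np.int64)
    X = np.zeros((n, p))
    for i in range(n):
        for k in range(q):
            X[i, 1 + k] = X_clin[i, k]
    beta0 = np.zeros(p)
    for k in range(q):
        beta0[1 + k] = beta_clin[k]
    for g in range(G):
        for i in range(n):
            X[i, 0] = expr[i, g]
        beta, ll, I, code, it = newton_cox(X, time, event, beta0, efron, max_iter, tol)
        codes[g] = code
        iters[g] = it
        if code != 2:
            cov = np.linalg.inv(I)
            if cov[0, 0] > 0:
                betas[g] = beta[0]
                ses[g] = np.sqrt(cov[0, 0])
            else:
                codes[g] = 2
    return betas, ses, codes, iters


@njit(cache=True)
def cox_score_test(X, time, event, efron):
    """Score (Rao) chi-square at beta = 0.

    With a single binary covariate and no tied event times this equals
    the two-group log-rank chi-square.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    ll, U, I = cox_stats(X, time, event, beta, efron)
    delta = np.linalg.solve(I, U)
    chi2 = 0.0
    for a in range(p):
        chi2 += U[a] * delta[a]
    return chi2
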