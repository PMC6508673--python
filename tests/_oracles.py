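"""Independent oracles used by the test suite.

Each oracle computes a quantity by a route independent of the package
implementation it checks: brute-force enumeration for the marginal
likelihood, 2-D grid integration for a single-species posterior,
statsmodels for logistic MLE, and exhaustive subset search for the
stepwise selection.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import expit


def loglik_by_enumeration(params, y, design) -> float:
    """Marginal log-likelihood by summing over all 2^(M*K) latent states."""
    M, J, K = y.y.shape
    alpha = params.alpha_matrix()
    beta = params.beta_matrix()
    Xocc = design.occupancy_matrix()
    Xdet = design.route_matrix()
    psi = expit(Xocc @ beta.T)      # (M, K)
    p = expit(Xdet @ alpha.T)       # (M, K)
    total = 0.0
    for i in range(M):
        for k in range(K):
            yy = y.y[i, :, k]
            obs = yy != -1
            like = 0.0
            for z in (0, 1):
                prior = psi[i, k] if z == 1 else 1 - psi[i, k]
                cond = 1.0
                for v in yy[obs]:
                    pd = p[i, k] * z
                    cond *= pd if v == 1 else 1 - pd
                like += prior * cond
            total += np.log(like)
    return float(total)


def grid_posterior_psi(detection_counts, n_occasions, prior_var,
                       grid=(-8.0, 8.0, 801)) -> tuple[float, float]:
    """Posterior means of (psi, p) for the intercept-only one-species model.

    Integrates the marginal likelihood over a (logit psi, logit p) grid
    with independent Normal(0, prior_var) priors on both logits — the
    same prior the sampler's non-hierarchical mode uses.
    """
    g = np.linspace(*grid[:2], int(grid[2]))
    LPsi, LP = np.meshgrid(g, g, indexing="ij")
    psi, p = expit(LPsi), expit(LP)
    ll = -(LPsi ** 2 + LP ** 2) / (2 * prior_var)
    for d, n in zip(detection_counts, n_occasions):
        cond = np.log(psi) + d * np.log(p) + (n - d) * np.log1p(-p)
        ll = ll + (np.logaddexp(cond, np.log1p(-psi)) if d == 0 else cond)
    w = np.exp(ll - ll.max())
    w /= w.sum()
    return float((w * psi).sum()), float((w * p).sum())


def statsmodels_logistic(X, y):
    """Logistic MLE via statsmodels Newton solver (coef, loglik)."""
    import statsmodels.api as sm

    X1 = sm.add_constant(np.asarray(X, dtype=float))
    res = sm.Logit(np.asarray(y, dtype=float), X1).fit(disp=0, method="newton")
    return np.asarray(res.params), float(res.llf)


def exhaustive_stepwise(table, metrics, corr_threshold, fit_fn) -> list[str]:
    """AIC-best model over all pairwise-correlation-feasible subsets.

    Feasibility: every pair within the subset has |Pearson r| below the
    threshold.  ``fit_fn(X, y, names)`` must return an object with an
    ``aic`` attribute.
    """
    corr = table[list(metrics)].corr().abs()
    y = table["ghost"].to_numpy(dtype=float)
    best_aic, best = np.inf, []
    for r in range(1, len(metrics) + 1):
        for subset in itertools.combinations(metrics, r):
            ok = all(corr.loc[a, b] < corr_threshold
                     for a, b in itertools.combinations(subset, 2))
            if not ok:
                continue
            fit = fit_fn(table[list(subset)].to_numpy(), y, list(subset))
            if fit.aic < best_aic:
                best_aic, best = fit.aic, list(subset)
    return best
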