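"""Independent reference implementations used only to cross-check the
package: brute-force subset enumeration, an exact permutation null, a
logistic-regression score test derived from statsmodels log-likelihood
derivatives, a Cochran-Armitage-style trend statistic from the 2x3 table,
and direct likelihood maximization for the CMC comparator. None of these
share code with the implementation paths they validate."""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def logistic_score_oracle(S, y):
    """Score test of logistic Y ~ intercept + S, slope constrained to 0.

    Uses statsmodels' Logit score (gradient) and Hessian evaluated at the
    constrained MLE (intercept = logit(mean y), slope 0), with the intercept
    profiled out of the Fisher information.
    """
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(S, dtype=float), np.asarray(S, float)])
    model = sm.Logit(np.asarray(y, float), X)
    pbar = np.mean(y)
    params = np.array([np.log(pbar / (1 - pbar)), 0.0])
    U = model.score(params)  # gradient of the log-likelihood
    info = -model.hessian(params)
    eff_info = info[1, 1] - info[1, 0] ** 2 / info[0, 0]
    return U[1] ** 2 / eff_info


def trend_score_oracle(g, y):
    """Cochran-Armitage-style trend statistic (ML variance) from the 2x3
    genotype table of a single variant."""
    g = np.asarray(g)
    y = np.asarray(y)
    n = len(y)
    counts = {(gi, yi): 0 for gi in (0, 1, 2) for yi in (0, 1)}
    for gi, yi in zip(g, y):
        counts[(int(gi), int(yi))] += 1
    scores = np.array([0.0, 1.0, 2.0])
    n1 = y.sum()
    col = np.array([counts[(k, 0)] + counts[(k, 1)] for k in (0, 1, 2)])
    case = np.array([counts[(k, 1)] for k in (0, 1, 2)])
    num = scores @ case - n1 / n * (scores @ col)
    pbar = n1 / n
    var = pbar * (1 - pbar) * (scores**2 @ col - (scores @ col) ** 2 / n)
    return 0.0 if var == 0 else num**2 / var


def exhaustive_best_subset(G, Y, coefficients):
    """Best score statistic over all nonempty variant subsets, by direct
    evaluation of the aggregated score (no Gram-matrix shortcuts)."""
    from rarecomb import score_statistic

    p = G.n_variants
    best, best_subset = -np.inf, None
    for r in range(1, p + 1):
        for subset in itertools.combinations(range(p), r):
            c = np.zeros(p)
            c[list(subset)] = coefficients[list(subset)]
            S = G.dosages @ c
            t = score_statistic(S, Y)
            if t > best:
                best, best_subset = t, subset
    return best, best_subset


def exact_permutation_pvalue(statistic_fn, y, t_obs):
    """Exact permutation p-value #{perm: T >= T_obs} / n! over all label
    permutations (tiny n only)."""
    n = len(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if statistic_fn(np.asarray(y)[list(perm)]) >= t_obs - 1e-12:
            count += 1
    return count / total


def cmc_loglik_oracle(X, y):
    """Maximized logistic log-likelihood via direct numerical optimization."""
    X1 = np.column_stack([np.ones(len(y)), X])

    def negll(b):
        eta = X1 @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = minimize(negll, np.zeros(X1.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return -res.fun
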