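"""Independent oracle implementations used by the test suite.

Everything here is deliberately written without reference to the package
internals it checks: brute-force loops, finite differences of the raw
log-likelihood, and textbook formulas.
"""

import numpy as np


def pearson_x2(a, b, c, d):
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def table_to_data(a, b, c, d):
    """2x2 status x carrier table -> (y, z) vectors."""
    y = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    z = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return y, z


def fd_score_statistic(y, X, G, h_grad=1e-6, h_hess=1e-3):
    """Efficient score statistic from numerical derivatives of the log-likelihood.

    The nuisance block is fixed at the null MLE (statsmodels GLM); the
    gradient uses central differences and the Hessian central second
    differences with Richardson extrapolation.
    """
    import statsmodels.api as sm

    null = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
    theta0 = np.concatenate([null.params, np.zeros(G.shape[1])])
    D = np.hstack([X, G])

    def loglik(t):
        eta = D @ t
        return float(y @ eta - np.log1p(np.exp(eta)).sum())

    k = D.shape[1]
    grad = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h_grad
        grad[i] = (loglik(theta0 + e) - loglik(theta0 - e)) / (2 * h_grad)

    def hess_at(h):
        out = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                ei, ej = np.zeros(k), np.zeros(k)
                ei[i], ej[j] = h, h
                out[i, j] = (
                    loglik(theta0 + ei + ej)
                    - loglik(theta0 + ei - ej)
                    - loglik(theta0 - ei + ej)
                    + loglik(theta0 - ei - ej)
                ) / (4 * h * h)
        return out

    # Richardson extrapolation kills the O(h^2) truncation term
    hess = (4.0 * hess_at(h_hess / 2) - hess_at(h_hess)) / 3.0
    info = -hess
    q = X.shape[1]
    U = grad[q:]
    I_eff = info[q:, q:] - info[q:, :q] @ np.linalg.solve(info[:q, :q], info[:q, q:])
    return float(U @ np.linalg.solve(I_eff, U))


def random_score_problem(rng, package_test):
    """Small random dataset where the score test is well posed.

    ``package_test`` is the function under test (returns a TestResult);
    returns (its result, the finite-difference oracle value).
    """
    from snpset.data_model import ValidationError
    from snpset.assoc_tests import SeparationError, ConvergenceError

    n = 12
    while True:
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        s = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        if y.sum() in (0, n):
            continue
        G = np.hstack([Z, Z * s[:, None]])
        if np.linalg.matrix_rank(np.hstack([X, G])) < X.shape[1] + G.shape[1]:
            continue
        try:
            res = package_test(y, X, Z, s)
        except (ValidationError, SeparationError, ConvergenceError):
            continue
        if res.df != G.shape[1]:
            continue
        return res, fd_score_statistic(y, X, G)


def holm_stepdown_bruteforce(p):
    """Literal step-down execution of the Holm procedure."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, candidate)
        adjusted[idx] = running_max
    return adjusted
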