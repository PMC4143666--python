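"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's profiled/eigendecomposed code
paths: likelihoods are evaluated from dense covariance matrices and
maximized by zoomed grid search, and BLUPs come from the textbook dense
formula.
"""

from __future__ import annotations

import numpy as np


def dense_loglik(y, X, V, criterion: str) -> float:
    """Gaussian (restricted) log-likelihood with beta profiled by dense GLS.

    Returns -inf for singular V (e.g. a pure random-effect covariance
    with repeated measures, which is rank deficient).
    """
    n, p = X.shape
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0 or not np.isfinite(logdet):
        return -np.inf
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return -np.inf
    A = X.T @ Vi @ X
    try:
        beta = np.linalg.solve(A, X.T @ Vi @ y)
    except np.linalg.LinAlgError:
        return -np.inf
    r = y - X @ beta
    q = float(r @ Vi @ r)
    if criterion == "ML":
        return -0.5 * (n * np.log(2 * np.pi) + logdet + q)
    _, ldA = np.linalg.slogdet(A)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + ldA + q)


def grid_max_loglik(y, X, G, criterion: str) -> float:
    """Brute-force maximum over the two variance components.

    The covariance is parametrized as V = s * (h*G + (1-h)*I) with
    h in [0, 1] (so both boundary fits are on the grid) and log s in
    [-8, 8].  A dense first sweep locates the basin (the surface can be
    multimodal in h); 14 zoom levels of a 33x33 grid, shrinking by 2,
    then resolve the optimum.
    """
    n = len(y)
    I = np.eye(n)

    def scan(ls_grid, h_grid, best):
        for ls in ls_grid:
            for h in h_grid:
                V = np.exp(ls) * (h * G + (1.0 - h) * I)
                ll = dense_loglik(y, X, V, criterion)
                if ll > best[0]:
                    best = (ll, ls, h)
        return best

    best = scan(np.linspace(-8, 8, 129), np.linspace(0.0, 1.0, 81), (-np.inf, 0.0, 0.5))
    ls_w, h_w = 0.25, 0.025
    for _ in range(14):
        _, ls_c, h_c = best
        best = scan(
            np.linspace(ls_c - ls_w, ls_c + ls_w, 33),
            np.linspace(max(h_c - h_w, 0.0), min(h_c + h_w, 1.0), 33),
            best,
        )
        ls_w /= 2.0
        h_w /= 2.0
    return best[0]


def dense_blup(y, X, beta, K_full, Z, var_kin, var_resid) -> np.ndarray:
    """alpha_hat = var_kin * K Z' V^-1 (y - X beta) from dense matrices."""
    V = var_kin * (Z @ K_full @ Z.T) + var_resid * np.eye(len(y))
    return var_kin * (K_full @ Z.T @ np.linalg.solve(V, y - X @ beta))


def incidence(person_index: np.ndarray, n_persons: int) -> np.ndarray:
    Z = np.zeros((len(person_index), n_persons))
    Z[np.arange(len(person_index)), person_index] = 1.0
    return Z
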