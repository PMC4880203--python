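"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions — cell-by-cell
loops, dense covariance construction — with no reuse of the package's fast
paths, so it can serve as the second route of every equivalence check.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize


def kinship_cell_loop(M: np.ndarray) -> np.ndarray:
    """K[i, j] = sum_k M[i, k] * M[j, k] via an explicit double loop."""
    n = M.shape[0]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = float(np.sum(M[i] * M[j]))
    return K


def epistatic_pair_loop(Z: np.ndarray, W: np.ndarray):
    """The four interaction kinships by literal enumeration of pairs k < k'."""
    n, m = Z.shape
    out = {c: np.zeros((n, n)) for c in ("aa", "ad", "da", "dd")}
    for k in range(m - 1):
        for kp in range(k + 1, m):
            cols = {
                "aa": Z[:, k] * Z[:, kp],
                "ad": Z[:, k] * W[:, kp],
                "da": W[:, k] * Z[:, kp],
                "dd": W[:, k] * W[:, kp],
            }
            for c, u in cols.items():
                out[c] += np.outer(u, u)
    return out


def ols_reml_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Closed-form REML log-likelihood of the iid Gaussian model (H = I)."""
    n, p = y.size, X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    sigma2 = rss / (n - p)
    ll = -0.5 * ((n - p) * (np.log(sigma2) + 1.0) + np.linalg.slogdet(X.T @ X)[1])
    return ll, sigma2


def dense_profiled_reml(H: np.ndarray, y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Profiled REML log-likelihood for covariance ``H * sigma2``, dense route."""
    n, p = y.size, X.shape[1]
    cf = linalg.cho_factor(H)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Hy = linalg.cho_solve(cf, y)
    HX = linalg.cho_solve(cf, X)
    XtHX = X.T @ HX
    XtHy = X.T @ Hy
    beta = np.linalg.solve(XtHX, XtHy)
    rss = float(y @ Hy - XtHy @ beta)
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (np.log(sigma2) + 1.0) + logdet_H + np.linalg.slogdet(XtHX)[1]
    )
    return ll, sigma2


def eq4_style_loglik(theta: np.ndarray, sigma2: float, y, X, Kstack) -> float:
    """The textbook REML criterion evaluated on the full covariance V.

    ``-1/2 ln|V| - 1/2 y'P y - 1/2 ln|X'V^-1 X|`` with
    ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1`` and
    ``V = sum_i theta_i K_i + I sigma2``.
    """
    n = y.size
    V = np.tensordot(theta, Kstack, axes=1) + sigma2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return float(
        -0.5 * np.linalg.slogdet(V)[1]
        - 0.5 * (y @ P @ y)
        - 0.5 * np.linalg.slogdet(XtViX)[1]
    )


def dense_candidate_lrt(cols: np.ndarray, y: np.ndarray, X: np.ndarray, G: np.ndarray) -> float:
    """Candidate-effect LRT by rebuilding the full n x n covariance.

    Maximizes the same profiled REML objective over the candidate variance
    ratios, but through dense Cholesky factorizations of
    ``G + I + sum_j gamma_j u_j u_j'`` — no rotation, no low-rank updates.
    """
    n = y.size
    base = G + np.eye(n)

    def loglik(gam: np.ndarray) -> float:
        H = base.copy()
        for gj, u in zip(gam, cols.T):
            H += gj * np.outer(u, u)
        return dense_profiled_reml(H, y, X)[0]

    L0 = loglik(np.zeros(cols.shape[1]))
    res = optimize.minimize(
        lambda t: -loglik(t),
        x0=np.full(cols.shape[1], 0.1),
        method="L-BFGS-B",
        bounds=[(0.0, 1e6)] * cols.shape[1],
        options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-8},
    )
    return max(2.0 * (-res.fun - L0), 0.0)


def pair_interaction_columns(Z, W, k, kp) -> np.ndarray:
    return np.column_stack([
        Z[:, k] * Z[:, kp],
        Z[:, k] * W[:, kp],
        W[:, k] * Z[:, kp],
        W[:, k] * W[:, kp],
    ])
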