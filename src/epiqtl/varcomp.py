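"""REML estimation of the six polygenic variance components.

The trait model is ``y = X b + g + e`` with six independent polygenic terms,
so that ``Var(y) = sum_i K_i s2_i + I s2``.  Dividing through by the residual
variance gives the ratio parameterization ``Var(y) = (sum_i lambda_i K_i + I)
s2`` with ``lambda_i = s2_i / s2 >= 0``.  The residual variance is profiled
out analytically, so the optimizer searches only the six ratios; the model
still has seven variance parameters, the seventh being recovered in closed
form at every point.

Writing ``H = sum_i lambda_i K_i + I``, the profiled REML log-likelihood (up
to an additive constant that does not depend on lambda) is::

    L(lambda) = -1/2 [ (n-p) (ln s2_hat + 1) + ln|H| + ln|X' H^-1 X| ]
    b_hat  = (X' H^-1 X)^-1 X' H^-1 y
    s2_hat = (y - X b_hat)' H^-1 (y - X b_hat) / (n - p)

which maximized over lambda in [0, inf)^6 by bound-constrained quasi-Newton
(L-BFGS-B) gives the REML estimates.  All estimates on the boundary pile up
at exactly 0, which is expected behaviour for variance ratios.

The fitted ratios also define the weighted kinship aggregate
``G = sum_i lambda_i K_i`` whose eigendecomposition ``G = U diag(delta) U'``
rotates the data into coordinates where the null covariance is diagonal
(``delta_i + 1``); both genome scans run in these coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .genotype_io import TraitVector
from .kinship import KinshipSet

__all__ = [
    "COMPONENTS",
    "VarianceComponents",
    "BackgroundSpectrum",
    "reml_loglik",
    "estimate_variance_components",
    "variance_proportions",
    "weigh_and_eigendecompose",
    "profiled_loglik_diagonal",
]

COMPONENTS = ("a", "d", "aa", "ad", "da", "dd")

# optimizer settings: start 0.5 per ratio, box [0, 1e4], stop when the
# objective changes < 1e-8 or the projected gradient norm < 1e-6, cap 500
_START = 0.5
_BOUNDS = (0.0, 1e4)
_FTOL = 1e-8
_GTOL = 1e-6
_MAXITER = 500


@dataclass
class VarianceComponents:
    """REML estimates of the six variance ratios and the residual variance."""

    lam: np.ndarray                    # six ratios lambda_i >= 0
    sigma2: float                      # residual variance
    component_variances: np.ndarray    # lambda_i * sigma2
    proportions: np.ndarray            # six genetic shares + residual share
    loglik: float
    converged: bool
    n_iter: int
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != (6,):
            raise ValueError("lambda must hold six ratios")
        if np.any(self.lam < 0):
            raise ValueError("variance ratios must be non-negative")
        if self.sigma2 <= 0:
            raise ValueError("residual variance must be positive")


@dataclass
class BackgroundSpectrum:
    """Eigendecomposed lambda-weighted kinship aggregate plus rotated data.

    ``rotation @ diag(eigenvalues) @ rotation.T`` reconstructs
    ``G = sum_i lambda_i K_i``; eigenvalues are clipped at zero from below
    and reported in non-increasing order.  ``y_star = U' y`` and
    ``X_star = U' X`` are the trait and design in the rotated coordinates.
    """

    eigenvalues: np.ndarray
    rotation: np.ndarray
    y_star: np.ndarray
    X_star: np.ndarray
    lam: np.ndarray


def _check_lambda(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (6,):
        raise ValueError("lambda must hold six ratios (a, d, aa, ad, da, dd)")
    if np.any(lam < 0):
        raise ValueError("variance ratios must be non-negative")
    return lam


def reml_loglik(
    lam, trait: TraitVector, kin: KinshipSet
) -> tuple[float, float, np.ndarray]:
    """Profiled REML log-likelihood at the given variance ratios.

    Returns ``(loglik, sigma2_hat, beta_hat)``.  The additive constant
    dropped from the log-likelihood is fixed across lambda, so differences
    (and hence LRTs) are unaffected.
    """
    lam = _check_lambda(lam)
    y, X = trait.y, trait.X
    n, p = trait.n, trait.p
    if kin.n != n:
        raise ValueError("kinship dimension does not match phenotype length")
    H = np.tensordot(lam, kin.stacked(), axes=1)
    H[np.diag_indices_from(H)] += 1.0
    cf = linalg.cho_factor(H, lower=True, check_finite=False)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Hi_y = linalg.cho_solve(cf, y, check_finite=False)
    Hi_X = linalg.cho_solve(cf, X, check_finite=False)
    XtHiX = X.T @ Hi_X
    XtHiy = X.T @ Hi_y
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' H^-1 X is singular")
    beta = np.linalg.solve(XtHiX, XtHiy)
    rss = float(y @ Hi_y - XtHiy @ beta)
    if rss <= 0:
        raise ValueError("zero or negative residual variance (degenerate trait)")
    sigma2 = rss / (n - p)
    ll = -0.5 * ((n - p) * (np.log(sigma2) + 1.0) + logdet_H + logdet_XtHiX)
    return float(ll), float(sigma2), beta


def estimate_variance_components(
    trait: TraitVector,
    kin: KinshipSet,
    components: tuple[str, ...] | None = None,
    start: float = _START,
    maxiter: int = _MAXITER,
) -> VarianceComponents:
    """Maximize the profiled REML log-likelihood over the variance ratios.

    ``components`` optionally restricts the fit to a subset of the six terms
    (the remaining ratios are fixed at zero), which supports partial-kinship
    runs.  The optimization is deterministic: identical inputs reproduce the
    result bit for bit.
    """
    if np.ptp(trait.y) == 0:
        raise ValueError("phenotype has zero variance; nothing to decompose")
    if components is None:
        components = COMPONENTS
    free = [COMPONENTS.index(c) for c in components]
    if not free:
        raise ValueError("at least one component must be free")

    history: list[float] = []

    def negloglik(theta: np.ndarray) -> float:
        lam = np.zeros(6)
        lam[free] = theta
        ll, _, _ = reml_loglik(lam, trait, kin)
        history.append(-ll)
        return -ll

    res = optimize.minimize(
        negloglik,
        x0=np.full(len(free), start),
        method="L-BFGS-B",
        bounds=[_BOUNDS] * len(free),
        options={"maxiter": maxiter, "ftol": _FTOL, "gtol": _GTOL},
    )
    lam = np.zeros(6)
    lam[free] = np.maximum(res.x, 0.0)
    ll, sigma2, _ = reml_loglik(lam, trait, kin)
    component_variances = lam * sigma2
    total = float(component_variances.sum() + sigma2)
    proportions = np.append(component_variances, sigma2) / total
    return VarianceComponents(
        lam=lam,
        sigma2=sigma2,
        component_variances=component_variances,
        proportions=proportions,
        loglik=float(ll),
        converged=bool(res.success),
        n_iter=int(res.nit),
        trace=np.array(history),
    )


def variance_proportions(vc: VarianceComponents) -> np.ndarray:
    """Seven shares (six genetic + residual) of total trait variance."""
    total = float(vc.component_variances.sum() + vc.sigma2)
    return np.append(vc.component_variances, vc.sigma2) / total


def weigh_and_eigendecompose(
    lam, kin: KinshipSet, trait: TraitVector
) -> BackgroundSpectrum:
    """Eigendecompose the lambda-weighted kinship aggregate and rotate data.

    Eigenvalues below ``max(delta) * 1e-12`` are clipped to zero (degenerate
    aggregates with some ratios at the boundary are expected); the spectrum
    is returned in non-increasing order.
    """
    lam = _check_lambda(lam)
    G = np.tensordot(lam, kin.stacked(), axes=1)
    asym = np.max(np.abs(G - G.T)) if G.size else 0.0
    if asym > 1e-8:
        raise linalg.LinAlgError(
            f"weighted kinship aggregate is not symmetric (max asymmetry {asym:g})"
        )
    G = 0.5 * (G + G.T)
    delta, U = linalg.eigh(G, check_finite=False)
    delta = delta[::-1].copy()
    U = U[:, ::-1].copy()
    tiny = max(delta.max(initial=0.0), 0.0) * 1e-12
    delta[delta < tiny] = 0.0
    return BackgroundSpectrum(
        eigenvalues=delta,
        rotation=U,
        y_star=U.T @ trait.y,
        X_star=U.T @ trait.X,
        lam=lam,
    )


def profiled_loglik_diagonal(
    d: np.ndarray, y_star: np.ndarray, X_star: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Profiled REML log-likelihood for a diagonal covariance ``diag(d)``.

    In the rotated coordinates of a :class:`BackgroundSpectrum` with
    ``d = eigenvalues + 1`` this equals :func:`reml_loglik` at the same
    ratios; it is the O(n) workhorse behind the genome scans.
    """
    n = y_star.size
    p = X_star.shape[1]
    dinv = 1.0 / d
    XtDX = (X_star.T * dinv) @ X_star
    XtDy = (X_star.T * dinv) @ y_star
    ytDy = float(y_star @ (dinv * y_star))
    sign, logdet_XtDX = np.linalg.slogdet(XtDX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' H^-1 X is singular")
    beta = np.linalg.solve(XtDX, XtDy)
    rss = ytDy - float(XtDy @ beta)
    if rss <= 0:
        raise ValueError("zero or negative residual variance (degenerate trait)")
    sigma2 = rss / (n - p)
    logdet = float(np.sum(np.log(d)))
    ll = -0.5 * ((n - p) * (np.log(sigma2) + 1.0) + logdet + logdet_XtDX)
    return float(ll), float(sigma2), beta
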