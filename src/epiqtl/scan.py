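"""Likelihood-ratio genome scans for main and epistatic QTL effects.

Both scans test candidate *random* effects on top of the fixed polygenic
background.  The null model is the pure six-component polygenic model with
the genome-wide variance ratios held at their REML estimates; its profiled
log-likelihood ``L0`` is computed once.  For each candidate the alternative
adds random effects with their own variance ratios:

* 1D (per marker k, 2 df): ``Var(y) = (g_a z z' + g_d w w' + G + I) s2``
  with ``z = Z_k``, ``w = W_k`` and ``G`` the lambda-weighted kinship
  aggregate; the candidate-effect variances are ``phi = g * s2_hat``.
* 2D (per pair k < k', 4 df): four Hadamard interaction columns
  ``z_k o z_k'``, ``z_k o w_k'``, ``w_k o z_k'``, ``w_k o w_k'`` enter the
  same way.

The LRT is ``2 (L1 - L0)``.  Because the candidate effects are random, rank
deficiency of the candidate columns (fewer than four distinguishable
genotype combinations of a pair, or an all-zero column) poses no problem:
degenerate columns are pinned at zero variance and the statistic stays
finite.

Computation runs in the rotated coordinates of the background spectrum,
where the null covariance is diagonal, via a Woodbury rank-q update: after
the one-time rotation of the candidate columns every objective evaluation
costs O(q^2) with q <= 4, independent of n.

P-values, when requested, use the nominal chi-square reference (2 or 4 df).
Variance parameters are tested on the boundary of their space, so the true
null distribution is stochastically smaller and these p-values are
conservative; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import partial
from typing import NamedTuple

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .genotype_io import CodedGenotypes
from .varcomp import BackgroundSpectrum, VarianceComponents, profiled_loglik_diagonal
from ._parallel import parallel_map

__all__ = [
    "ScanResult1D",
    "ScanResult2D",
    "scan_marker_lrt",
    "scan_main",
    "scan_pair_lrt",
    "scan_epistasis",
    "plot_main_scan",
    "plot_epistasis_heatmap",
]

# candidate-variance optimizer: start 0.1 per ratio, box [0, 1e6], cap 200
_CAND_START = 0.1
_CAND_BOUNDS = (0.0, 1e6)
_CAND_MAXITER = 200
_CAND_FTOL = 1e-10
_CAND_GTOL = 1e-8

_LRT_CLIP = 1e-8       # negatives above this magnitude are an internal error
_ZERO_COL_TOL = 1e-12  # candidate columns with smaller norm are pinned at 0


@dataclass
class ScanResult1D:
    """Per-marker 2-df LRT profile with candidate-effect variance estimates."""

    marker_ids: list[str]
    lrt: np.ndarray
    phi_a: np.ndarray
    phi_d: np.ndarray
    null_loglik: float
    degenerate: np.ndarray
    chromosomes: list[str] | None = None
    df: int = 2

    def pvalues(self) -> np.ndarray:
        """Nominal chi-square(2) p-values (conservative; boundary test)."""
        return chi2.sf(self.lrt, self.df)


@dataclass
class ScanResult2D:
    """Lower-triangular pairwise 4-df LRT listing (each pair once, k < k')."""

    marker_ids: list[str]
    pairs: list[tuple[int, int]]
    lrt: np.ndarray
    null_loglik: float
    phis: np.ndarray | None = None   # per-pair (phi_aa, phi_ad, phi_da, phi_dd)
    df: int = 4

    def pvalues(self) -> np.ndarray:
        return chi2.sf(self.lrt, self.df)

    def lrt_matrix(self) -> np.ndarray:
        """Dense m x m matrix with LRTs in the lower triangle, NaN elsewhere."""
        m = len(self.marker_ids)
        M = np.full((m, m), np.nan)
        for (k, kp), v in zip(self.pairs, self.lrt):
            M[kp, k] = v
        return M


class MarkerScan(NamedTuple):
    lrt: float
    phi_a: float
    phi_d: float
    degenerate: bool


class PairScan(NamedTuple):
    lrt: float
    phis: tuple[float, float, float, float]
    degenerate: bool


@dataclass
class _Prep:
    """Null-model quantities reused by every candidate fit."""

    d: np.ndarray
    dinv: np.ndarray
    ys: np.ndarray
    Xs: np.ndarray
    XtDX: np.ndarray
    XtDy: np.ndarray
    ytDy: float
    logdet_d: float
    L0: float
    n: int
    p: int


def _prepare(bg: BackgroundSpectrum) -> _Prep:
    d = bg.eigenvalues + 1.0
    dinv = 1.0 / d
    ys, Xs = bg.y_star, bg.X_star
    L0, _, _ = profiled_loglik_diagonal(d, ys, Xs)
    return _Prep(
        d=d,
        dinv=dinv,
        ys=ys,
        Xs=Xs,
        XtDX=(Xs.T * dinv) @ Xs,
        XtDy=(Xs.T * dinv) @ ys,
        ytDy=float(ys @ (dinv * ys)),
        logdet_d=float(np.sum(np.log(d))),
        L0=L0,
        n=ys.size,
        p=Xs.shape[1],
    )


def _candidate_fit(A: np.ndarray, prep: _Prep) -> tuple[float, np.ndarray, bool]:
    """Maximize the profiled REML over candidate variance ratios.

    ``A`` holds the rotated candidate columns.  Returns
    ``(lrt, phi per column, degenerate flag)``; all-zero columns are pinned
    at zero variance, and a candidate with no informative column returns an
    exact zero LRT.
    """
    q = A.shape[1]
    norms = np.linalg.norm(A, axis=0)
    active = norms > _ZERO_COL_TOL
    phis = np.zeros(q)
    if not np.any(active):
        return 0.0, phis, True
    Aa = A[:, active]
    qa = Aa.shape[1]
    AtD = Aa.T * prep.dinv
    S = AtD @ Aa
    TX = AtD @ prep.Xs           # (qa, p)
    ty = AtD @ prep.ys           # (qa,)
    n, p = prep.n, prep.p
    eye = np.eye(qa)

    def profiled(gam: np.ndarray) -> tuple[float, float]:
        # Woodbury update of M = D + Aa diag(gam) Aa'
        C = eye + S * gam[None, :]
        sign_c, logdet_C = np.linalg.slogdet(C)
        if sign_c <= 0:
            return -np.inf, np.nan
        R = gam[:, None] * np.linalg.inv(C)   # Gamma C^-1, symmetric PSD
        XtMX = prep.XtDX - TX.T @ R @ TX
        XtMy = prep.XtDy - TX.T @ (R @ ty)
        ytMy = prep.ytDy - float(ty @ (R @ ty))
        sign_x, logdet_XtMX = np.linalg.slogdet(XtMX)
        if sign_x <= 0:
            return -np.inf, np.nan
        beta = np.linalg.solve(XtMX, XtMy)
        rss = ytMy - float(XtMy @ beta)
        if rss <= 0:
            return -np.inf, np.nan
        sigma2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * (np.log(sigma2) + 1.0)
            + prep.logdet_d + logdet_C + logdet_XtMX
        )
        return ll, sigma2

    def neg(gam: np.ndarray) -> float:
        ll, _ = profiled(gam)
        return 1e12 if not np.isfinite(ll) else -ll

    res = optimize.minimize(
        neg,
        x0=np.full(qa, _CAND_START),
        method="L-BFGS-B",
        bounds=[_CAND_BOUNDS] * qa,
        options={"maxiter": _CAND_MAXITER, "ftol": _CAND_FTOL, "gtol": _CAND_GTOL},
    )
    gam = np.maximum(res.x, 0.0)
    L1, sigma2 = profiled(gam)
    if L1 < prep.L0:  # boundary optimum; the null is nested
        gam = np.zeros(qa)
        L1, sigma2 = prep.L0, np.nan
    lrt = 2.0 * (L1 - prep.L0)
    if lrt < -_LRT_CLIP:
        raise RuntimeError(
            f"internal inconsistency: LRT {lrt:g} below the clip threshold"
        )
    lrt = max(lrt, 0.0)
    if np.isfinite(sigma2):
        phis[active] = gam * sigma2
    return float(lrt), phis, False


# ---------------------------------------------------------------------------
# 1D scan


def scan_marker_lrt(
    k: int, g: CodedGenotypes, bg: BackgroundSpectrum,
    vc: VarianceComponents | None = None, _prep: _Prep | None = None,
) -> MarkerScan:
    """2-df LRT for marker k's additive and dominance random effects.

    A marker whose Z and W columns are both identically zero yields an LRT
    of 0 with the degenerate flag set rather than an exception.
    """
    if not 0 <= k < g.m:
        raise IndexError(f"marker index {k} out of range [0, {g.m})")
    prep = _prep if _prep is not None else _prepare(bg)
    A = bg.rotation.T @ np.column_stack([g.Z[:, k], g.W[:, k]])
    lrt, phis, degenerate = _candidate_fit(A, prep)
    return MarkerScan(lrt, float(phis[0]), float(phis[1]), degenerate)


def _scan_marker_worker(k: int, g, bg, prep) -> MarkerScan:
    return scan_marker_lrt(k, g, bg, _prep=prep)


def scan_main(
    g: CodedGenotypes, bg: BackgroundSpectrum,
    vc: VarianceComponents | None = None, workers: int = 1,
) -> ScanResult1D:
    """2-df LRT scan over all m markers; deterministic for any worker count."""
    prep = _prepare(bg)
    fn = partial(_scan_marker_worker, g=g, bg=bg, prep=prep)
    rows = parallel_map(range(g.m), fn, workers=workers)
    return ScanResult1D(
        marker_ids=list(g.marker_ids),
        lrt=np.array([r.lrt for r in rows]),
        phi_a=np.array([r.phi_a for r in rows]),
        phi_d=np.array([r.phi_d for r in rows]),
        null_loglik=prep.L0,
        degenerate=np.array([r.degenerate for r in rows]),
        chromosomes=list(g.chromosome_of_marker) if g.chromosome_of_marker else None,
    )


# ---------------------------------------------------------------------------
# 2D scan


def _pair_columns(g: CodedGenotypes, k: int, kp: int) -> np.ndarray:
    Z, W = g.Z, g.W
    return np.column_stack([
        Z[:, k] * Z[:, kp],
        Z[:, k] * W[:, kp],
        W[:, k] * Z[:, kp],
        W[:, k] * W[:, kp],
    ])


def scan_pair_lrt(
    k: int, kp: int, g: CodedGenotypes, bg: BackgroundSpectrum,
    vc: VarianceComponents | None = None, _prep: _Prep | None = None,
) -> PairScan:
    """4-df LRT for the four interaction effects of marker pair (k, k').

    Pairs with fewer than four distinguishable genotype combinations (rank-
    deficient or zero interaction columns) are handled by the random-model
    formulation; degenerate columns are pinned at zero variance.
    """
    if not (0 <= k < kp < g.m):
        raise IndexError(f"pair indices must satisfy 0 <= k < k' < m, got ({k}, {kp})")
    prep = _prep if _prep is not None else _prepare(bg)
    A = bg.rotation.T @ _pair_columns(g, k, kp)
    lrt, phis, degenerate = _candidate_fit(A, prep)
    return PairScan(lrt, tuple(phis), degenerate)


def _scan_pair_worker(pair: tuple[int, int], g, bg, prep) -> PairScan:
    return scan_pair_lrt(pair[0], pair[1], g, bg, _prep=prep)


def scan_epistasis(
    g: CodedGenotypes, bg: BackgroundSpectrum,
    vc: VarianceComponents | None = None, workers: int = 1,
) -> ScanResult2D:
    """4-df LRT scan over all m(m-1)/2 unordered marker pairs."""
    if g.m < 2:
        raise ValueError("the pairwise scan needs at least two markers")
    prep = _prepare(bg)
    pairs = [(k, kp) for k in range(g.m - 1) for kp in range(k + 1, g.m)]
    fn = partial(_scan_pair_worker, g=g, bg=bg, prep=prep)
    rows = parallel_map(pairs, fn, workers=workers)
    return ScanResult2D(
        marker_ids=list(g.marker_ids),
        pairs=pairs,
        lrt=np.array([r.lrt for r in rows]),
        null_loglik=prep.L0,
        phis=np.array([r.phis for r in rows]),
    )


# ---------------------------------------------------------------------------
# plot hooks


def plot_main_scan(res: ScanResult1D, ax=None, threshold: float | None = None):
    """LRT-vs-genome-position profile, chromosomes separated by dashed lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(res.lrt))
    ax.plot(x, res.lrt, lw=0.8)
    if res.chromosomes is not None:
        bounds = [i for i in range(1, len(x)) if res.chromosomes[i] != res.chromosomes[i - 1]]
        for b in bounds:
            ax.axvline(b - 0.5, ls="--", color="grey", lw=0.6)
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=0.8)
    ax.set_xlabel("marker index")
    ax.set_ylabel("LRT (2 df)")
    return ax


def plot_epistasis_heatmap(res: ScanResult2D, ax=None):
    """Lower-triangular heat map of pairwise LRT values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(res.lrt_matrix(), origin="lower", cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="LRT (4 df)")
    ax.set_xlabel("marker k")
    ax.set_ylabel("marker k'")
    return ax
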