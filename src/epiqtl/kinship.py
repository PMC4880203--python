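"""Marker-generated kinship matrices for the six-component epistatic model.

The total genetic covariance of a quantitative trait in an F2-type population
is decomposed into six terms — additive (a), dominance (d) and the four
pairwise interaction types aa, ad, da and dd — each with its own n x n
marker-generated kinship matrix acting as the covariance structure of one
random genetic effect:

* ``K_a_raw  = sum_k Z_k Z_k'``            (additive)
* ``K_d_raw  = sum_k W_k W_k'``            (dominance)
* ``K_xy_raw = sum_{k<k'} u u'`` with ``u`` the elementwise (Hadamard)
  product of the role-x column of marker k and the role-y column of marker
  k', for (x, y) in {aa, ad, da, dd}.

The self-pair k = k' is excluded everywhere, and ad/da are distinct because
the roles are ordered within each unordered pair k < k'.

Two construction paths are provided: a definitional brute-force enumeration
of all m(m-1)/2 pairs, and an algebraically equivalent fast path built from
Gram-matrix Hadamard identities plus suffix accumulation for the ordered
ad/da terms.  Matrices are normalized to mean diagonal 1 so the six variance
components are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .genotype_io import CodedGenotypes

__all__ = [
    "KinshipSet",
    "RawEpistaticKinships",
    "kinship_main",
    "kinship_epistatic_bruteforce",
    "kinship_epistatic_fast",
    "normalize_kinships",
    "compute_kinships",
]

COMPONENTS = ("a", "d", "aa", "ad", "da", "dd")


@dataclass
class KinshipSet:
    """Six symmetric n x n kinship matrices plus normalization bookkeeping.

    ``norm_constants[c]`` records the divisor applied to the raw matrix of
    component ``c``; raw = normalized * constant exactly.  A raw matrix that
    is identically zero is passed through unchanged with constant 1.
    """

    K_a: np.ndarray
    K_d: np.ndarray
    K_aa: np.ndarray
    K_ad: np.ndarray
    K_da: np.ndarray
    K_dd: np.ndarray
    norm_constants: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in COMPONENTS}
    )
    normalized: bool = False

    COMPONENTS = COMPONENTS

    def matrix(self, comp: str) -> np.ndarray:
        return getattr(self, f"K_{comp}")

    def matrices(self) -> list[np.ndarray]:
        return [self.matrix(c) for c in COMPONENTS]

    def stacked(self) -> np.ndarray:
        """The six matrices as a (6, n, n) array in canonical order."""
        return np.stack(self.matrices())

    @property
    def n(self) -> int:
        return self.K_a.shape[0]


class RawEpistaticKinships(NamedTuple):
    K_aa: np.ndarray
    K_ad: np.ndarray
    K_da: np.ndarray
    K_dd: np.ndarray
    n_pairs: int


def _mirror_upper(G: np.ndarray) -> np.ndarray:
    # use each of the n(n+1)/2 unique cells once; mirror the strict upper part
    return np.triu(G) + np.triu(G, 1).T


def kinship_main(g: CodedGenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Raw additive and dominance kinships, sum of marker-column outer products."""
    if g.m == 0:
        raise ValueError("no markers")
    K_a = _mirror_upper(g.Z @ g.Z.T)
    K_d = _mirror_upper(g.W @ g.W.T)
    return K_a, K_d


def kinship_epistatic_bruteforce(g: CodedGenotypes) -> RawEpistaticKinships:
    """Definitional pair enumeration of the four raw interaction kinships.

    Enumerates every unordered marker pair k < k' exactly once and
    accumulates the outer product of each Hadamard interaction column.
    Quadratic in m; serves as the oracle for the fast path.
    """
    if g.m < 2:
        raise ValueError("epistatic kinships need at least two markers")
    n, m = g.n, g.m
    Z, W = g.Z, g.W
    K = {c: np.zeros((n, n)) for c in ("aa", "ad", "da", "dd")}
    n_pairs = 0
    for k in range(m - 1):
        for kp in range(k + 1, m):
            n_pairs += 1
            for comp, u in (
                ("aa", Z[:, k] * Z[:, kp]),
                ("ad", Z[:, k] * W[:, kp]),
                ("da", W[:, k] * Z[:, kp]),
                ("dd", W[:, k] * W[:, kp]),
            ):
                K[comp] += np.outer(u, u)
    return RawEpistaticKinships(K["aa"], K["ad"], K["da"], K["dd"], n_pairs)


def kinship_epistatic_fast(g: CodedGenotypes) -> RawEpistaticKinships:
    """Fast interaction kinships, equal to the brute-force enumeration.

    Uses the identities (with G_Z = ZZ', G_W = WW' and o the Hadamard
    product)::

        K_aa = (G_Z o G_Z - (ZoZ)(ZoZ)') / 2
        K_dd = (G_W o G_W - (WoW)(WoW)') / 2
        K_ad = sum_k (Z_k Z_k') o S_k,  S_k = sum_{k'>k} W_k' W_k''
        K_da = symmetric in roles (W leading, Z trailing)

    The ad/da suffix sums run in O(m n^2) instead of O(m^2 n^2).
    """
    if g.m < 2:
        raise ValueError("epistatic kinships need at least two markers")
    n, m = g.n, g.m
    Z, W = g.Z, g.W

    G_Z = Z @ Z.T
    G_W = W @ W.T
    Z2 = Z * Z
    W2 = W * W
    K_aa = 0.5 * (G_Z * G_Z - Z2 @ Z2.T)
    K_dd = 0.5 * (G_W * G_W - W2 @ W2.T)

    K_ad = np.zeros((n, n))
    K_da = np.zeros((n, n))
    S_W = np.zeros((n, n))  # suffix sum of W_k' W_k''
    S_Z = np.zeros((n, n))
    for k in range(m - 1, -1, -1):
        zz = np.outer(Z[:, k], Z[:, k])
        ww = np.outer(W[:, k], W[:, k])
        K_ad += zz * S_W
        K_da += ww * S_Z
        S_W += ww
        S_Z += zz

    # BLAS products can leave ~1e-16 asymmetry; enforce exact symmetry
    K_aa = 0.5 * (K_aa + K_aa.T)
    K_dd = 0.5 * (K_dd + K_dd.T)
    return RawEpistaticKinships(K_aa, K_ad, K_da, K_dd, m * (m - 1) // 2)


def normalize_kinships(
    K_a, K_d, K_aa, K_ad, K_da, K_dd, normalize: bool = True
) -> KinshipSet:
    """Scale each raw matrix so its mean diagonal entry is 1.

    The divisor is recorded per component so the raw matrix can be recovered
    exactly.  An identically-zero matrix (e.g. K_aa when Z has a single
    informative column) is passed through with constant 1 and a warning.
    """
    raw = dict(zip(COMPONENTS, (K_a, K_d, K_aa, K_ad, K_da, K_dd)))
    out = {}
    constants = {}
    for comp, K in raw.items():
        K = np.asarray(K, dtype=float)
        c = float(np.mean(np.diag(K)))
        if not normalize:
            out[comp] = K
            constants[comp] = 1.0
            continue
        if c <= 0.0:
            if np.any(K != 0.0):
                raise ValueError(
                    f"kinship {comp} has non-positive mean diagonal {c} "
                    "but is not identically zero"
                )
            warnings.warn(
                f"kinship matrix {comp} is identically zero; left unscaled",
                RuntimeWarning,
                stacklevel=2,
            )
            out[comp] = K
            constants[comp] = 1.0
        else:
            out[comp] = K / c
            constants[comp] = c
    return KinshipSet(
        K_a=out["a"], K_d=out["d"], K_aa=out["aa"], K_ad=out["ad"],
        K_da=out["da"], K_dd=out["dd"],
        norm_constants=constants, normalized=normalize,
    )


def compute_kinships(
    g: CodedGenotypes, method: str = "fast", normalize: bool = True
) -> KinshipSet:
    """Compute all six kinship matrices from coded genotypes."""
    K_a, K_d = kinship_main(g)
    if g.m >= 2:
        if method == "fast":
            epi = kinship_epistatic_fast(g)
        elif method == "bruteforce":
            epi = kinship_epistatic_bruteforce(g)
        else:
            raise ValueError(f"unknown kinship method {method!r}")
        K_aa, K_ad, K_da, K_dd = epi.K_aa, epi.K_ad, epi.K_da, epi.K_dd
    else:
        raise ValueError("epistatic kinships need at least two markers")
    return normalize_kinships(K_a, K_d, K_aa, K_ad, K_da, K_dd, normalize=normalize)
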