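"""Simulation of F2-type genotypes and traits under the epistatic model.

Genotypes emulate an F2 biparental population: each individual carries two
parental gametes, each gamete a Markov chain along every chromosome whose
switch probability between adjacent markers is the recombination fraction
``r`` (the two gametes recombine independently; no interference).  The
genotype at a marker is the pair of parental origins, giving the F2
stationary frequencies 1/4 A : 1/2 H : 1/4 B, and is returned already coded
into additive/dominance indicators.

Traits are generated under the complete epistatic model

    y = mu + sum_k Z_k a_k + sum_k W_k d_k
        + sum_{k<k'} (Z_k o Z_k') aa_kk' + (Z_k o W_k') ad_kk'
        + (W_k o Z_k') da_kk' + (W_k o W_k') dd_kk'  + e,   e ~ N(0, s2 I)

in one of two modes: *sparse* (a handful of explicit nonzero effects —
planted-QTL studies) or *polygenic* (every marker/pair effect drawn iid
normal, the per-component variance split equally across its terms).  A third
route, :func:`draw_polygenic_trait`, samples the trait directly from the
six-component covariance ``(sum_i lambda_i K_i + I) s2`` built from actual
kinship matrices; it realizes a prescribed set of variance ratios exactly
and drives the parameter-recovery studies.

Every draw is reproducible from the configuration and seed, and the truth
record returned with each phenotype contains the drawn effects and residuals
exactly (``y`` minus the recorded genetic sum equals the recorded residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import CodedGenotypes, TraitVector
from .kinship import KinshipSet
from .varcomp import COMPONENTS

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "draw_polygenic_trait",
]

# genotype symbol by count of first-parent alleles: 2 -> A, 1 -> H, 0 -> B
_Z_BY_DOSE = np.array([-1.0, 0.0, 1.0])
_W_BY_DOSE = np.array([0.0, 1.0, 0.0])


@dataclass
class SimulationConfig:
    """Study design for one simulated dataset.

    Defaults emulate a rice-like F2 bin map: up to 12 chromosomes and an
    adjacent-bin recombination fraction of 0.2 (bins are broad segments, so
    adjacent-bin recombination is appreciable).
    """

    n: int
    m: int
    n_chromosomes: int | None = None
    r: float = 0.2
    mode: str = "sparse"
    # sparse mode: explicit effects
    additive_effects: list[tuple[int, float]] = field(default_factory=list)
    dominance_effects: list[tuple[int, float]] = field(default_factory=list)
    interaction_effects: list[tuple[int, int, str, float]] = field(default_factory=list)
    # polygenic mode: total variance per component, split across its terms
    variances: dict[str, float] = field(default_factory=dict)
    mu: float = 0.0
    sigma2: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 individuals and m >= 1 markers")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("recombination fraction must lie in [0, 0.5]")
        if self.sigma2 <= 0:
            raise ValueError("residual variance must be positive")
        if self.n_chromosomes is None:
            self.n_chromosomes = min(12, self.m)
        if not 1 <= self.n_chromosomes <= self.m:
            raise ValueError("number of chromosomes must lie in [1, m]")
        if self.mode not in ("sparse", "polygenic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for k, _ in self.additive_effects + self.dominance_effects:
            if not 0 <= k < self.m:
                raise ValueError(f"marker index {k} out of range")
        for k, kp, comp, _ in self.interaction_effects:
            if not 0 <= k < kp < self.m:
                raise ValueError(f"pair ({k}, {kp}) must satisfy 0 <= k < k' < m")
            if comp not in ("aa", "ad", "da", "dd"):
                raise ValueError(f"unknown interaction type {comp!r}")
        for comp, v in self.variances.items():
            if comp not in COMPONENTS:
                raise ValueError(f"unknown component {comp!r}")
            if v < 0:
                raise ValueError("component variances must be non-negative")


def simulate_genotypes(cfg: SimulationConfig, rng=None) -> CodedGenotypes:
    """Draw an F2-type genotype table, already coded into Z/W indicators."""
    if rng is None:
        # distinct child stream per stage so genotype and trait draws never
        # consume the same portion of the seed sequence
        rng = np.random.default_rng(None if cfg.seed is None else [cfg.seed, 0])
    chrom_sizes = [c.size for c in np.array_split(np.arange(cfg.m), cfg.n_chromosomes)]
    dose_cols = []
    chrom_labels = []
    for ci, L in enumerate(chrom_sizes):
        if L == 0:
            continue
        # two independent gametes; allele switches between adjacent markers
        # occur with probability r; parity of switch counts gives the origin
        a0 = rng.random((cfg.n, 2, 1)) < 0.5
        if L > 1:
            switches = rng.random((cfg.n, 2, L - 1)) < cfg.r
            parity = np.concatenate(
                [np.zeros((cfg.n, 2, 1), dtype=int), np.cumsum(switches, axis=2) % 2],
                axis=2,
            )
        else:
            parity = np.zeros((cfg.n, 2, 1), dtype=int)
        alleles = a0.astype(int) ^ parity
        dose_cols.append(alleles.sum(axis=1))  # n x L, values 0/1/2
        chrom_labels.extend([f"chr{ci + 1:02d}"] * L)
    dose = np.concatenate(dose_cols, axis=1)
    return CodedGenotypes(
        Z=_Z_BY_DOSE[dose],
        W=_W_BY_DOSE[dose],
        chromosome_of_marker=chrom_labels,
    )


def _polygenic_sum(g: CodedGenotypes, variances: dict[str, float], rng) -> tuple[np.ndarray, dict]:
    n, m = g.n, g.m
    Z, W = g.Z, g.W
    n_pairs = m * (m - 1) // 2
    genetic = np.zeros(n)
    truth: dict[str, np.ndarray] = {}
    for comp in ("a", "d"):
        v = variances.get(comp, 0.0)
        if v == 0.0:
            continue
        eff = rng.normal(0.0, np.sqrt(v / m), size=m)
        genetic += (Z if comp == "a" else W) @ eff
        truth[comp] = eff
    roles = {"aa": (Z, Z), "ad": (Z, W), "da": (W, Z), "dd": (W, W)}
    for comp, (L, R) in roles.items():
        v = variances.get(comp, 0.0)
        if v == 0.0 or n_pairs == 0:
            continue
        eff = rng.normal(0.0, np.sqrt(v / n_pairs), size=n_pairs)
        truth[comp] = eff
        pos = 0
        for k in range(m - 1):
            width = m - 1 - k
            genetic += L[:, k] * (R[:, k + 1:] @ eff[pos:pos + width])
            pos += width
    return genetic, truth


def simulate_phenotype(
    g: CodedGenotypes, cfg: SimulationConfig, rng=None
) -> tuple[TraitVector, dict]:
    """Generate a trait under the configured truth; return it with the truth record.

    The truth record holds the genetic sum (including the intercept), the
    residual vector and the drawn effects, so ``y - genetic`` reproduces the
    residual exactly.
    """
    if rng is None:
        rng = np.random.default_rng(None if cfg.seed is None else [cfg.seed, 1])
    if g.m != cfg.m or g.n != cfg.n:
        raise ValueError("genotypes do not match the simulation config")
    Z, W = g.Z, g.W
    if cfg.mode == "sparse":
        genetic = np.zeros(cfg.n)
        for k, a in cfg.additive_effects:
            genetic += Z[:, k] * a
        for k, d in cfg.dominance_effects:
            genetic += W[:, k] * d
        roles = {"aa": (Z, Z), "ad": (Z, W), "da": (W, Z), "dd": (W, W)}
        for k, kp, comp, e in cfg.interaction_effects:
            L, R = roles[comp]
            genetic += L[:, k] * R[:, kp] * e
        effects = {
            "additive": list(cfg.additive_effects),
            "dominance": list(cfg.dominance_effects),
            "interaction": list(cfg.interaction_effects),
        }
    else:
        genetic, effects = _polygenic_sum(g, cfg.variances, rng)
    genetic = genetic + cfg.mu
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2), size=cfg.n)
    y = genetic + eps
    eps = y - genetic  # re-derive so the y = genetic + eps identity is exact
    truth = {
        "mode": cfg.mode,
        "mu": cfg.mu,
        "sigma2": cfg.sigma2,
        "seed": cfg.seed,
        "genetic": genetic,
        "epsilon": eps,
        "effects": effects,
    }
    return TraitVector(y, trait_name="simulated"), truth


def draw_polygenic_trait(
    kin: KinshipSet,
    lam,
    sigma2: float = 1.0,
    mu: float = 0.0,
    rng=None,
    trait_name: str = "simulated",
) -> TraitVector:
    """Sample ``y ~ N(mu, (sum_i lambda_i K_i + I) sigma2)`` exactly.

    This is the generative counterpart of the REML model itself: the
    supplied variance ratios are realized exactly on the scale of the given
    (normalized) kinship matrices, which makes it the reference route for
    parameter-recovery studies.
    """
    rng = np.random.default_rng() if rng is None else rng
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (6,):
        raise ValueError("lambda must hold six ratios (a, d, aa, ad, da, dd)")
    if np.any(lam < 0) or sigma2 <= 0:
        raise ValueError("variance parameters must be non-negative, sigma2 > 0")
    G = np.tensordot(lam, kin.stacked(), axes=1)
    G = 0.5 * (G + G.T)
    delta, U = np.linalg.eigh(G)
    delta = np.clip(delta, 0.0, None)
    z = rng.standard_normal(kin.n)
    y = mu + np.sqrt(sigma2) * (U @ (np.sqrt(delta + 1.0) * z))
    return TraitVector(y, trait_name=trait_name)
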