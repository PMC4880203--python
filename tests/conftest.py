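import numpy as np
import pytest

import epiqtl as eq


def random_coded(rng, n, m):
    """A random valid A/H/B-coded genotype table (not F2-structured)."""
    Z = rng.choice([-1.0, 0.0, 1.0], size=(n, m), p=[0.25, 0.5, 0.25])
    W = (Z == 0).astype(float)
    return eq.CodedGenotypes(Z, W)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated F2 dataset with a planted additive QTL, fitted once."""
    cfg = eq.SimulationConfig(
        n=80, m=12, seed=42, mode="sparse", additive_effects=[(5, 2.0)]
    )
    g = eq.simulate_genotypes(cfg)
    trait, truth = eq.simulate_phenotype(g, cfg)
    kin = eq.compute_kinships(g)
    return g, trait, kin, truth


@pytest.fixture(scope="session")
def fitted_background(small_dataset):
    g, trait, kin, _ = small_dataset
    vc = eq.estimate_variance_components(trait, kin)
    bg = eq.weigh_and_eigendecompose(vc.lam, kin, trait)
    return vc, bg
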