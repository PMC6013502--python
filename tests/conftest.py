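import numpy as np
import pandas as pd
import pytest

from regmod.containers import GenotypeMatrix
from regmod.synth import SimulationConfig, simulate_genotypes
from regmod.theta import AssociationPattern


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def locus_genotypes():
    """One simulated LD locus shared by read-only tests (300 x ~200)."""
    return simulate_genotypes(
        SimulationConfig(n_samples=300, n_variants=200, block_len=20, block_r2=0.8, seed=11)
    )


def make_pattern(
    nlp,
    sign=None,
    trait="t",
    chrom="1",
    pos=None,
    anchor_pos=None,
    ref="A",
    alt="G",
):
    """Hand-built association pattern for unit tests."""
    nlp = np.asarray(nlp, dtype=float)
    m = nlp.size
    if pos is None:
        pos = 1_000_000 + 1_000 * np.arange(m)
    sign = np.ones(m) if sign is None else np.asarray(sign, dtype=float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": 0.25,
        }
    )
    anchor = (chrom, int(anchor_pos if anchor_pos is not None else np.median(pos)))
    return AssociationPattern(trait, variants, nlp, sign, anchor)


def random_patterns(rng, m=30, trait_prefix="p"):
    """A random pair of patterns over shared variants (for oracle tests)."""
    nlp_a = rng.exponential(1.5, m) + rng.choice([0, 3], m, p=[0.7, 0.3])
    nlp_b = rng.exponential(1.5, m) + rng.choice([0, 3], m, p=[0.7, 0.3])
    sign_a = rng.choice([-1.0, 1.0], m)
    sign_b = rng.choice([-1.0, 1.0], m)
    a = make_pattern(nlp_a, sign_a, trait=f"{trait_prefix}A")
    b = make_pattern(nlp_b, sign_b, trait=f"{trait_prefix}B")
    return a, b


@pytest.fixture
def pattern_factory():
    return make_pattern
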