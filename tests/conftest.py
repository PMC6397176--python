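import numpy as np
import pandas as pd
import pytest

from concordia.callset_io import INDEL, SNP, MergedMatrix, VariantKey
from concordia.simulate import SimulationConfig, simulate_bundle


def make_matrix(
    codes,
    variant_types=None,
    pipelines=None,
    depth=None,
    alt_depth=None,
    support=None,
):
    """Build a MergedMatrix directly from a genotype-code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    pipelines = pipelines or [f"P{j}" for j in range(p)]
    variant_types = variant_types or [SNP] * n
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "pos": np.arange(100, 100 + 10 * n, 10),
            "ref": ["A"] * n,
            "alt": ["G"] * n,
            "variant_type": variant_types,
        }
    )
    return MergedMatrix(
        variants=variants,
        pipelines=list(pipelines),
        codes=codes,
        depth=np.full((n, p), np.nan) if depth is None else np.asarray(depth, float),
        alt_depth=(
            np.full((n, p), np.nan)
            if alt_depth is None
            else np.asarray(alt_depth, float)
        ),
        support=support
        or {pid: frozenset({SNP, INDEL}) for pid in pipelines},
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study used across modules."""
    cfg = SimulationConfig(n_variants=400, genome_length=200_000)
    return simulate_bundle(cfg, seed=7)


@pytest.fixture(scope="session")
def default_bundle():
    """The default 2,000-variant desk-scale bundle."""
    return simulate_bundle(SimulationConfig(), seed=11)


def random_key(rng, chrom="1", lo=1, hi=10_000) -> VariantKey:
    pos = int(rng.integers(lo, hi))
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    return VariantKey(chrom, pos, str(ref), str(alt))
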