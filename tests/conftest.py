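"""Shared fixtures: the default synthetic design and derived objects.

Session scope keeps the expensive objects (2,000-gene simulation,
normalization, TOM) computed once for the whole run.
"""

import numpy as np
import pandas as pd
import pytest

from cienet.network import adjacency, tom
from cienet.preprocess import two_stage_normalize
from cienet.simulate import SyntheticDesign, simulate_expression, _sample_grid
from cienet.types import ExpressionMatrix

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    """Default design: 2,000 genes, 5 planted modules, 48 samples, 2 batches."""
    return simulate_expression(SyntheticDesign(rng_seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def normalized(default_sim):
    em, _ = default_sim
    return two_stage_normalize(em)


@pytest.fixture(scope="session")
def default_network(normalized):
    return tom(adjacency(normalized, 6))


@pytest.fixture(scope="session")
def small_sim():
    """One 30-gene decay module in 100 genes; cheap per-test material."""
    design = SyntheticDesign(
        n_genes=100, module_sizes=(30,), profiles=("decay",), effect_sizes=(3.0,),
        rng_seed=7,
    )
    return simulate_expression(design)


def make_null_matrix(n_genes: int, seed: int, noise_sd: float = 0.5) -> ExpressionMatrix:
    """Pure-noise matrix on the 2x4x6 design grid (no group effects)."""
    rng = np.random.default_rng(seed)
    meta = _sample_grid(
        SyntheticDesign(n_genes=n_genes, module_sizes=(), profiles=(),
                        effect_sizes=(), rng_seed=seed)
    )
    values = pd.DataFrame(
        rng.normal(8.0, noise_sd, size=(n_genes, len(meta))),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=meta.index,
    )
    return ExpressionMatrix(values, meta.reset_index())
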