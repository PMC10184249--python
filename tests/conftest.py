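import numpy as np
import pytest

from mandiblescape.biomech import SolverParams, compute_warp_traits, trait_grid
from mandiblescape.outlines import (
    Outline,
    build_morphospace,
    efa,
    procrustes_align,
    resample_outline,
    warp_grid,
)
from mandiblescape.synthetic import JawParams, SimConfig, make_dataset, make_outline


@pytest.fixture(scope="session")
def dataset():
    """Two-clade synthetic dataset: 30 jaw outlines, tree, groups, masses."""
    return make_dataset(SimConfig(seed=42, n_taxa=(15, 15)))


@pytest.fixture(scope="session")
def aligned(dataset):
    res = [resample_outline(o, 300) for o in dataset.outlines]
    return procrustes_align(res)


@pytest.fixture(scope="session")
def morphospace(aligned):
    coefs, _ = efa(aligned, 0.99)
    return build_morphospace(coefs, ids=aligned.ids)


@pytest.fixture(scope="session")
def warps(morphospace):
    return warp_grid(morphospace, 10, 10)


@pytest.fixture(scope="session")
def warp_traits(warps):
    # coarse mesh keeps the 100 bending simulations quick
    return compute_warp_traits(warps, SolverParams(h=1.2), model_length=100.0)


@pytest.fixture(scope="session")
def grid(warps, warp_traits):
    return trait_grid(warps, warp_traits)


@pytest.fixture
def rectangle():
    return Outline(
        np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 4.0], [0.0, 4.0]]),
        id="rect",
        canonical=True,
    )


@pytest.fixture
def beam():
    return Outline(
        np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 10.0], [0.0, 10.0]]),
        id="beam",
        canonical=True,
    )


@pytest.fixture
def default_jaw():
    return make_outline(JawParams(), id="jaw")
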