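import numpy as np
import pytest

from pacsmd import ToyPotentialSpec, arrange_ligand_copies


@pytest.fixture
def funnel_spec() -> ToyPotentialSpec:
    """Small funnel landscape used across unit tests."""
    return ToyPotentialSpec(
        well_depth=10.0,
        well_width=1.5,
        excluded_radius=2.0,
        confinement_radius=12.0,
        copy_repulsion_strength=5.0,
        copy_repulsion_range=2.0,
    )


@pytest.fixture
def six_copy_state(funnel_spec):
    return arrange_ligand_copies(
        funnel_spec, n_copies=6, r_min=5.0, r_max=10.0, min_separation=2.5, seed=7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
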