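import numpy as np
import pytest

from mangrovecarbon import features as ft
from mangrovecarbon import synthetic as syn

DEFAULT_FRACTIONS = {
    "A_marina": 0.28,
    "R_stylosa": 0.16,
    "A_corniculatum": 0.12,
    "B_gymnorrhiza": 0.09,
    "soil": 0.15,
    "water": 0.14,
    "shadow": 0.06,
}


@pytest.fixture(scope="session")
def signatures():
    return syn.default_signatures()


@pytest.fixture(scope="session")
def scene(signatures):
    """One 160×160 mixed-community scene shared across the suite."""
    label_map = syn.generate_species_map(
        (160, 160), DEFAULT_FRACTIONS, patch_scale=8.0, seed=11
    )
    return syn.generate_scene(label_map, signatures, noise_seed=12)


@pytest.fixture(scope="session")
def plots(scene, signatures):
    return syn.sample_plots(scene, signatures, n_per_species=10, seed=13)


@pytest.fixture(scope="session")
def stack(scene):
    """Full 55-layer feature stack for the shared scene."""
    return ft.build_feature_stack(scene)


@pytest.fixture(scope="session")
def plot_table(stack, plots):
    return ft.aggregate_to_plots(stack, plots)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
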