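import numpy as np
import pytest

from vinotaste.synthetic import (
    DyeResponseModel,
    default_dye_model,
    generate_panel,
)


@pytest.fixture(scope="session")
def dye_model() -> DyeResponseModel:
    return default_dye_model()


@pytest.fixture(scope="session")
def panel45():
    """The canonical 23 base wines + 22 mixtures, seeded."""
    return generate_panel(23, 22, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150818)


@pytest.fixture(scope="session")
def tiny_dye_model() -> DyeResponseModel:
    """A hand-built two-peak model with analytically transparent numbers."""
    from vinotaste.chemicals import CHEMICALS

    n_chem = len(CHEMICALS)
    sens = np.zeros((8, 3, n_chem))
    # dye 0 responds only to fructose (idx 2): +40 R, -20 G, +10 B at saturation
    sens[0, :, 2] = [40.0, -20.0, 10.0]
    for d in range(1, 8):
        sens[d, d % 3, (d + 3) % n_chem] = 5.0 + d
    peaks = [np.array([[550.0, 30.0, 1.0]])] + [
        np.array([[450.0 + 30 * d, 25.0, 0.5]]) for d in range(1, 8)
    ]
    gains = [np.full((1, n_chem), 0.5) for _ in range(8)]
    return DyeResponseModel(
        dyes=default_dye_model().dyes,
        baseline_rgb=np.full((8, 3), 128.0),
        sensitivity=sens,
        half_saturation=np.full(n_chem, 1000.0),
        peaks=peaks,
        spectral_gain=gains,
    )
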