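import numpy as np
import pytest

from punctaquant.golgi import CellGeometry, dispersion_profile
from punctaquant.simulate import GolgiSimConfig, NoiseModel, TransportSimConfig, simulate_golgi_image


@pytest.fixture
def circle_geometry() -> CellGeometry:
    """Circular cell (radius 80 px) with circular nucleus (24 px), centred."""
    return CellGeometry.from_ellipses((95.5, 95.5), (24.0, 24.0), (80.0, 80.0), background_angle=200.0)


@pytest.fixture
def small_transport_config():
    def make(**overrides) -> TransportSimConfig:
        params = dict(n_puncta=6, n_frames=60, seed=0)
        params.update(overrides)
        return TransportSimConfig(**params)

    return make


@pytest.fixture
def golgi_cell_factory():
    """Simulate a realistic cell image + its dispersion profile."""

    def make(scale: float, seed: int, profile: bool = True):
        cfg = GolgiSimConfig(
            dispersion_scale=scale,
            seed=seed,
            background_amplitude=100.0,
            noise=NoiseModel(poisson=True, gaussian_sd=10.0),
        )
        img, geom, truth = simulate_golgi_image(cfg)
        if not profile:
            return img, geom, truth
        return dispersion_profile(img, geom)

    return make
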