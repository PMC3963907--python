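import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fruittherm.config import RunConfig
from fruittherm.geometry import Ellipsoid, StoneGeometry, build_fruit_mesh

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mature_fruit() -> Ellipsoid:
    """Mature (M4) Cogshall-like fruit: 12.5 x 8.0 x 7.5 cm."""
    return Ellipsoid(0.0625, 0.040, 0.0375)


@pytest.fixture(scope="session")
def fruit_mesh(mature_fruit):
    stone = StoneGeometry.from_ratios(mature_fruit, (0.85, 0.45, 0.30))
    return build_fruit_mesh(mature_fruit, stone, 0.001, 800, (0.0, 1.0, 0.0))


@pytest.fixture(scope="session")
def sphere_mesh():
    r = 4e-3
    return build_fruit_mesh(
        Ellipsoid(r, r, r),
        StoneGeometry(0.0, 0.0, 0.0),
        peel_thickness=r * 1e-3,
        target_cells=800,
        sun_normal=(1.0, 1.0, 1.0),
    )


@pytest.fixture()
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140324)
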