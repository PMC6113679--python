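import numpy as np
import pytest

from addftir import (
    ParticleSpec,
    SceneSpec,
    Spectrum,
    SpectrumMetadata,
    WavenumberGrid,
    default_imaging_grid,
    synth_library,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def atr_grid() -> WavenumberGrid:
    """Full ATR range, 4 cm^-1 spacing (4000..400)."""
    return WavenumberGrid(np.arange(4000.0, 399.0, -4.0))


@pytest.fixture(scope="session")
def imaging_grid() -> WavenumberGrid:
    """Imaging range 3600..1256, 8 cm^-1 spacing."""
    return default_imaging_grid()


@pytest.fixture
def flat_spectrum(atr_grid) -> Spectrum:
    return Spectrum(atr_grid, np.full(len(atr_grid), 0.5),
                    SpectrumMetadata("flat"))


@pytest.fixture(scope="session")
def library5(imaging_grid):
    """Five well-separated pseudo-polymers, one cluster each."""
    return synth_library(5, seed=1, grid=imaging_grid)


# 12 non-touching rectangular particles from 5 pseudo-polymers on 64 x 64;
# gaps far exceed the closing radius so particle identity is unambiguous
TWELVE_PARTICLES = tuple(
    ParticleSpec(pid, pos, "rect", size)
    for pid, pos, size in [
        ("polymer_01", (2, 2), (1, 1)),
        ("polymer_02", (2, 12), (2, 2)),
        ("polymer_03", (2, 24), (3, 3)),
        ("polymer_04", (2, 36), (2, 4)),
        ("polymer_05", (2, 48), (3, 2)),
        ("polymer_01", (20, 4), (4, 4)),
        ("polymer_02", (20, 20), (1, 3)),
        ("polymer_03", (20, 34), (5, 5)),
        ("polymer_04", (20, 50), (2, 2)),
        ("polymer_05", (40, 6), (3, 5)),
        ("polymer_01", (40, 25), (4, 2)),
        ("polymer_02", (40, 40), (5, 3)),
    ]
)


@pytest.fixture(scope="session")
def twelve_particle_scene() -> SceneSpec:
    return SceneSpec(shape=(64, 64), particles=TWELVE_PARTICLES, seed=0)
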