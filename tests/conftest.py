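import numpy as np
import pytest

from eemferm.data_model import EEMGrid, EEMeasurement, SpectrumSeries
from eemferm.synthetic_data import SimConfig, generate_experiment


@pytest.fixture
def tiny_grid() -> EEMGrid:
    """3 excitation x 7 emission grid small enough for hand checks."""
    return EEMGrid(excitation=[300.0, 400.0, 500.0], emission=300.0 + 50.0 * np.arange(7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_measurement(grid, rng=None, well="A1", time=0.0):
    if rng is None:
        data = np.arange(np.prod(grid.shape), dtype=float).reshape(grid.shape)
    else:
        data = rng.uniform(0, 100, size=grid.shape)
    return EEMeasurement(well_id=well, time=time, intensities=data, grid=grid)


@pytest.fixture
def toy_series(tiny_grid, rng) -> SpectrumSeries:
    """One well, three time points, random non-negative intensities."""
    ms = [make_measurement(tiny_grid, rng, "A1", t) for t in (0.0, 0.5, 1.0)]
    return SpectrumSeries(well_id="A1", measurements=ms)


def small_plate_config(seed: int = 1, **overrides) -> SimConfig:
    """Scaled-down magnesium plate: coarse emission axis, hourly spectra.

    Keeps the full 30 h span (the sparse 6 h schedule needs it) but cuts the
    pixel count ~10x and the spectra count 2x, so a full plate generates in
    well under a second.
    """
    defaults = dict(
        preset="Mg",
        seed=seed,
        emission_preset="coarse",
        cadence=1.0,
        dt=0.02,
        replicates=2,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_mg_plate():
    """Session-wide scaled-down synthetic magnesium plate (seed 1)."""
    return generate_experiment(small_plate_config(seed=1))
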