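import numpy as np
import pytest

from phototox import pipeline
from phototox.config import PipelineConfig
from phototox.spectra import (
    UNIT_DIMENSIONLESS,
    UNIT_SPECTRAL_IRRADIANCE,
    UNIT_SPECTRAL_RADIANCE,
    SpectralCurve,
)


def flat_curve(level, unit=UNIT_SPECTRAL_RADIANCE, start=380.0, stop=700.0, n=33):
    grid = np.linspace(start, stop, n)
    return SpectralCurve(grid, np.full(n, float(level)), unit)


@pytest.fixture
def flat_radiance():
    return flat_curve(10.0, UNIT_SPECTRAL_RADIANCE)


@pytest.fixture
def flat_irradiance():
    return flat_curve(2.0, UNIT_SPECTRAL_IRRADIANCE)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_radiometry(default_config):
    return pipeline.run_radiometry(default_config)
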