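"""Bundled reference tables and default geometries.

The two shipped tables are synthetic stand-ins: a smooth solar-like
spectral irradiance (the real pipeline consumes a tabulated reference
solar spectrum in the same two-column format) and an ocular-media
transmittance anchor table with the canonical shape — opaque below
390 nm, steep rise through the violet, plateau around 0.6-0.75 in the
green and red.  Both are plain CSV and can be replaced from the
pipeline configuration.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .radiometry import ExposureConfig, EyeGeometry
from .spectra import (
    UNIT_DIMENSIONLESS,
    UNIT_SPECTRAL_IRRADIANCE,
    SpectralCurve,
    default_grid,
)


def _bundled(name: str):
    return resources.files("phototox.data").joinpath(name)


def default_solar_spectrum() -> SpectralCurve:
    """The bundled solar-like spectral irradiance table (W/m^2/nm)."""
    with resources.as_file(_bundled("solar_spectrum_synthetic.csv")) as path:
        return SpectralCurve.from_csv(path, unit=UNIT_SPECTRAL_IRRADIANCE)


def load_transmittance_anchors(path=None) -> SpectralCurve:
    """Raw transmittance anchor table (bundled one if ``path`` is None)."""
    if path is None:
        with resources.as_file(_bundled("ocular_transmittance_synthetic.csv")) as p:
            return SpectralCurve.from_csv(p, unit=UNIT_DIMENSIONLESS)
    return SpectralCurve.from_csv(path, unit=UNIT_DIMENSIONLESS)


def ocular_transmittance(grid: np.ndarray | None = None, anchors: SpectralCurve | None = None) -> SpectralCurve:
    """Monotone (PCHIP) interpolation of the transmittance anchors onto
    ``grid`` (default 1 nm, 380-700 nm).  Wavelengths outside the anchor
    support are clamped to the boundary values."""
    anchors = anchors or load_transmittance_anchors()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    interp = PchipInterpolator(anchors.wavelengths_nm, anchors.values, extrapolate=False)
    vals = interp(grid)
    vals = np.where(grid < anchors.wavelengths_nm[0], anchors.values[0], vals)
    vals = np.where(grid > anchors.wavelengths_nm[-1], anchors.values[-1], vals)
    return SpectralCurve(grid, np.clip(vals, 0.0, 1.0), UNIT_DIMENSIONLESS)


def default_eye(grid: np.ndarray | None = None) -> EyeGeometry:
    """5 mm pupil, 17 mm eye, bundled ocular transmittance."""
    return EyeGeometry(transmittance=ocular_transmittance(grid))


def default_exposure() -> ExposureConfig:
    """f = 66, 18 h light, 6 h dark rest."""
    return ExposureConfig()
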