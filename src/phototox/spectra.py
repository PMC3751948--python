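"""Wavelength-indexed spectral curves.

The :class:`SpectralCurve` is the common container for every spectral
quantity handled by the pipeline: source radiance, corneal/retinal
irradiance, ocular-media transmittance, chromophore absorbance and
plate-reader signals.  Units are tracked as plain strings from a small
registry so that the radiometric stages can refuse physically
meaningless compositions (e.g. applying the pupil-throughput step to a
curve that is not a corneal irradiance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised units.  Spectral quantities are per-nm densities.
UNIT_SPECTRAL_IRRADIANCE = "W/m^2/nm"
UNIT_SPECTRAL_RADIANCE = "W/sr/m^2/nm"
UNIT_SPECTRAL_POWER = "W/nm"
UNIT_DIMENSIONLESS = "dimensionless"
UNIT_ABSORBANCE = "AU"
UNIT_RFU = "RFU"
UNIT_RLU = "RLU"

KNOWN_UNITS = frozenset(
    {
        UNIT_SPECTRAL_IRRADIANCE,
        UNIT_SPECTRAL_RADIANCE,
        UNIT_SPECTRAL_POWER,
        UNIT_DIMENSIONLESS,
        UNIT_ABSORBANCE,
        UNIT_RFU,
        UNIT_RLU,
    }
)

#: Units whose values must be non-negative.
_NONNEGATIVE_UNITS = {
    UNIT_SPECTRAL_IRRADIANCE,
    UNIT_SPECTRAL_RADIANCE,
    UNIT_SPECTRAL_POWER,
    UNIT_RFU,
    UNIT_RLU,
}


@dataclass(frozen=True)
class SpectralCurve:
    """A physical quantity sampled on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing sample wavelengths in nanometres (length >= 2).
    values
        Quantity sampled at those wavelengths, same length.
    unit
        One of the units in :data:`KNOWN_UNITS`.  Transmittance curves
        (``dimensionless``) must lie in [0, 1]; radiometric quantities and
        plate-reader signals must be non-negative.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: str = UNIT_DIMENSIONLESS

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectral curve needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError("wavelengths and values must be finite")
        if self.unit not in KNOWN_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(KNOWN_UNITS)}")
        if self.unit == UNIT_DIMENSIONLESS and (vals.min() < 0 or vals.max() > 1 + 1e-12):
            raise ValueError("transmittance values must lie in [0, 1]")
        if self.unit in _NONNEGATIVE_UNITS and vals.min() < 0:
            raise ValueError(f"{self.unit} values must be non-negative")

    # -- basic algebra -------------------------------------------------

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "SpectralCurve":
        return SpectralCurve(self.wavelengths_nm, values, unit or self.unit)

    def scaled(self, factor: float) -> "SpectralCurve":
        """Multiply by a non-negative scalar, keeping the unit."""
        return self.with_values(self.values * factor)

    def __mul__(self, other: "SpectralCurve") -> "SpectralCurve":
        """Pointwise product with a dimensionless curve on the same grid."""
        if not isinstance(other, SpectralCurve):
            return NotImplemented
        if other.unit != UNIT_DIMENSIONLESS:
            raise ValueError("can only multiply by a dimensionless curve")
        if not np.array_equal(self.wavelengths_nm, other.wavelengths_nm):
            raise ValueError("grids differ; resample first")
        return self.with_values(self.values * other.values)

    def value_at(self, wavelength_nm: float) -> float:
        """Linear interpolation at a single wavelength (0 outside support)."""
        return float(
            np.interp(wavelength_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        )

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.wavelengths_nm, "value": self.values})

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        """Write the two-column CSV format (``wavelength_nm,value``)."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, unit: str = UNIT_DIMENSIONLESS) -> "SpectralCurve":
        df = pd.read_csv(path, comment="#")
        if not {"wavelength_nm", "value"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns wavelength_nm,value")
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), unit)


def default_grid(start_nm: float = 380.0, stop_nm: float = 700.0, step_nm: float = 1.0) -> np.ndarray:
    """The pipeline's working wavelength grid (1 nm from 380 to 700 by default)."""
    n = int(round((stop_nm - start_nm) / step_nm))
    return start_nm + step_nm * np.arange(n + 1)


def resample(curve: SpectralCurve, grid: np.ndarray, fill: str = "raise") -> SpectralCurve:
    """Linearly interpolate ``curve`` onto ``grid``.

    Parameters
    ----------
    curve
        Input curve; its unit is preserved.
    grid
        Strictly increasing target wavelengths (nm).
    fill
        ``"raise"`` (default) requires ``grid`` to lie within the curve's
        support; ``"zero"`` assigns 0 outside the support.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty target grid")
    if grid.ndim != 1 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("target grid must be 1-D and strictly increasing")
    lo, hi = curve.wavelengths_nm[0], curve.wavelengths_nm[-1]
    outside = (grid < lo) | (grid > hi)
    if outside.any() and fill != "zero":
        raise ValueError(
            f"grid extends outside curve support [{lo}, {hi}] nm; "
            "pass fill='zero' to zero-fill"
        )
    vals = np.interp(grid, curve.wavelengths_nm, curve.values, left=0.0, right=0.0)
    if grid.size < 2:
        # degenerate single-point grids only make sense as probes; widen
        # by duplicating the point offset epsilon is not meaningful, so
        # we simply disallow constructing a 1-point curve.
        raise ValueError("target grid must contain at least 2 points to form a curve")
    return SpectralCurve(grid, vals, curve.unit)
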