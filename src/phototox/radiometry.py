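"""Retinal irradiance from a light source or the sun.

Implements the simplified eye/source model used to normalise in vitro
light exposures to physiological retinal levels.  The source is a small
emitter of spectral radiance ``L(lambda)`` at distance ``u`` from the
cornea; cornea, pupil and nodal planes are taken as coincident and the
eye is a single refracting element of length ``u'``:

* corneal irradiance          ``E_cornea = L * S_source / u**2``
* radiant power at the pupil  ``Phi_pupil = E_cornea * A_pupil``
* retinal image area          ``S_retina = S_source * (u' / u)**2``
* retinal irradiance          ``E_retina = Phi_pupil * tau / S_retina``

which collapses to the source-geometry-free closed form
``E_retina = L * tau * A_pupil / u'**2``: the emitter's size and distance
cancel, as they must for an imaging system.

Plate-level exposure irradiances are the retinal band irradiances scaled
by the acceleration factor ``f`` (default 66), which compresses a chronic
exposure into the 18 h in vitro protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    UNIT_DIMENSIONLESS,
    UNIT_SPECTRAL_IRRADIANCE,
    UNIT_SPECTRAL_POWER,
    UNIT_SPECTRAL_RADIANCE,
    SpectralCurve,
    resample,
)

#: Apparent angular radius of the solar disk seen from the ground, degrees.
SUN_ANGULAR_RADIUS_DEG = 0.266


@dataclass(frozen=True)
class SourceGeometry:
    """Emitting surface and viewing distance of a small light source."""

    emitting_area_m2: float
    distance_m: float
    #: the point-source approximation is considered valid while
    #: area / distance**2 stays below this solid-angle-like threshold (sr).
    small_source_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.emitting_area_m2 < 0:
            raise ValueError("emitting area must be >= 0")
        if self.distance_m <= 0:
            raise ValueError("distance must be > 0")

    @property
    def solid_angle_sr(self) -> float:
        return self.emitting_area_m2 / self.distance_m**2

    @property
    def is_small_source(self) -> bool:
        return self.solid_angle_sr < self.small_source_threshold


@dataclass(frozen=True)
class EyeGeometry:
    """Pupil, eye length and ocular-media transmittance.

    Defaults: 5 mm pupil, 17 mm eye.  ``transmittance`` is the combined
    filter of cornea, aqueous humour, lens and vitreous; ``None`` means a
    perfectly transparent eye (tau = 1), convenient for unit checks.
    """

    pupil_diameter_m: float = 5e-3
    eye_length_m: float = 17e-3
    transmittance: SpectralCurve | None = None

    def __post_init__(self) -> None:
        if self.pupil_diameter_m <= 0 or self.eye_length_m <= 0:
            raise ValueError("pupil diameter and eye length must be > 0")
        if self.transmittance is not None and self.transmittance.unit != UNIT_DIMENSIONLESS:
            raise ValueError("transmittance curve must be dimensionless")

    @property
    def pupil_area_m2(self) -> float:
        return np.pi * (self.pupil_diameter_m / 2) ** 2

    def tau_on(self, grid: np.ndarray) -> np.ndarray:
        """Transmittance sampled on ``grid`` (1.0 everywhere if unset)."""
        if self.transmittance is None:
            return np.ones_like(np.asarray(grid, dtype=float))
        return resample(self.transmittance, grid, fill="zero").values


@dataclass(frozen=True)
class ExposureConfig:
    """In vitro exposure protocol constants."""

    acceleration_factor: float = 66.0
    exposure_hours: float = 18.0
    post_exposure_rest_hours: float = 6.0  # metadata only

    def __post_init__(self) -> None:
        if self.acceleration_factor <= 0:
            raise ValueError("acceleration factor must be > 0")
        if self.exposure_hours < 0 or self.post_exposure_rest_hours < 0:
            raise ValueError("exposure durations must be >= 0")

    @property
    def exposure_seconds(self) -> float:
        return self.exposure_hours * 3600.0


# ---------------------------------------------------------------------
# radiometric chain
# ---------------------------------------------------------------------

def corneal_irradiance(radiance: SpectralCurve, source: SourceGeometry) -> SpectralCurve:
    """Spectral irradiance at the cornea from a small source.

    ``E_cornea(lambda) = L(lambda) * S_source / u**2`` (point-source
    inverse-square law).  Warns if the source violates the small-source
    assumption.
    """
    if radiance.unit != UNIT_SPECTRAL_RADIANCE:
        raise ValueError(f"expected spectral radiance, got {radiance.unit}")
    if not source.is_small_source:
        warnings.warn(
            "source subtends a large solid angle; the point-source "
            "approximation degrades",
            stacklevel=2,
        )
    factor = source.emitting_area_m2 / source.distance_m**2
    return radiance.with_values(radiance.values * factor, UNIT_SPECTRAL_IRRADIANCE)


def pupil_flux(corneal: SpectralCurve, eye: EyeGeometry) -> SpectralCurve:
    """Radiant power entering the pupil: ``Phi(lambda) = E_cornea * A_pupil``."""
    if corneal.unit != UNIT_SPECTRAL_IRRADIANCE:
        raise ValueError(f"expected spectral irradiance, got {corneal.unit}")
    return corneal.with_values(corneal.values * eye.pupil_area_m2, UNIT_SPECTRAL_POWER)


def retinal_image_area(source: SourceGeometry, eye: EyeGeometry) -> float:
    """Retinal image area of the source: ``S_retina = S_source * (u'/u)**2``."""
    return source.emitting_area_m2 * (eye.eye_length_m / source.distance_m) ** 2


def retinal_irradiance(
    radiance: SpectralCurve, source: SourceGeometry, eye: EyeGeometry
) -> SpectralCurve:
    """Retinal spectral irradiance through the full chain.

    Computed as ``Phi_pupil * tau / S_retina``; algebraically this equals
    ``L * tau * A_pupil / u'**2`` and is independent of the source's size
    and distance.
    """
    s_retina = retinal_image_area(source, eye)
    if s_retina <= 0:
        raise ValueError("retinal image area is zero; source has no extent")
    flux = pupil_flux(corneal_irradiance(radiance, source), eye)
    tau = eye.tau_on(flux.wavelengths_nm)
    return flux.with_values(flux.values * tau / s_retina, UNIT_SPECTRAL_IRRADIANCE)


def solar_retinal_irradiance(
    solar_irradiance: SpectralCurve,
    eye: EyeGeometry,
    mode: str = "transmittance-only",
    sun_angular_radius_deg: float = SUN_ANGULAR_RADIUS_DEG,
    scale: float = 1.0,
) -> SpectralCurve:
    """Retinal spectral irradiance produced by a tabulated solar spectrum.

    Two rules are available for the geometric factor that converts the
    ground-level solar spectral irradiance into a retinal one:

    ``"direct-ratio"``
        Treats the tabulated irradiance as the corneal irradiance of the
        solar disk imaged onto the retina:
        ``E_retina = E_solar * tau * A_pupil / S_retina_sun`` with
        ``S_retina_sun = pi * (u' * tan(theta_sun))**2`` from the sun's
        angular radius.  This is the direct-viewing (sun-gazing) geometry
        and yields retinal irradiances far above ambient-viewing levels.

    ``"transmittance-only"`` (default)
        ``E_retina = scale * E_solar * tau`` — the ocular-media filter
        applied to the solar spectrum, with an explicit ``scale`` chosen
        by the caller (the pipeline sets it so that the exposure device
        reproduces its configured plate irradiances).  This represents an
        averaged, orientation-free daylight exposure.
    """
    if solar_irradiance.unit != UNIT_SPECTRAL_IRRADIANCE:
        raise ValueError(f"expected spectral irradiance, got {solar_irradiance.unit}")
    tau = eye.tau_on(solar_irradiance.wavelengths_nm)
    if mode == "direct-ratio":
        theta = np.deg2rad(sun_angular_radius_deg)
        s_retina_sun = np.pi * (eye.eye_length_m * np.tan(theta)) ** 2
        factor = eye.pupil_area_m2 / s_retina_sun
    elif mode == "transmittance-only":
        factor = scale
    else:
        raise ValueError(f"unknown solar mode {mode!r}")
    return solar_irradiance.with_values(solar_irradiance.values * tau * factor)


def plate_irradiance(retinal_band_irradiance_w_m2, cfg: ExposureConfig):
    """Plate-level exposure irradiance: retinal band irradiance times ``f``."""
    value = np.asarray(retinal_band_irradiance_w_m2, dtype=float)
    if np.any(value < 0):
        raise ValueError("irradiance must be >= 0")
    out = value * cfg.acceleration_factor
    return float(out) if out.ndim == 0 else out


def radiant_exposure_j_m2(plate_irradiance_w_m2, cfg: ExposureConfig):
    """Radiant exposure (dose) delivered over the configured exposure time."""
    value = np.asarray(plate_irradiance_w_m2, dtype=float)
    out = value * cfg.exposure_seconds
    return float(out) if out.ndim == 0 else out


W_M2_PER_MW_CM2 = 10.0  # 1 mW/cm^2 = 10 W/m^2


def mw_cm2(value_w_m2):
    """Convert W/m^2 to the device display unit mW/cm^2."""
    return np.asarray(value_w_m2, dtype=float) / W_M2_PER_MW_CM2
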