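"""Parametric spectral model of the lipofuscin fluorophore A2E.

A2E (N-retinylidene-N-retinylethanolamine) is the photosensitizer that
accumulates in RPE lysosomes with age.  Its absorbance is modelled as
the sum of two gaussian peaks (UV peak near 335 nm, visible peak at
440 nm); emission is a single gaussian whose centre differs between the
free form (640 nm) and the intracellular form (620 nm) — the blue shift
is an observed property stored without mechanistic interpretation.

The module also carries the linear intracellular-uptake calibration used
for chromatographic (UPLC) quantification: cells incubated at ``c`` uM
accumulate ``endogenous + slope * c`` ng of A2E per 1e5 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import UNIT_ABSORBANCE, UNIT_RFU, SpectralCurve


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _gaussian(grid: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    sigma = _fwhm_to_sigma(fwhm)
    return amplitude * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


@dataclass(frozen=True)
class ChromophoreModel:
    """A2E spectral parameters and uptake calibration.

    Peak positions are measured quantities; widths and amplitudes shape
    the synthetic curves and are free parameters (the gaussian FWHMs
    default to 30 nm and 45 nm for the UV and visible absorbance peaks).
    ``uptake_slope_ng_per_uM`` is a synthetic calibration constant: only
    the linearity of uptake (not its slope) is an observed property.
    """

    uv_peak_nm: float = 335.0
    uv_fwhm_nm: float = 30.0
    uv_amplitude_au: float = 0.9
    vis_peak_nm: float = 440.0
    vis_fwhm_nm: float = 45.0
    vis_amplitude_au: float = 1.0
    emission_free_peak_nm: float = 640.0
    emission_intracellular_peak_nm: float = 620.0
    emission_fwhm_nm: float = 90.0
    uptake_slope_ng_per_uM: float = 0.25
    endogenous_ng_per_1e5_cells: float = 0.032

    def __post_init__(self) -> None:
        for name in ("uv_fwhm_nm", "uv_amplitude_au", "vis_fwhm_nm", "vis_amplitude_au",
                     "emission_fwhm_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.uptake_slope_ng_per_uM < 0 or self.endogenous_ng_per_1e5_cells < 0:
            raise ValueError("uptake parameters must be >= 0")


def absorbance_spectrum(model: ChromophoreModel, grid: np.ndarray) -> SpectralCurve:
    """A2E absorbance (AU) on ``grid``: two positive gaussian peaks."""
    grid = np.asarray(grid, dtype=float)
    vals = _gaussian(grid, model.uv_peak_nm, model.uv_fwhm_nm, model.uv_amplitude_au)
    vals = vals + _gaussian(grid, model.vis_peak_nm, model.vis_fwhm_nm, model.vis_amplitude_au)
    return SpectralCurve(grid, vals, UNIT_ABSORBANCE)


def emission_spectrum(
    model: ChromophoreModel, grid: np.ndarray, form: str = "free"
) -> SpectralCurve:
    """A2E fluorescence emission (arbitrary RFU) for the free or
    intracellular form."""
    grid = np.asarray(grid, dtype=float)
    if form == "free":
        center = model.emission_free_peak_nm
    elif form == "intracellular":
        center = model.emission_intracellular_peak_nm
    else:
        raise ValueError(f"unknown form {form!r}; expected 'free' or 'intracellular'")
    vals = _gaussian(grid, center, model.emission_fwhm_nm, 1.0)
    return SpectralCurve(grid, vals, UNIT_RFU)


def difference_spectrum(loaded: SpectralCurve, untreated: SpectralCurve) -> SpectralCurve:
    """Pointwise difference (loaded - untreated) of two spectra on a
    common grid; isolates the chromophore's contribution from the cell
    background.  May be negative."""
    if loaded.unit != untreated.unit:
        raise ValueError("spectra must share a unit")
    if not np.array_equal(loaded.wavelengths_nm, untreated.wavelengths_nm):
        raise ValueError("spectra must share a grid; resample first")
    return loaded.with_values(loaded.values - untreated.values)


def intracellular_content(incubated_uM, model: ChromophoreModel):
    """A2E content (ng per 1e5 cells) after incubation at ``incubated_uM``.

    Linear uptake on top of the endogenous content.
    """
    c = np.asarray(incubated_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("incubation concentration must be >= 0")
    out = model.endogenous_ng_per_1e5_cells + model.uptake_slope_ng_per_uM * c
    return float(out) if out.ndim == 0 else out


def fit_uptake(incubated_uM, content_ng) -> dict:
    """Ordinary least-squares line through measured uptake points.

    Returns slope, intercept and r^2 — the linear calibration used to
    quantify intracellular A2E from chromatographic peak areas.
    """
    x = np.asarray(incubated_uM, dtype=float)
    y = np.asarray(content_ng, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two calibration points")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r_squared": r2}
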