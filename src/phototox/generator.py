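"""Seeded generator of triplex plate-assay data.

Emulates the measured structure of the phototoxicity screen: 96-well
plates split into six 16-well subdivisions (five illuminated 10 nm bands
plus one dark control), four A2E concentrations with four wells each,
and per-well viability (fluorescence), caspase-3/7 (luminescence) and
necrosis (fluorescence) readouts.

The generative model composes

* a dark A2E cytotoxicity sigmoid (4-parameter logistic, IC50 67.5 uM),
* a wavelength-dependent photochemical hazard driven by the radiant
  exposure, the A2E absorbance at the band centre and the intracellular
  A2E content, with a short-wavelength efficiency factor and a small
  A2E-independent damage kernel in the violet,
* a caspase channel proportional to the A2E-mediated part of the
  light-induced viability deficit (no apoptosis without A2E),
* a light-independent necrosis channel,
* multiplicative log-normal well noise and a per-experiment scale factor
  standing in for varying cell densities between experiments.

All randomness flows from a single seed, so a pipeline run is exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import DARK, Band, PlateLayout
from .chromophore import ChromophoreModel, absorbance_spectrum, intracellular_content
from .radiometry import ExposureConfig


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic assay.

    Dose-response constants (``dark_*``) mirror the dark-toxicity sigmoid
    of A2E itself; the photohazard constants are synthetic calibration
    values chosen so that, at the default plate irradiances, apoptosis is
    sharply confined to the 420-450 nm bands at the intermediate A2E
    concentrations while A2E-free viability losses stay modest and
    restricted to the violet bands.  They are not measured quantities.
    """

    # dark A2E toxicity (fraction of untreated viability)
    dark_ic50_uM: float = 67.5
    dark_hill: float = 4.0
    dark_top: float = 1.0
    dark_bottom: float = 0.0

    # photochemical hazard
    #: hazard per (J/m^2 of radiant exposure x AU of absorbance x ng/1e5 cells)
    photohazard_coeff: float = 3.4e-6
    #: weight of the A2E-independent violet damage kernel, in the same
    #: absorbance-times-content units as the A2E term
    a2e_free_component: float = 0.30
    a2e_free_center_nm: float = 425.0
    a2e_free_fwhm_nm: float = 35.0
    #: short-wavelength photochemical efficiency exponent: the hazard per
    #: absorbed dose scales as (reference_nm / lambda)**exponent
    short_wavelength_exponent: float = 12.0
    reference_nm: float = 440.0

    # caspase / necrosis channels
    apoptosis_baseline: float = 1.0
    apoptosis_gain: float = 1.5
    necrosis_level: float = 0.3
    necrosis_a2e_slope_per_uM: float = 0.025

    # noise and scales
    noise_cv: float = 0.10
    experiment_scale_sd: float = 0.15
    viability_scale_rfu: float = 5000.0
    caspase_scale_rlu: float = 800.0
    necrosis_scale_rfu: float = 2000.0

    def __post_init__(self) -> None:
        if self.dark_ic50_uM <= 0 or self.dark_hill <= 0:
            raise ValueError("dark IC50 and Hill coefficient must be > 0")
        if not self.dark_bottom < self.dark_top:
            raise ValueError("dark_bottom must be < dark_top")
        for name in ("photohazard_coeff", "a2e_free_component", "apoptosis_baseline",
                     "apoptosis_gain", "necrosis_level", "noise_cv",
                     "experiment_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def dark_viability_fraction(a2e_uM, p: GeneratorParams):
    """Viability in darkness as a fraction of untreated cells.

    Four-parameter logistic in the incubated A2E concentration:
    ``bottom + (top - bottom) / (1 + (c / ic50)**hill)``.
    """
    c = np.asarray(a2e_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("A2E concentration must be >= 0")
    frac = p.dark_bottom + (p.dark_top - p.dark_bottom) / (
        1.0 + (c / p.dark_ic50_uM) ** p.dark_hill
    )
    return float(frac) if frac.ndim == 0 else frac


def _hazard_terms(
    center_nm: float,
    a2e_uM,
    dose_j_m2: float,
    chromo: ChromophoreModel,
    p: GeneratorParams,
):
    """A2E-mediated and A2E-free hazard exponents for one band."""
    grid = np.array([center_nm - 1.0, center_nm, center_nm + 1.0])
    absorbance = absorbance_spectrum(chromo, grid).values[1]
    content = intracellular_content(a2e_uM, chromo)
    efficiency = (p.reference_nm / center_nm) ** p.short_wavelength_exponent
    sigma = p.a2e_free_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    violet = math.exp(-0.5 * ((center_nm - p.a2e_free_center_nm) / sigma) ** 2)
    scale = p.photohazard_coeff * dose_j_m2
    h_a2e = scale * absorbance * efficiency * np.asarray(content, dtype=float)
    h_free = scale * p.a2e_free_component * violet
    return h_a2e, h_free


def photo_survival_fraction(
    band: Band,
    a2e_uM,
    plate_irradiance_w_m2: float,
    cfg: ExposureConfig,
    chromo: ChromophoreModel,
    p: GeneratorParams,
):
    """Fraction of cells surviving the light exposure (1.0 in darkness).

    Exponential survival against the integrated photochemical hazard:
    ``exp(-k * D * [Q(lambda) * A(lambda) * content(a2e) + phi * B(lambda)])``
    with ``D`` the radiant exposure (J/m^2), ``A`` the A2E absorbance at
    the band centre, ``Q`` the short-wavelength efficiency factor,
    ``B`` the A2E-free violet kernel and ``content`` the intracellular
    A2E mass.  The exponential form keeps the fraction in (0, 1] at any
    dose.
    """
    if plate_irradiance_w_m2 < 0:
        raise ValueError("plate irradiance must be >= 0")
    dose = plate_irradiance_w_m2 * cfg.exposure_seconds
    h_a2e, h_free = _hazard_terms(band.center_nm, a2e_uM, dose, chromo, p)
    out = np.exp(-(h_a2e + h_free))
    return float(out) if np.ndim(out) == 0 else out


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=size)


def generate(
    layouts: list[PlateLayout],
    params: GeneratorParams,
    plate_irradiance_by_band: dict[float, float],
    cfg: ExposureConfig,
    chromo: ChromophoreModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the triplex readout for a list of plate layouts.

    Parameters
    ----------
    layouts
        Plates from :func:`phototox.bands.plan_experiment`.
    plate_irradiance_by_band
        Exposure irradiance (W/m^2) per band centre, as produced by the
        radiometry stage; dark wells receive zero.
    seed
        Single source of randomness; the same seed reproduces the same
        records exactly.

    Returns
    -------
    DataFrame in the long interchange format
    ``experiment, plate, subdivision, well, band_nm, a2e_uM,
    viability, caspase, necrosis``.
    """
    rng = np.random.default_rng(seed)
    df = pd.concat([p.wells for p in layouts], ignore_index=True).copy()

    missing = {
        b for b in df["band_nm"].unique() if b != DARK and float(b) not in plate_irradiance_by_band
    }
    if missing:
        raise ValueError(f"no plate irradiance supplied for bands {sorted(missing)}")

    # per-experiment cell-density scale factor
    experiments = df["experiment"].unique()
    scales = dict(
        zip(
            experiments,
            np.exp(rng.normal(0.0, params.experiment_scale_sd, size=len(experiments))),
        )
    )
    exp_scale = df["experiment"].map(scales).to_numpy()

    a2e = df["a2e_uM"].to_numpy(dtype=float)
    dark_frac = dark_viability_fraction(a2e, params)

    survival = np.ones(len(df))
    apo_deficit = np.zeros(len(df))
    for b in df["band_nm"].unique():
        if b == DARK:
            continue
        mask = (df["band_nm"] == b).to_numpy()
        dose = plate_irradiance_by_band[float(b)] * cfg.exposure_seconds
        h_a2e, h_free = _hazard_terms(float(b), a2e[mask], dose, chromo, params)
        s_total = np.exp(-(h_a2e + h_free))
        s_free = np.exp(-h_free)
        survival[mask] = s_total
        # caspase activation tracks the A2E-mediated part of the deficit
        apo_deficit[mask] = s_free - s_total

    n = len(df)
    viability = (
        params.viability_scale_rfu
        * exp_scale
        * dark_frac
        * survival
        * _lognormal_noise(rng, params.noise_cv, n)
    )
    # baseline caspase luminescence scales with the viable-cell fraction,
    # so light that kills without caspase induction does not inflate the
    # per-viable-cell apoptosis ratio (no apoptosis signal without A2E)
    caspase = (
        params.caspase_scale_rlu
        * exp_scale
        * (params.apoptosis_baseline * dark_frac * survival
           + params.apoptosis_gain * apo_deficit)
        * _lognormal_noise(rng, params.noise_cv, n)
    )
    necrosis = (
        params.necrosis_scale_rfu
        * exp_scale
        * params.necrosis_level
        * (1.0 + params.necrosis_a2e_slope_per_uM * a2e)
        * _lognormal_noise(rng, params.noise_cv, n)
    )

    out = df[["experiment", "plate", "subdivision", "well", "band_nm", "a2e_uM"]].copy()
    out["viability"] = viability
    out["caspase"] = caspase
    out["necrosis"] = necrosis
    return out
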