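"""High-level pipeline stages tying radiometry, simulation and analysis."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis, bands, generator, presets, radiometry, spectra
from .config import PipelineConfig


@dataclass(frozen=True)
class RadiometryResult:
    """Retinal spectrum plus per-band exposure irradiances."""

    retinal_spectrum: spectra.SpectralCurve = field(repr=False)
    table: pd.DataFrame = field(repr=False)  # band_nm, retinal_w_m2, plate_w_m2, plate_mw_cm2

    def plate_irradiance_by_band(self) -> dict[float, float]:
        return dict(zip(self.table["band_nm"], self.table["plate_w_m2"]))


def make_bandset(cfg: PipelineConfig) -> bands.BandSet:
    return bands.make_default_bandset(
        first_nm=cfg.band_first_nm,
        last_nm=cfg.band_last_nm,
        step_nm=cfg.band_step_nm,
        extra_nm=tuple(cfg.band_extra_nm),
        width_nm=cfg.band_width_nm,
        shape=cfg.band_shape,
    )


def make_eye(cfg: PipelineConfig, grid: np.ndarray) -> radiometry.EyeGeometry:
    anchors = presets.load_transmittance_anchors(cfg.tau_csv)
    tau = presets.ocular_transmittance(grid, anchors=anchors)
    return radiometry.EyeGeometry(
        pupil_diameter_m=cfg.pupil_diameter_mm * 1e-3,
        eye_length_m=cfg.eye_length_mm * 1e-3,
        transmittance=tau,
    )


def run_radiometry(cfg: PipelineConfig) -> RadiometryResult:
    """Solar spectrum -> retinal spectral irradiance -> band exposures.

    With the default ``transmittance-only`` mode the ocular-media filter
    shapes the spectrum and the overall scale is set so that the
    brightest band's plate irradiance equals ``plate_peak_mw_cm2``; with
    ``direct-ratio`` the solar-disk imaging geometry fixes the scale and
    no normalization is applied.
    """
    grid = spectra.default_grid(cfg.grid_start_nm, cfg.grid_stop_nm, cfg.grid_step_nm)
    if cfg.solar_csv is None:
        solar = presets.default_solar_spectrum()
    else:
        solar = spectra.SpectralCurve.from_csv(cfg.solar_csv, unit=spectra.UNIT_SPECTRAL_IRRADIANCE)
    solar = spectra.resample(solar, grid, fill="zero")
    eye = make_eye(cfg, grid)
    exposure = cfg.exposure_config()
    bandset = make_bandset(cfg)

    retinal = radiometry.solar_retinal_irradiance(
        solar, eye, mode=cfg.solar_mode, sun_angular_radius_deg=cfg.sun_angular_radius_deg
    )
    band_vals = np.array([bands.band_integrate(retinal, b) for b in bandset])
    plate_vals = radiometry.plate_irradiance(band_vals, exposure)
    if cfg.solar_mode == "transmittance-only":
        peak = plate_vals.max()
        if peak <= 0:
            raise ValueError("all bands received zero irradiance; check inputs")
        scale = cfg.plate_peak_mw_cm2 * radiometry.W_M2_PER_MW_CM2 / peak
        retinal = retinal.scaled(scale)
        band_vals = band_vals * scale
        plate_vals = plate_vals * scale
    table = pd.DataFrame(
        {
            "band_nm": bandset.centers_nm,
            "retinal_w_m2": band_vals,
            "plate_w_m2": plate_vals,
            "plate_mw_cm2": radiometry.mw_cm2(plate_vals),
        }
    )
    return RadiometryResult(retinal_spectrum=retinal, table=table)


def run_simulation(
    cfg: PipelineConfig,
    seed: int | None = None,
    rad: RadiometryResult | None = None,
) -> pd.DataFrame:
    """Plan the plate campaign and generate synthetic triplex records."""
    rad = rad or run_radiometry(cfg)
    seed = cfg.seed if seed is None else seed
    layouts = bands.plan_experiment(
        make_bandset(cfg),
        a2e_levels=tuple(cfg.a2e_levels_uM),
        replicates=cfg.replicates,
        wells_per_condition=cfg.wells_per_condition,
        seed=seed,
    )
    return generator.generate(
        layouts,
        cfg.generator_params(),
        rad.plate_irradiance_by_band(),
        cfg.exposure_config(),
        cfg.chromophore_model(),
        seed=seed,
    )


REQUIRED_COLUMNS = (
    "experiment", "plate", "subdivision", "well", "band_nm", "a2e_uM",
    "viability", "caspase", "necrosis",
)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Schema check for the long interchange format (raises on violation)."""
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"plate data is missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("plate data is empty")
    return records


@dataclass(frozen=True)
class AnalysisResult:
    spectrum: analysis.ActionSpectrum
    dark_fit: analysis.DoseResponseFit
    toxic: analysis.ToxicRange


def run_analysis(
    records: pd.DataFrame,
    cfg: PipelineConfig,
    toxic_channel: str = "apoptosis",
    toxic_a2e_uM: float = 20.0,
) -> AnalysisResult:
    """Normalization, statistics, dark dose-response fit and toxic range."""
    validate_records(records)
    spectrum = analysis.assemble_action_spectrum(
        records, alpha_gate=cfg.alpha_gate, alpha=cfg.alpha
    )
    normalized = analysis.normalize_records(records)
    dark = analysis.experiment_means(normalized, "viability")
    dark = dark[dark["band_nm"] == bands.DARK]
    dose_means = dark.groupby("a2e_uM")["value"].mean()
    try:
        fit = analysis.fit_dose_response(dose_means.index.to_numpy(), dose_means.to_numpy())
        if not fit.flagged and np.isfinite(fit.ic50) and fit.ic50 > dose_means.index.max():
            fit = replace(
                fit, flagged=True,
                message="IC50 beyond tested dose range; value is extrapolated",
            )
    except ValueError as err:
        fit = analysis.DoseResponseFit(
            top=np.nan, bottom=np.nan, ic50=np.nan, hill=np.nan, r_squared=np.nan,
            n_points=int(dose_means.size), flagged=True, message=str(err),
        )
    toxic = analysis.toxic_range(
        spectrum, toxic_channel, toxic_a2e_uM,
        step_nm=cfg.band_step_nm, half_width_nm=cfg.band_width_nm / 2,
        blue_green=(cfg.band_first_nm, cfg.band_last_nm),
    )
    return AnalysisResult(spectrum=spectrum, dark_fit=fit, toxic=toxic)
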