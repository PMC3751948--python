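"""The 10 nm illumination-band design and its mapping onto 96-well plates.

The exposure device provides fifteen 10 nm channels: fourteen bands
covering the blue-green range (centres 390, 400, ..., 520 nm) plus a
630 nm control band.  Five bands are run simultaneously per plate, each
illuminating one 16-well subdivision, while a sixth subdivision stays in
darkness as the plate's own control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectralCurve, resample

DARK = "DARK"

#: default A2E incubation concentrations (uM)
DEFAULT_A2E_LEVELS = (0.0, 12.5, 20.0, 40.0)


@dataclass(frozen=True)
class Band:
    """A narrow illumination band."""

    center_nm: float
    width_nm: float = 10.0
    shape: str = "rectangular"  # or "gaussian-fwhm"

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be > 0")
        if self.center_nm <= self.width_nm / 2:
            raise ValueError("band center must exceed half its width")
        if self.shape not in ("rectangular", "gaussian-fwhm"):
            raise ValueError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of bands with unique centres."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        centers = [b.center_nm for b in self.bands]
        if len(set(centers)) != len(centers):
            raise ValueError("band centers must be unique")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([b.center_nm for b in self.bands])


def make_default_bandset(
    first_nm: float = 390.0,
    last_nm: float = 520.0,
    step_nm: float = 10.0,
    extra_nm: tuple[float, ...] = (630.0,),
    width_nm: float = 10.0,
    shape: str = "rectangular",
) -> BandSet:
    """The device's band design: 14 blue-green bands in 10 nm increments
    from 390 to 520 nm, plus a 630 nm control band."""
    n = int(round((last_nm - first_nm) / step_nm))
    centers = [first_nm + i * step_nm for i in range(n + 1)]
    centers += [c for c in extra_nm if c not in centers]
    return BandSet(tuple(Band(c, width_nm, shape) for c in centers))


def band_integrate(spectrum: SpectralCurve, band: Band) -> float:
    """Integrate a spectral irradiance over one band, returning W/m^2.

    Rectangular bands use the trapezoidal integral of the spectrum over
    [center - width/2, center + width/2]; gaussian bands integrate the
    spectrum against a unit-area gaussian of FWHM = width.  Regions where
    the spectrum is undefined contribute zero.
    """
    if band.shape == "rectangular":
        lo = band.center_nm - band.width_nm / 2
        hi = band.center_nm + band.width_nm / 2
        grid = np.union1d(
            np.array([lo, hi]),
            spectrum.wavelengths_nm[
                (spectrum.wavelengths_nm > lo) & (spectrum.wavelengths_nm < hi)
            ],
        )
        vals = np.interp(grid, spectrum.wavelengths_nm, spectrum.values, left=0.0, right=0.0)
        return float(np.trapezoid(vals, grid))
    # gaussian-fwhm
    sigma = band.width_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    grid = np.linspace(band.center_nm - 5 * sigma, band.center_nm + 5 * sigma, 501)
    kernel = np.exp(-0.5 * ((grid - band.center_nm) / sigma) ** 2)
    kernel /= np.trapezoid(kernel, grid)
    vals = np.interp(grid, spectrum.wavelengths_nm, spectrum.values, left=0.0, right=0.0)
    return float(np.trapezoid(vals * kernel, grid))


# ---------------------------------------------------------------------
# plate layouts
# ---------------------------------------------------------------------

_ROWS = "ABCDEFGH"
N_SUBDIVISIONS = 6
WELLS_PER_SUBDIVISION = 16
#: subdivision index reserved for the dark control (fixed by convention)
DARK_SUBDIVISION = 5


@dataclass(frozen=True)
class PlateLayout:
    """One 96-well plate: six 4x4 subdivisions, five illuminated + one dark.

    ``wells`` is a DataFrame with one row per well and columns
    ``experiment, plate, subdivision, well, row, col, band_nm, a2e_uM``
    (``band_nm`` holds the band centre, or the string ``DARK``).
    """

    experiment: int
    plate: int
    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.wells) != 96:
            raise ValueError("a plate layout must contain exactly 96 wells")
        n_dark = (self.wells["band_nm"] == DARK).sum()
        if n_dark != WELLS_PER_SUBDIVISION:
            raise ValueError("exactly one 16-well subdivision must be dark")

    @property
    def band_centers(self) -> list[float]:
        vals = self.wells.loc[self.wells["band_nm"] != DARK, "band_nm"].unique()
        return sorted(float(v) for v in vals)


def _subdivision_wells(subdivision: int) -> list[tuple[str, int, int]]:
    """(well name, row index, column index) of a 4x4 subdivision.

    Subdivisions tile the plate as 2 row-blocks x 3 column-blocks.
    """
    rb, cb = divmod(subdivision, 3)
    out = []
    for r in range(4 * rb, 4 * rb + 4):
        for c in range(4 * cb, 4 * cb + 4):
            out.append((f"{_ROWS[r]}{c + 1}", r, c))
    return out


def make_plate_layout(
    experiment: int,
    plate: int,
    bands: list[Band],
    a2e_levels: tuple[float, ...] = DEFAULT_A2E_LEVELS,
    wells_per_condition: int = 4,
) -> PlateLayout:
    """Assign 5 bands + dark to the six subdivisions of one plate.

    Within each subdivision the A2E concentrations occupy one contiguous
    4-well row each (lowest concentration in the top row).
    """
    if len(bands) != N_SUBDIVISIONS - 1:
        raise ValueError(f"a plate carries exactly {N_SUBDIVISIONS - 1} illuminated bands")
    if len(a2e_levels) * wells_per_condition != WELLS_PER_SUBDIVISION:
        raise ValueError(
            "A2E levels x wells per condition must fill the 16-well subdivision"
        )
    assignment: list[object] = [None] * N_SUBDIVISIONS
    assignment[DARK_SUBDIVISION] = DARK
    lit = [i for i in range(N_SUBDIVISIONS) if i != DARK_SUBDIVISION]
    for sub, band in zip(lit, bands):
        assignment[sub] = band.center_nm
    rows = []
    for sub in range(N_SUBDIVISIONS):
        for i, (well, r, c) in enumerate(_subdivision_wells(sub)):
            level = a2e_levels[i // wells_per_condition]
            rows.append(
                {
                    "experiment": experiment,
                    "plate": plate,
                    "subdivision": sub,
                    "well": well,
                    "row": r,
                    "col": c,
                    "band_nm": assignment[sub],
                    "a2e_uM": level,
                }
            )
    return PlateLayout(experiment, plate, pd.DataFrame(rows))


def plan_experiment(
    bandset: BandSet,
    a2e_levels: tuple[float, ...] = DEFAULT_A2E_LEVELS,
    replicates: int = 4,
    wells_per_condition: int = 4,
    seed: int = 0,
) -> list[PlateLayout]:
    """Plan the full campaign: every band tested in ``replicates`` plates.

    Each plate is one independent experiment carrying 5 bands plus its
    dark control.  Bands are shuffled (deterministically from ``seed``)
    before being chunked into plates, so band co-occupancy varies between
    replicate rounds as it would across real experimental sessions.  When
    the number of bands is not a multiple of 5 the remainder plate is
    completed with a seeded draw of already-planned bands, so those bands
    accrue extra replicates (experiments run "at least 4 and up to 6"
    times rather than exactly 4).
    """
    if len(a2e_levels) * wells_per_condition != WELLS_PER_SUBDIVISION:
        raise ValueError("more A2E levels than the 16-well subdivision allows")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    per_plate = N_SUBDIVISIONS - 1
    layouts: list[PlateLayout] = []
    plate_id = 0
    for _ in range(replicates):
        order = list(rng.permutation(len(bandset)))
        # pad the final chunk with distinct extra bands drawn from the rest
        short = (-len(order)) % per_plate
        if short:
            pool = [i for i in range(len(bandset)) if i not in order[-(per_plate - short):]]
            order += list(rng.choice(pool, size=short, replace=False))
        for start in range(0, len(order), per_plate):
            chunk = [bandset.bands[i] for i in order[start : start + per_plate]]
            layouts.append(
                make_plate_layout(
                    experiment=plate_id,
                    plate=plate_id,
                    bands=chunk,
                    a2e_levels=a2e_levels,
                    wells_per_condition=wells_per_condition,
                )
            )
            plate_id += 1
    return layouts


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    """Concatenate plate layouts into the exportable long table."""
    df = pd.concat([p.wells for p in layouts], ignore_index=True)
    out = df.copy()
    out["band_nm"] = out["band_nm"].map(lambda b: "" if b == DARK else b)
    return out
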