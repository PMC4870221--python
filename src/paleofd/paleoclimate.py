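"""Historical (glacial-legacy) predictors from paired present / LGM climate.

Builds the two predictors that carry the paleoclimatic signal:

* **climate velocity** — the local speed (km per decade) at which a climate
  isoline must move to track the change between the Last Glacial Maximum
  (~21 kyr BP) and the present: temporal anomaly divided by the local
  spatial gradient of the present-day surface;
* **accessibility to glacial refugia** — for each cell, the sum of inverse
  distances to all cells that were climatically suitable for cool-temperate
  trees at the LGM (suitability = growing degree-days, coldest-month
  temperature, and summer precipitation thresholds).

Supporting steps: ensemble averaging over climate models, change-factor
statistical downscaling of coarse LGM output onto a fine present-day
baseline, and growing degree-day accumulation from monthly means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist

from .grids import ClimateGrid

__all__ = [
    "RefugiaThresholds",
    "RefugiaMask",
    "VelocityGrid",
    "ensemble_mean",
    "change_factor_downscale",
    "growing_degree_days",
    "coldest_month_mean",
    "summer_precipitation",
    "refugia_mask",
    "climate_velocity",
    "accessibility",
]

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
SUMMER_MONTHS = (6, 7, 8)  # JJA, Northern-Hemisphere convention

#: floor on the spatial gradient (units per km) to keep velocity finite on
#: flat surfaces; standard practice in the climate-velocity literature
GRADIENT_FLOOR = 1e-5


@dataclass(frozen=True)
class RefugiaThresholds:
    """Climatic suitability limits for cool-temperate trees at the LGM.

    The coldest-month limit defaults to −15 °C: a *minimum* winter
    temperature that cold-tolerant temperate trees can survive. A +15 °C
    reading would exclude essentially all of temperate Europe and is not a
    coherent cold-tolerance bound; the sign is configurable here.
    """

    gdd_min: float = 800.0       # °C·day
    tcold_min: float = -15.0     # °C, mean of coldest month
    psummer_min: float = 50.0    # mm, June–August total


@dataclass
class RefugiaMask:
    """Boolean suitability grid plus the thresholds that produced it."""

    mask: np.ndarray
    grid: ClimateGrid  # georeference carrier
    thresholds: RefugiaThresholds

    @property
    def n_refugial(self) -> int:
        return int(np.nansum(self.mask))


@dataclass
class VelocityGrid:
    """Climate velocity (km·decade⁻¹) with its log10 companion."""

    values: np.ndarray
    log10_values: np.ndarray
    variable: str
    gradient_floored: np.ndarray  # True where the gradient floor was applied


def ensemble_mean(grids: Sequence[ClimateGrid]) -> ClimateGrid:
    """Cellwise mean over an ensemble of model surfaces, ignoring nodata.

    Cells where every member is nodata stay nodata.
    """
    if len(grids) == 0:
        raise ValueError("ensemble_mean needs at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_georeference(g):
            raise ValueError("ensemble members must share georeference")
        if g.variable != first.variable:
            raise ValueError("ensemble members must share variable")
    stack = np.stack([g.values for g in grids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(stack, axis=0)
    return first.with_values(mean)


def _bilinear_to_fine(coarse: ClimateGrid, fine: ClimateGrid) -> np.ndarray:
    """Bilinearly interpolate a coarse field at the fine grid's cell centers.

    Fine centers outside the coarse center hull are clamped to the edge
    (nearest-edge extrapolation), so a spatially constant coarse field
    survives the operation exactly.
    """
    nrows, ncols = coarse.shape
    xs = coarse.x0 + (np.arange(ncols) + 0.5) * coarse.cell_size_km
    ys = coarse.y0 + (nrows - 1 - np.arange(nrows) + 0.5) * coarse.cell_size_km
    # rows run north->south, so ys is decreasing; flip for the interpolator
    interp = RegularGridInterpolator(
        (ys[::-1], xs), coarse.values[::-1, :], method="linear",
        bounds_error=False, fill_value=None,
    )
    FX, FY = fine.cell_centers()
    fy = np.clip(FY, ys.min(), ys.max())
    fx = np.clip(FX, xs.min(), xs.max())
    return interp(np.stack([fy.ravel(), fx.ravel()], axis=1)).reshape(fine.shape)


def change_factor_downscale(
    coarse_lgm: ClimateGrid,
    coarse_present: ClimateGrid,
    fine_present: ClimateGrid,
    precip_eps: float = 0.1,
) -> ClimateGrid:
    """Change-factor (delta/ratio) downscaling of a coarse LGM surface.

    Temperature uses additive anomalies, precipitation multiplicative
    ratios (with the coarse present floored at ``precip_eps`` mm to avoid
    division blow-ups), each interpolated bilinearly to the fine grid and
    applied to the fine present-day baseline. Precipitation is clipped at 0.
    """
    if coarse_lgm.variable != coarse_present.variable or coarse_lgm.variable != fine_present.variable:
        raise ValueError("downscaling inputs must share a variable")
    if not coarse_lgm.same_georeference(coarse_present):
        raise ValueError("coarse grids must share georeference")
    if fine_present.variable.startswith("precip"):
        ratio = coarse_lgm.values / np.maximum(coarse_present.values, precip_eps)
        factor_grid = coarse_lgm.with_values(ratio)
        fine_vals = fine_present.values * _bilinear_to_fine(factor_grid, fine_present)
        fine_vals = np.clip(fine_vals, 0.0, None)
    else:
        anomaly = coarse_lgm.with_values(coarse_lgm.values - coarse_present.values)
        fine_vals = fine_present.values + _bilinear_to_fine(anomaly, fine_present)
    return fine_present.with_values(fine_vals, epoch="lgm")


def growing_degree_days(monthly_temps: Sequence[ClimateGrid], base: float = 5.0) -> ClimateGrid:
    """Annual growing degree-days (°C·day) above ``base``, non-leap calendar.

    GDD = Σ_m max(0, T_m − base) · days(m), with monthly mean temperature
    standing in for the daily series.
    """
    if len(monthly_temps) != 12:
        raise ValueError("growing_degree_days needs 12 monthly grids")
    first = monthly_temps[0]
    gdd = np.zeros(first.shape)
    for m, g in enumerate(monthly_temps):
        if not first.same_georeference(g):
            raise ValueError("monthly grids must share georeference")
        gdd = gdd + np.maximum(0.0, g.values - base) * DAYS_IN_MONTH[m]
    return first.with_values(gdd, variable="gdd", month=None)


def coldest_month_mean(monthly_temps: Sequence[ClimateGrid]) -> ClimateGrid:
    """Cellwise mean temperature of the coldest month."""
    if len(monthly_temps) != 12:
        raise ValueError("need 12 monthly grids")
    stack = np.stack([g.values for g in monthly_temps])
    return monthly_temps[0].with_values(np.min(stack, axis=0), variable="tcold", month=None)


def summer_precipitation(monthly_precip: Sequence[ClimateGrid]) -> ClimateGrid:
    """June + July + August precipitation total (mm)."""
    if len(monthly_precip) != 12:
        raise ValueError("need 12 monthly grids")
    total = sum(monthly_precip[m - 1].values for m in SUMMER_MONTHS)
    return monthly_precip[0].with_values(total, variable="psummer", month=None)


def refugia_mask(
    gdd: ClimateGrid,
    tcold: ClimateGrid,
    psummer: ClimateGrid,
    thresholds: RefugiaThresholds | None = None,
) -> RefugiaMask:
    """Cells climatically suitable for cool-temperate trees at the LGM.

    A cell is refugial iff all three conditions hold, boundaries inclusive:
    GDD ≥ gdd_min, coldest-month mean ≥ tcold_min, summer precip ≥ psummer_min.
    """
    thresholds = thresholds or RefugiaThresholds()
    if not (gdd.same_georeference(tcold) and gdd.same_georeference(psummer)):
        raise ValueError("refugia inputs must share georeference")
    mask = (
        (gdd.values >= thresholds.gdd_min)
        & (tcold.values >= thresholds.tcold_min)
        & (psummer.values >= thresholds.psummer_min)
    )
    mask &= ~(gdd.nodata_mask | tcold.nodata_mask | psummer.nodata_mask)
    return RefugiaMask(mask=mask, grid=gdd, thresholds=thresholds)


def _horn_gradient(values: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope magnitude (units per km) of the 3×3 plane fit, Horn's method.

    Edge cells reuse the nearest interior values (edge replication), i.e.
    they fall back on the neighbors that exist.
    """
    z = np.pad(values, 1, mode="edge")
    c = z[1:-1, 1:-1]
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    del c
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * cell_size)
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * cell_size)
    return np.hypot(gx, gy)


def climate_velocity(
    present: ClimateGrid,
    lgm: ClimateGrid,
    years: float = 21_000.0,
    gradient_floor: float = GRADIENT_FLOOR,
) -> VelocityGrid:
    """LGM-to-present climate velocity, km per decade.

    Temporal trend per cell is the absolute LGM anomaly spread over the
    elapsed decades; the spatial gradient is the Horn 3×3 slope of the
    present-day surface, floored at ``gradient_floor`` so flat terrain
    yields a large-but-finite velocity (flagged in the output).
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if not present.same_georeference(lgm):
        raise ValueError("present and LGM grids must share georeference")
    trend = np.abs(present.values - lgm.values) / (years / 10.0)
    gradient = _horn_gradient(present.values, present.cell_size_km)
    floored = gradient < gradient_floor
    velocity = trend / np.maximum(gradient, gradient_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        log10 = np.where(velocity > 0, np.log10(np.maximum(velocity, 1e-300)), np.nan)
    return VelocityGrid(
        values=velocity,
        log10_values=log10,
        variable=present.variable,
        gradient_floored=floored,
    )


def accessibility(
    cell_coords: np.ndarray,
    refugia: RefugiaMask | np.ndarray,
    cell_size_km: float | None = None,
) -> np.ndarray:
    """Inverse-distance accessibility (km⁻¹) of every cell to the refugia.

    A_i = Σ_{j refugial} 1/d_ij over Euclidean centroid distances on the
    projected plane. A refugial focal cell contributes a self-term with
    d = cell_size/2 (half a cell: the distance to its own interior).
    """
    coords = np.asarray(cell_coords, dtype=float)
    if isinstance(refugia, RefugiaMask):
        flags = refugia.mask.ravel().astype(bool)
        if cell_size_km is None:
            cell_size_km = refugia.grid.cell_size_km
    else:
        flags = np.asarray(refugia).ravel().astype(bool)
    if flags.shape[0] != coords.shape[0]:
        raise ValueError("refugia flags must align with cell coordinates")
    if not flags.any():
        warnings.warn("empty refugia set: accessibility is zero everywhere")
        return np.zeros(coords.shape[0])
    if cell_size_km is None:
        raise ValueError("cell_size_km required when refugia given as flags")
    d = cdist(coords, coords[flags])
    # self-distance of refugial cells shows up as an exact zero
    d[d == 0.0] = cell_size_km / 2.0
    return (1.0 / d).sum(axis=1)
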