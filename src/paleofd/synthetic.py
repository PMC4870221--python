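"""Synthetic study system: every input the analysis needs, from one config.

The generators emulate the statistical structure of a continental plant
atlas coupled to paired present/glacial climate surfaces:

* lognormal traits with a chosen inter-trait correlation on the log scale
  and genus-level random intercepts (taxonomic signal), plus a growth form
  per genus;
* missing-completely-at-random gaps at per-trait rates matching published
  trait-database completeness (≈ 42–53% missing);
* a rectangular equal-area grid whose per-cell species richness follows an
  environmental gradient, with Gaussian trait filtering that narrows the
  sampled trait space where a chosen predictor is extreme;
* monthly present-day temperature/precipitation surfaces and glacial
  counterparts offset by a spatially varying anomaly (colder, strongest at
  high latitude);
* response vectors drawn from the simultaneous-autoregressive error
  process y = Xβ + u, (I − λW)u = ε, for parameter-recovery experiments.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .fd import OccurrenceMatrix
from .grids import ClimateGrid
from .spatial import SpatialWeights
from .traits import GROWTH_FORMS, TRAITS

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "generate_traits",
    "inject_missingness",
    "generate_occurrences",
    "generate_climate_pair",
    "generate_response",
]


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


def _default_trait_corr() -> np.ndarray:
    R = np.full((4, 4), 0.5)
    np.fill_diagonal(R, 1.0)
    return R


def _default_missing_rates() -> dict[str, float]:
    # completeness of large compiled trait databases: roughly half missing
    return {"sla": 0.50, "max_height": 0.53, "seed_mass": 0.50, "stem_density": 0.42}


def _default_effects() -> dict[str, float]:
    return {"accessibility": 0.5, "gdd": 0.3}


# log10-scale location and total SD per trait (units: cm² g⁻¹, mg, m, kg m⁻³)
TRAIT_LOG_MEAN = {"sla": 2.3, "seed_mass": 0.0, "max_height": -0.3, "stem_density": 2.7}
TRAIT_LOG_SD = {"sla": 0.3, "seed_mass": 0.8, "max_height": 0.6, "stem_density": 0.15}
GENUS_VARIANCE_SHARE = 0.3  # fraction of log-scale variance between genera

GROWTH_FORM_PROBS = {
    "forb": 0.45, "graminoid": 0.15, "shrub": 0.13,
    "tree": 0.10, "fern": 0.09, "climber": 0.08,
}


@dataclass
class SyntheticConfig:
    """Study-system parameters; defaults define the reference conditions."""

    grid_nrows: int = 20
    grid_ncols: int = 20
    cell_size_km: float = 50.0
    n_species: int = 300
    n_genera: int = 40
    trait_corr: np.ndarray = field(default_factory=_default_trait_corr)
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    richness_range: tuple[int, int] = (10, 150)
    sar_lambda: float = 0.3
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.grid_nrows < 3 or self.grid_ncols < 3:
            raise ConfigError("grid dimensions must be >= 3")
        if self.cell_size_km <= 0:
            raise ConfigError("cell size must be positive")
        if self.n_species < 2 * self.n_genera:
            raise ConfigError("need n_species >= 2 * n_genera")
        R = self.trait_corr
        if R.shape != (4, 4) or not np.allclose(R, R.T):
            raise ConfigError("trait_corr must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ConfigError("trait_corr must be positive-definite")
        for tr, rate in self.missing_rates.items():
            if not (0 <= rate < 1):
                raise ConfigError(f"missing rate for {tr!r} must be in [0, 1)")
        rmin, rmax = self.richness_range
        if rmin < 1:
            raise ConfigError("minimum richness must be >= 1")
        if rmax < rmin:
            raise ConfigError("richness_range must be (min, max) with min <= max")
        if rmax > self.n_species:
            raise ConfigError("maximum richness cannot exceed n_species")
        if not (-1 < self.sar_lambda < 1):
            raise ConfigError("sar_lambda must lie in (-1, 1)")


def generate_traits(cfg: SyntheticConfig) -> pd.DataFrame:
    """Complete species×trait table with genus structure, log-scale corr.

    Both the genus intercepts and the within-genus species deviations are
    multivariate normal with the *same* correlation matrix, so the total
    log-scale inter-trait correlation equals ``cfg.trait_corr`` regardless
    of how variance is split between the two levels.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_species, cfg.n_genera
    sd = np.array([TRAIT_LOG_SD[t] for t in TRAITS])
    mu = np.array([TRAIT_LOG_MEAN[t] for t in TRAITS])
    cov_shape = cfg.trait_corr * np.outer(sd, sd)
    L = np.linalg.cholesky(cov_shape)

    genus_of = rng.integers(0, g, size=n)
    genus_of[: 2 * g] = np.repeat(np.arange(g), 2)  # every genus >= 2 species
    genus_eff = (rng.standard_normal((g, 4)) @ L.T) * np.sqrt(GENUS_VARIANCE_SHARE)
    species_eff = (rng.standard_normal((n, 4)) @ L.T) * np.sqrt(1 - GENUS_VARIANCE_SHARE)
    log_traits = mu + genus_eff[genus_of] + species_eff

    gf_pool = list(GROWTH_FORM_PROBS)
    gf_p = np.array(list(GROWTH_FORM_PROBS.values()))
    genus_gf = rng.choice(gf_pool, size=g, p=gf_p)

    df = pd.DataFrame(10.0**log_traits, columns=TRAITS)
    df.insert(0, "species_id", [f"sp{i:04d}" for i in range(n)])
    df.insert(1, "genus", [f"gen{gi:03d}" for gi in genus_of])
    df.insert(2, "growth_form", pd.Categorical(genus_gf[genus_of], categories=GROWTH_FORMS))
    return df


def inject_missingness(
    traits: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Mask each trait completely at random at its requested rate.

    Exactly ``round(n · rate)`` cells per column are blanked; genus and
    growth form are never masked.
    """
    for tr, rate in rates.items():
        if not (0 <= rate < 1):
            raise ValueError(f"missing rate for {tr!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = traits.copy()
    n = len(out)
    for tr, rate in rates.items():
        k = int(round(n * rate))
        if k:
            out.loc[out.index[rng.choice(n, size=k, replace=False)], tr] = np.nan
    return out


def generate_occurrences(
    cfg: SyntheticConfig,
    env: pd.DataFrame,
    traits_std: pd.DataFrame,
    richness_driver: str = "accessibility",
    filter_predictor: str = "gdd",
    filter_trait: str = "sla",
    niche_width: tuple[float, float] = (0.4, 2.5),
    optimum_slope: float = 1.0,
    seed: int | None = None,
) -> OccurrenceMatrix:
    """Cells×species binary matrix with a richness gradient + trait filtering.

    Per-cell richness is a deterministic monotone (min–max) rescaling of
    ``env[richness_driver]`` into the configured richness range. Species
    membership is then drawn without replacement with Gaussian inclusion
    weights on the standardized log value of ``filter_trait``: the niche
    optimum tracks the standardized filter predictor, and the niche width
    shrinks where that predictor is extreme, so environmental filtering
    narrows the occupied trait space exactly where the recovery tests
    expect it to.

    ``env`` must carry one row per grid cell, in row-major grid order, with
    columns ``x_km``/``y_km`` for the centroids.
    """
    rmin, rmax = cfg.richness_range
    if rmax > cfg.n_species:
        raise ValueError("maximum richness cannot exceed the species pool")
    n_cells = cfg.grid_nrows * cfg.grid_ncols
    if len(env) != n_cells:
        raise ValueError("env must have one row per grid cell")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    driver = env[richness_driver].to_numpy(dtype=float)
    span = driver.max() - driver.min()
    rel = (driver - driver.min()) / span if span > 0 else np.zeros_like(driver)
    richness = np.rint(rmin + rel * (rmax - rmin)).astype(int)

    filt = env[filter_predictor].to_numpy(dtype=float)
    filt_z = (filt - filt.mean()) / (filt.std() or 1.0)
    z_trait = traits_std.set_index("species_id")[filter_trait]
    z = z_trait.to_numpy(dtype=float)
    w_lo, w_hi = niche_width
    widths = np.clip(w_hi - (w_hi - w_lo) * np.abs(filt_z) / 2.0, w_lo, w_hi)
    optima = optimum_slope * filt_z

    n_species = cfg.n_species
    matrix = np.zeros((n_cells, n_species), dtype=bool)
    for i in range(n_cells):
        logw = -((z - optima[i]) ** 2) / (2.0 * widths[i] ** 2)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        chosen = rng.choice(n_species, size=richness[i], replace=False, p=w)
        matrix[i, chosen] = True

    coords = env[["x_km", "y_km"]].to_numpy(dtype=float)
    cell_ids = [f"c{i:04d}" for i in range(n_cells)]
    return OccurrenceMatrix(
        cell_ids=cell_ids, coords=coords,
        species_ids=list(z_trait.index), matrix=matrix,
    )


def _grid_fields(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (0..1) east–west and south–north coordinate fields."""
    rows = np.arange(cfg.grid_nrows)
    cols = np.arange(cfg.grid_ncols)
    C, R = np.meshgrid(cols, rows)
    lat = 1.0 - R / max(cfg.grid_nrows - 1, 1)   # row 0 = north = 1
    lon = C / max(cfg.grid_ncols - 1, 1)
    return lon, lat


def _smooth_field(lon: np.ndarray, lat: np.ndarray, rng: np.random.Generator,
                  n_components: int = 6) -> np.ndarray:
    """Smooth mean-0, SD-1 random surface: a few low-frequency sinusoids.

    Gives each climate variable its own geography (orography, continentality,
    glacial anomaly pattern ...) so that the predictors derived downstream
    are only weakly cross-correlated, as in real continental predictor sets,
    instead of all collapsing onto the latitude gradient.
    """
    f = np.zeros_like(lon)
    for _ in range(n_components):
        u, v = rng.integers(1, 4, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.normal(0, 1.0 / np.hypot(u, v))
        f = f + amp * np.sin(2 * np.pi * (u * lon) + phase[0]) * np.sin(
            2 * np.pi * (v * lat) + phase[1]
        )
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_climate_pair(
    cfg: SyntheticConfig,
    anomaly_temperature: float | np.ndarray | None = None,
    anomaly_precip_factor: float | np.ndarray | None = None,
) -> dict[str, dict[str, list[ClimateGrid]]]:
    """Monthly present and LGM surfaces for temperature and precipitation.

    Present temperature combines a south–north gradient, a seasonal cycle
    whose amplitude varies with a "continentality" surface, and a mild
    independent texture; precipitation follows its own smooth "orography"
    surface plus a weak latitude term, so temperature- and water-derived
    predictors are only loosely related. The LGM surfaces subtract a
    temperature anomaly that grows toward high grid latitude (~5–15 °C,
    everywhere colder) with its own spatial texture, and scale
    precipitation down by a spatially varying factor. Pass scalars/arrays
    to override either anomaly.

    Returns ``{"temperature": {"present": [12 grids], "lgm": [...]},
    "precipitation": {...}}``.
    """
    lon, lat = _grid_fields(cfg)
    field_rng = np.random.default_rng([cfg.seed, 1723])
    continentality = _smooth_field(lon, lat, field_rng)
    orography = _smooth_field(lon, lat, field_rng)
    glacial_texture = _smooth_field(lon, lat, field_rng)
    glacial_wet = _smooth_field(lon, lat, field_rng)

    if anomaly_temperature is None:
        # colder everywhere, strongest at high latitude, own geography
        d_temp = -np.maximum(5.0 + 10.0 * lat + 3.0 * glacial_texture, 1.0)
    else:
        d_temp = np.broadcast_to(
            np.asarray(anomaly_temperature, dtype=float), lat.shape
        ).copy()
    if anomaly_precip_factor is None:
        # glacial aridity strong enough that the summer-moisture criterion
        # co-limits the refugia: refugial geography then has its own pattern
        # rather than mirroring present-day warmth
        p_fac = np.clip(0.45 - 0.1 * lat + 0.25 * glacial_wet, 0.05, 1.1)
    else:
        p_fac = np.broadcast_to(
            np.asarray(anomaly_precip_factor, dtype=float), lat.shape
        ).copy()

    season_amp = 8.0 + 3.0 * continentality
    out: dict[str, dict[str, list[ClimateGrid]]] = {
        "temperature": {"present": [], "lgm": []},
        "precipitation": {"present": [], "lgm": []},
    }
    for m in range(1, 13):
        season = np.cos(2.0 * np.pi * (m - 7) / 12.0)  # peak in July
        t_present = (
            16.0 - 14.0 * lat + season_amp * season
            + 1.5 * np.sin(2.0 * np.pi * lon)
        )
        p_present = np.clip(
            70.0 + 30.0 * orography + 10.0 * (1.0 - lat)
            + 15.0 * np.cos(2.0 * np.pi * (m - 11) / 12.0),
            0.0, None,
        )
        common = dict(cell_size_km=cfg.cell_size_km, x0=0.0, y0=0.0)
        out["temperature"]["present"].append(
            ClimateGrid(t_present, variable="temperature", epoch="present", month=m, **common)
        )
        out["temperature"]["lgm"].append(
            ClimateGrid(t_present + d_temp, variable="temperature", epoch="lgm", month=m, **common)
        )
        out["precipitation"]["present"].append(
            ClimateGrid(p_present, variable="precipitation", epoch="present", month=m, **common)
        )
        out["precipitation"]["lgm"].append(
            ClimateGrid(
                np.clip(p_present * p_fac, 0.0, None),
                variable="precipitation", epoch="lgm", month=m, **common,
            )
        )
    return out


def generate_response(
    pred: pd.DataFrame,
    effects: dict[str, float],
    sar_lambda: float,
    W: SpatialWeights,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Draw y = Xβ + u with SAR(λ) errors: (I − λW)u = ε, ε ~ N(0, σ²I).

    ``effects`` maps predictor columns to their coefficients β; columns not
    named get zero effect. The spatial innovation system is solved exactly
    (sparse LU), not by truncated series.
    """
    unknown = [c for c in effects if c not in pred.columns]
    if unknown:
        raise ValueError(f"effect names missing from predictors: {unknown}")
    if not (-1 < sar_lambda < 1):
        raise ValueError("|sar_lambda| must be < 1")
    n = len(pred)
    if W.n != n:
        raise ValueError("weights do not match predictor table")
    rng = np.random.default_rng(seed)
    xb = np.zeros(n)
    for col, beta in effects.items():
        xb += beta * pred[col].to_numpy(dtype=float)
    eps = rng.standard_normal(n) * noise_sd
    A = (sparse.identity(n) - sar_lambda * W.W).tocsc()
    u = spsolve(A, eps)
    return xb + u
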