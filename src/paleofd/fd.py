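"""Functional-diversity metrics per grid cell, with a richness-preserving null.

Two multivariate metrics on the standardized log-trait space:

* **functional richness** (F_Rich) — the convex-hull volume of the
  co-occurring species' trait points: the size of the occupied trait space,
  abundance-free. Undefined (NaN) when fewer than d+1 species are present
  or the points are affinely degenerate; a degenerate assemblage is not the
  same thing as a genuinely tiny hull.
* **functional dispersion** (F_Disp) — the mean Euclidean distance of each
  species to the unweighted trait centroid of the assemblage.

Univariate range and (population) SD per trait complement them. The null
model redraws each cell's species uniformly from the full pool, holding the
cell's species richness fixed; standardized effect sizes (SES) are
(observed − null mean) / null SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .traits import TRAITS, ImputedSet, pool_over_replicates

__all__ = [
    "OccurrenceMatrix",
    "FDResult",
    "functional_richness",
    "functional_dispersion",
    "univariate_range_sd",
    "randomize_occurrence",
    "ses",
    "fd_pipeline",
]


@dataclass
class OccurrenceMatrix:
    """Binary cells×species matrix on a projected equal-area grid."""

    cell_ids: list[str]
    coords: np.ndarray          # (n_cells, 2) centroid km
    species_ids: list[str]
    matrix: np.ndarray          # bool, cells × species

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix).astype(bool)
        self.coords = np.asarray(self.coords, dtype=float)
        n_cells, n_species = self.matrix.shape
        if len(self.cell_ids) != n_cells or len(self.species_ids) != n_species:
            raise ValueError("matrix shape does not match id lists")
        if self.coords.shape != (n_cells, 2):
            raise ValueError("coords must be (n_cells, 2)")

    @property
    def richness(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def functional_richness(trait_points: np.ndarray) -> float:
    """Convex-hull volume of an assemblage in trait space; NaN if degenerate.

    Needs at least d+1 affinely independent points in d dimensions. Qhull
    joggling is deliberately off: a degenerate input returns NaN rather
    than a perturbation-dependent volume.
    """
    pts = np.atleast_2d(np.asarray(trait_points, dtype=float))
    n, d = pts.shape
    if n < d + 1:
        return float("nan")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return float("nan")


def functional_dispersion(trait_points: np.ndarray) -> float:
    """Mean Euclidean distance to the unweighted centroid; 0 for one point."""
    pts = np.atleast_2d(np.asarray(trait_points, dtype=float))
    centroid = pts.mean(axis=0)
    return float(np.linalg.norm(pts - centroid, axis=1).mean())


def univariate_range_sd(values: np.ndarray) -> tuple[float, float]:
    """(max − min, population SD) of one trait in one assemblage."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty assemblage")
    return float(v.max() - v.min()), float(v.std())


def randomize_occurrence(occ: OccurrenceMatrix, seed: int | np.random.Generator) -> OccurrenceMatrix:
    """Uniform richness-preserving randomization of the occurrence matrix.

    Every cell keeps its species count; its members are redrawn uniformly
    without replacement from the full species pool.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cells, n_species = occ.matrix.shape
    out = np.zeros_like(occ.matrix)
    richness = occ.richness
    for i in range(n_cells):
        k = int(richness[i])
        if k == n_species:
            out[i] = True
        elif k > 0:
            out[i, rng.choice(n_species, size=k, replace=False)] = True
    return OccurrenceMatrix(
        cell_ids=occ.cell_ids, coords=occ.coords,
        species_ids=occ.species_ids, matrix=out,
    )


def ses(observed: float, null_values: np.ndarray) -> float:
    """(observed − null mean) / null SD (n−1 denominator); NaN if undefined."""
    nulls = np.asarray(null_values, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size < 2 or not np.isfinite(observed):
        return float("nan")
    sd = nulls.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((observed - nulls.mean()) / sd)


@dataclass
class FDResult:
    """Per-replicate and pooled per-cell FD tables."""

    per_replicate: list[pd.DataFrame]
    pooled: pd.DataFrame
    n_null: int
    seed: int


def _cell_metrics(points: np.ndarray) -> dict[str, float]:
    row: dict[str, float] = {
        "f_rich": functional_richness(points),
        "f_disp": functional_dispersion(points),
    }
    for j, tr in enumerate(TRAITS):
        rng_, sd_ = univariate_range_sd(points[:, j])
        row[f"range_{tr}"] = rng_
        row[f"sd_{tr}"] = sd_
    return row


def fd_pipeline(
    occ: OccurrenceMatrix,
    imputed: ImputedSet,
    n_null: int = 0,
    seed: int = 0,
) -> FDResult:
    """FD metrics per cell, per imputation replicate, with optional SES.

    For each replicate the standardized trait matrix is aligned to the
    occurrence species order (an error lists any species missing from the
    traits). With ``n_null > 0``, SES of F_Rich and F_Disp is computed from
    that many richness-preserving randomizations; null draws share one
    seeded stream so reruns reproduce exactly. Pooled output is the
    replicate mean plus min/max range per column.
    """
    results: list[pd.DataFrame] = []
    richness = occ.richness
    if (richness < 1).any():
        raise ValueError("every retained cell must have richness >= 1")
    for r_idx, rep in enumerate(imputed.replicates):
        tr_df = rep.set_index("species_id")
        missing = [s for s in occ.species_ids if s not in tr_df.index]
        if missing:
            raise ValueError(f"species absent from trait table: {missing[:10]}")
        points_all = tr_df.loc[occ.species_ids, TRAITS].to_numpy(dtype=float)
        rows = []
        for i in range(len(occ.cell_ids)):
            pts = points_all[occ.matrix[i]]
            row = {"cell_id": occ.cell_ids[i], "richness": int(richness[i])}
            row.update(_cell_metrics(pts))
            rows.append(row)
        df = pd.DataFrame(rows).set_index("cell_id")

        if n_null > 0:
            rng = np.random.default_rng([seed, r_idx])
            null_rich = np.empty((n_null, len(occ.cell_ids)))
            null_disp = np.empty((n_null, len(occ.cell_ids)))
            for b in range(n_null):
                rand = randomize_occurrence(occ, rng)
                for i in range(len(occ.cell_ids)):
                    pts = points_all[rand.matrix[i]]
                    null_rich[b, i] = functional_richness(pts)
                    null_disp[b, i] = functional_dispersion(pts)
            df["ses_f_rich"] = [
                ses(df["f_rich"].iloc[i], null_rich[:, i]) for i in range(len(df))
            ]
            df["ses_f_disp"] = [
                ses(df["f_disp"].iloc[i], null_disp[:, i]) for i in range(len(df))
            ]
        results.append(df)

    numeric_cols = results[0].columns
    mean, (lo, hi) = pool_over_replicates([df[numeric_cols].to_numpy() for df in results])
    pooled = pd.DataFrame(mean, index=results[0].index, columns=numeric_cols)
    for j, col in enumerate(numeric_cols):
        pooled[f"{col}_min"] = lo[:, j]
        pooled[f"{col}_max"] = hi[:, j]
    return FDResult(per_replicate=results, pooled=pooled, n_null=n_null, seed=seed)
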