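"""Trait-table preparation: log10 + z-score transform and multiple imputation.

The trait table is a pandas DataFrame with one row per species and columns
``species_id``, ``genus``, ``growth_form`` plus the four continuous traits
(:data:`TRAITS`): specific leaf area (cm²·g⁻¹), seed mass (mg), maximum
stem height (m) and stem/wood density (kg·m⁻³). Continuous traits are
lognormal, so every analysis runs on log10-transformed, z-scored values.

Gaps are filled by a constrained chained-equations imputation (MICE): each
incomplete trait is regressed on the other traits, growth-form indicators
(the ecological constraint) and genus-level mean trait values (the
evolutionary constraint), and missing entries are drawn by predictive mean
matching so imputations stay inside the observed support. The whole
procedure is repeated m times (default 10) to propagate imputation
uncertainty into the downstream diversity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "GROWTH_FORMS",
    "TransformMeta",
    "ImputedSet",
    "log_standardize",
    "inverse_log_standardize",
    "mice_impute",
    "pool_over_replicates",
]

TRAITS = ["sla", "seed_mass", "max_height", "stem_density"]
GROWTH_FORMS = ["fern", "graminoid", "forb", "shrub", "tree", "climber"]

MIN_OBSERVED_PER_TRAIT = 10


@dataclass(frozen=True)
class TransformMeta:
    """Per-trait mean/SD of the log10 values; enables exact inversion."""

    means: dict[str, float]
    sds: dict[str, float]


@dataclass
class ImputedSet:
    """m complete copies of a trait table plus the imputation audit trail."""

    replicates: list[pd.DataFrame]
    m: int
    seed: int
    convergence_log: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.replicates) != self.m:
            raise ValueError("replicate count does not match m")


def log_standardize(traits: pd.DataFrame, columns: list[str] | None = None) -> tuple[pd.DataFrame, TransformMeta]:
    """log10-transform then z-score each continuous trait (mean 0, SD 1).

    Statistics are computed over observed entries only, with the population
    (n-denominator) SD. Returns the transformed table and the inverse
    metadata. Non-positive observed values are reported with species and
    trait; a constant column (zero SD) is an error.
    """
    columns = columns or TRAITS
    out = traits.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        bad = obs & (vals <= 0)
        if bad.any():
            sp = out.loc[bad, "species_id"].iloc[0] if "species_id" in out else out.index[bad][0]
            raise ValueError(f"non-positive value for trait {col!r} (species {sp!r})")
        logged = np.where(obs, np.log10(np.where(obs, vals, 1.0)), np.nan)
        mu = float(np.nanmean(logged))
        sd = float(np.nanstd(logged))  # population SD
        if sd == 0:
            raise ValueError(f"trait {col!r} is constant on the log scale; cannot standardize")
        out[col] = (logged - mu) / sd
        means[col] = mu
        sds[col] = sd
    return out, TransformMeta(means=means, sds=sds)


def inverse_log_standardize(traits: pd.DataFrame, meta: TransformMeta) -> pd.DataFrame:
    """Undo :func:`log_standardize` exactly (up to float round-off)."""
    out = traits.copy()
    for col, mu in meta.means.items():
        out[col] = 10.0 ** (out[col] * meta.sds[col] + mu)
    return out


def _genus_mean_covariate(df: pd.DataFrame, trait: str) -> np.ndarray:
    """Genus mean of the observed values of ``trait``, with fallbacks.

    Genera with no observed value for the trait (monotypic genera whose one
    species is missing it, in particular) fall back to the growth-form
    observed mean, then to the overall observed mean.
    """
    obs = df[trait].notna()
    overall = float(df.loc[obs, trait].mean()) if obs.any() else 0.0
    gmeans = df.loc[obs].groupby("genus")[trait].mean().to_dict()
    fmeans = (
        df.loc[obs].groupby(df.loc[obs, "growth_form"].astype(str))[trait]
        .mean()
        .to_dict()
    )
    genus = df["genus"].to_numpy(dtype=object)
    gform = df["growth_form"].astype(str).to_numpy(dtype=object)
    return np.array(
        [
            gmeans.get(g, fmeans.get(f, overall))
            for g, f in zip(genus, gform)
        ],
        dtype=float,
    )


def mice_impute(
    traits: pd.DataFrame,
    m: int = 10,
    max_iter: int = 20,
    seed: int = 0,
    k_pmm: int = 5,
    tol: float = 1e-3,
) -> ImputedSet:
    """Constrained MICE on standardized log traits, m independent chains.

    Per sweep, each incomplete trait is regressed (OLS) on the other three
    traits at their current filled values, growth-form indicators, and its
    genus-mean covariate. Coefficients are perturbed by a draw from their
    sampling distribution, predictions for the missing rows are matched to
    the ``k_pmm`` nearest observed predictions, and one donor's observed
    value is imputed. A chain stops when the mean absolute change of
    imputed values drops below ``tol`` (standardized scale) or after
    ``max_iter`` sweeps.

    Observed cells are never altered; every replicate is complete.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for tr in TRAITS:
        n_obs = int(traits[tr].notna().sum())
        if n_obs < MIN_OBSERVED_PER_TRAIT:
            raise ValueError(
                f"trait {tr!r} has only {n_obs} observed values "
                f"(need >= {MIN_OBSERVED_PER_TRAIT})"
            )
    if traits["genus"].isna().any() or traits["growth_form"].isna().any():
        raise ValueError("genus and growth form must be complete")

    base = traits.reset_index(drop=True)
    miss = {tr: base[tr].isna().to_numpy() for tr in TRAITS}
    incomplete = [tr for tr in TRAITS if miss[tr].any()]

    gf_dummies = pd.get_dummies(base["growth_form"], drop_first=True).to_numpy(dtype=float)
    genus_cov = {tr: _genus_mean_covariate(base, tr) for tr in TRAITS}

    root = np.random.default_rng(seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=m)

    replicates: list[pd.DataFrame] = []
    convergence_log: list[list[float]] = []
    for c in range(m):
        rng = np.random.default_rng(int(chain_seeds[c]))
        filled = {tr: base[tr].to_numpy(dtype=float).copy() for tr in TRAITS}
        for tr in TRAITS:  # initialize gaps at the observed mean
            if miss[tr].any():
                filled[tr][miss[tr]] = np.nanmean(base[tr].to_numpy(dtype=float))
        log: list[float] = []
        for _ in range(max_iter if incomplete else 0):
            total_change = 0.0
            n_imputed = 0
            for tr in incomplete:
                others = [t for t in TRAITS if t != tr]
                Xfull = np.column_stack(
                    [np.ones(len(base))]
                    + [filled[t] for t in others]
                    + [gf_dummies, genus_cov[tr][:, None]]
                )
                obs = ~miss[tr]
                y_obs = filled[tr][obs]
                X_obs, X_mis = Xfull[obs], Xfull[miss[tr]]
                beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
                resid = y_obs - X_obs @ beta
                dof = max(X_obs.shape[0] - X_obs.shape[1], 1)
                sigma2 = float(resid @ resid) / dof
                XtX_inv = np.linalg.pinv(X_obs.T @ X_obs)
                # proper imputation: parameter draw feeds the PMM matching;
                # eigendecomposition tolerates the singular covariance a
                # collinear dummy column produces
                evals, evecs = np.linalg.eigh(sigma2 * XtX_inv)
                half = evecs * np.sqrt(np.clip(evals, 0.0, None))
                beta_star = beta + half @ rng.standard_normal(beta.size)
                pred_obs = X_obs @ beta
                pred_mis = X_mis @ beta_star
                order = np.argsort(pred_obs)
                sorted_pred = pred_obs[order]
                sorted_y = y_obs[order]
                pos = np.searchsorted(sorted_pred, pred_mis)
                new_vals = np.empty(pred_mis.size)
                k = min(k_pmm, y_obs.size)
                for i, p in enumerate(pos):
                    lo = int(np.clip(p - k, 0, max(y_obs.size - 2 * k, 0)))
                    hi = min(lo + 2 * k, y_obs.size)
                    gaps = np.abs(sorted_pred[lo:hi] - pred_mis[i])
                    donors = np.argsort(gaps)[:k]
                    new_vals[i] = sorted_y[lo + donors[rng.integers(donors.size)]]
                total_change += float(np.abs(new_vals - filled[tr][miss[tr]]).sum())
                n_imputed += new_vals.size
                filled[tr][miss[tr]] = new_vals
            mean_change = total_change / max(n_imputed, 1)
            log.append(mean_change)
            if mean_change < tol:
                break
        rep = base.copy()
        for tr in TRAITS:
            rep[tr] = filled[tr]
        replicates.append(rep)
        convergence_log.append(log)
    return ImputedSet(replicates=replicates, m=m, seed=seed, convergence_log=convergence_log)


def pool_over_replicates(values: list[np.ndarray]) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Elementwise mean and (min, max) range over imputation replicates."""
    arrs = [np.asarray(v, dtype=float) for v in values]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("replicate vectors must share a shape")
    stack = np.stack(arrs)
    return stack.mean(axis=0), (stack.min(axis=0), stack.max(axis=0))
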